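"""Month-window predictors, bootstrapped correlation/response functions,
partial correlation."""
import numpy as np
import pandas as pd
import pytest

from ewdclim.errors import AlignmentError, DegenerateControlError, InsufficientDataError
from ewdclim.io import ClimateTable
from ewdclim.response import (
    MonthWindow,
    bootstrap_correlations,
    build_month_matrix,
    default_window,
    partial_correlation,
    response_function,
    seasonal_predictor,
)


def _climate(years, rng=None, base=15.0):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        base + rng.standard_normal((len(years), 12)),
        index=np.asarray(years),
        columns=[f"m{i}" for i in range(1, 13)],
    )
    df.index.name = "year"
    return ClimateTable("tmax", "degC", df)


class TestMonthWindow:
    def test_default_window_has_15_slots(self):
        w = default_window()
        assert len(w.slots) == 15
        assert w.slots[0] == (-1, 7)
        assert w.slots[-1] == (0, 9)
        assert w.labels()[0] == "prev_Jul"

    def test_unordered_slots_rejected(self):
        with pytest.raises(InsufficientDataError):
            MonthWindow([(0, 6), (0, 5)])

    def test_direct_lookup(self):
        clim = _climate(np.arange(1953, 1957))
        w = MonthWindow([(0, 5), (0, 6)])
        X = build_month_matrix(clim, w, [1954, 1955])
        assert X.shape == (2, 2)
        assert X.loc[1954, "cur_May"] == clim.monthly(5).loc[1954]
        assert X.loc[1955, "cur_Jun"] == clim.monthly(6).loc[1955]

    def test_prior_year_alignment_error(self):
        clim = _climate(np.arange(1953, 2009))
        with pytest.raises(AlignmentError):
            build_month_matrix(clim, default_window(), np.arange(1953, 2009))

    def test_seasonal_predictor_is_monthly_mean(self):
        clim = _climate(np.arange(1953, 2009))
        v = seasonal_predictor(clim, [5, 6], np.arange(1953, 2009))
        assert len(v) == 56
        expected = (clim.monthly(5) + clim.monthly(6)) / 2
        np.testing.assert_allclose(v.to_numpy(), expected.to_numpy())


class TestBootstrapCorrelations:
    def test_self_correlation_is_significant_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(56)
        years = np.arange(1953, 2009)
        y = pd.Series(x, index=years)
        X = pd.DataFrame({"copy": x, "noise": rng.standard_normal(56)}, index=years)
        res = bootstrap_correlations(y, X, n_boot=500, seed=0)
        assert res.coef[0] == pytest.approx(1.0, abs=1e-12)
        assert bool(res.significant[0])

    def test_zero_variance_slot_flagged_not_fatal(self):
        rng = np.random.default_rng(2)
        years = np.arange(1950, 2010)
        y = pd.Series(rng.standard_normal(60), index=years)
        X = pd.DataFrame(
            {"dead": np.ones(60), "live": y.to_numpy() + rng.standard_normal(60)},
            index=years,
        )
        res = bootstrap_correlations(y, X, n_boot=500, seed=0)
        assert np.isnan(res.coef[0])
        assert res.flags and "dead" in res.flags[0]
        assert np.isfinite(res.coef[1])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        years = np.arange(1950, 2010)
        y = pd.Series(rng.standard_normal(60), index=years)
        X = pd.DataFrame(rng.standard_normal((60, 5)), index=years)
        a = bootstrap_correlations(y, X, n_boot=600, seed=9)
        b = bootstrap_correlations(y, X, n_boot=600, seed=9)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)

    def test_bounds_converge_with_replicates(self):
        rng = np.random.default_rng(4)
        years = np.arange(1940, 2009)
        y = pd.Series(rng.standard_normal(69), index=years)
        X = pd.DataFrame(rng.standard_normal((69, 3)), index=years)
        a = bootstrap_correlations(y, X, n_boot=10000, seed=1)
        b = bootstrap_correlations(y, X, n_boot=10000, seed=2)
        assert np.abs(a.lo - b.lo).max() < 0.01
        assert np.abs(a.hi - b.hi).max() < 0.01

    def test_benchmark_sign_pattern(self, bench_run):
        """Density rises with May-June warmth and falls with May rain."""
        tmax = bench_run.correlations["tmax"]
        precip = bench_run.correlations["precip"]
        i_may = tmax.slots.index("cur_May")
        i_jun = tmax.slots.index("cur_Jun")
        assert tmax.coef[i_may] > 0 and tmax.significant[i_may]
        assert tmax.coef[i_jun] > 0 and tmax.significant[i_jun]
        j_may = precip.slots.index("cur_May")
        assert precip.coef[j_may] < 0 and precip.significant[j_may]


class TestResponseFunction:
    def test_recovers_single_signal_slot(self):
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame(rng.standard_normal((n, 15)), index=np.arange(n))
        y = pd.Series(0.8 * X[0].to_numpy() + 0.3 * rng.standard_normal(n), index=np.arange(n))
        res = response_function(y, X, n_boot=500, seed=3)
        assert res.coef[0] > 0 and res.significant[0]
        assert not res.significant[1:].any()

    def test_null_specificity_per_slot(self):
        rng = np.random.default_rng(8)
        flagged = total = 0
        for _ in range(25):
            y = pd.Series(rng.standard_normal(56), index=np.arange(56))
            X = pd.DataFrame(rng.standard_normal((56, 15)), index=np.arange(56))
            res = response_function(y, X, n_boot=500, seed=int(rng.integers(2**31)))
            flagged += int(res.significant.sum())
            total += 15
        assert flagged / total < 0.10

    def test_duplicate_columns_get_equal_coefficients(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((60, 4)), index=np.arange(60))
        X[4] = X[3]
        y = pd.Series(X[0].to_numpy() + 0.5 * rng.standard_normal(60), index=np.arange(60))
        res = response_function(y, X, n_boot=500, seed=1)
        assert res.coef[3] == pytest.approx(res.coef[4], abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((80, 6)), index=np.arange(80))
        y = pd.Series(X[2].to_numpy() + rng.standard_normal(80), index=np.arange(80))
        a = response_function(y, X, n_boot=500, seed=5)
        X2 = X.copy()
        X2[2] = 1000.0 * X2[2] + 5.0
        b = response_function(y, X2, n_boot=500, seed=5)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-9)


class TestPartialCorrelation:
    def test_formula_equals_residual_correlation(self):
        x = np.arange(1.0, 13.0)
        y = x[::-1].copy()
        z = np.tile([1.0, -1.0], 6)
        r, _ = partial_correlation(x, y, z)
        # independent oracle: correlate OLS residuals of x|z and y|z
        def resid(v):
            A = np.column_stack([np.ones_like(z), z])
            beta, *_ = np.linalg.lstsq(A, v, rcond=None)
            return v - A @ beta
        r_oracle = np.corrcoef(resid(x), resid(y))[0, 1]
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_random_inputs_match_residual_oracle_and_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        x = rng.standard_normal(40)
        z = rng.standard_normal(40)
        y = 0.5 * x + 0.3 * z + rng.standard_normal(40)
        r, p = partial_correlation(x, y, z)
        out = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-8)

    def test_independent_control_changes_little(self):
        rng = np.random.default_rng(13)
        n = 2000
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        r_partial, _ = partial_correlation(x, y, z)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_plain, abs=0.05)

    def test_collinear_control_error(self):
        x = np.arange(20.0)
        y = np.arange(20.0)[::-1].copy()
        with pytest.raises(DegenerateControlError):
            partial_correlation(x, y, x)

    def test_benchmark_temperature_signal_survives_precip_removal(self, bench, bench_run):
        """Removing the precipitation signal leaves a strong positive
        temperature partial correlation (the paper's qualitative conclusion)."""
        chron = bench_run.chronology.series()
        years = [int(y) for y in chron.index if 1953 <= y <= 2008]
        t = seasonal_predictor(bench.climate["tmax"], [5, 6], years)
        p = seasonal_predictor(bench.climate["precip"], [5, 6], years)
        r, pval = partial_correlation(t, chron.loc[years], p)
        assert r > 0.4
        assert pval < 0.01
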