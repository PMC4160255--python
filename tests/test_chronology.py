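"""Biweight mean, Rbar/EPS diagnostics and reliability truncation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewdclim.chronology import (
    Chronology,
    biweight_mean,
    build_chronology,
    eps_from_rbar,
    running_rbar_eps,
    truncate_reliable,
)
from ewdclim.detrend import IndexSeries, GrowthCurve, detrend_all
from ewdclim.errors import (
    CoverageGapError,
    EmptyReliablePeriodError,
    InsufficientDataError,
)
from ewdclim.synthetic import GeneratorConfig, make_benchmark_dataset


def _ix(sid, tree, first, values):
    return IndexSeries(sid, tree, first, np.asarray(values, dtype=float),
                       GrowthCurve("horizontal_mean", {"mean": 1.0}))


def _brute_biweight(x, iterations=200, c=9.0):
    """Independent fixed-point oracle (plain loop, no shared code paths)."""
    x = list(map(float, x))
    m = float(np.median(x))
    for _ in range(iterations):
        s = float(np.median([abs(v - m) for v in x]))
        if s == 0:
            return m
        num = den = 0.0
        for v in x:
            u = (v - m) / (c * s)
            if abs(u) < 1:
                w = (1 - u * u) ** 2
                num += w * v
                den += w
        m = num / den
    return m


class TestBiweight:
    def test_constant_values(self):
        assert biweight_mean([7.3] * 5) == 7.3

    def test_symmetric_triplet(self):
        assert biweight_mean([1, 2, 3]) == pytest.approx(2.0, abs=1e-12)

    def test_outlier_resistance_vs_oracle(self):
        data = [1.0, 1.1, 0.9, 1.0, 10.0]
        m = biweight_mean(data)
        assert m == pytest.approx(_brute_biweight(data), abs=1e-9)
        assert 0.9 < m < 1.2
        assert abs(m - 1.0) < abs(np.mean(data) - 1.0)

    def test_empty_input(self):
        with pytest.raises(InsufficientDataError):
            biweight_mean([])

    def test_equals_mean_without_outliers(self):
        data = [0.9, 0.95, 1.0, 1.05, 1.1]  # symmetric, all weights interior
        assert biweight_mean(data) == pytest.approx(np.mean(data), abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=30
        ),
        c=st.floats(min_value=0.1, max_value=50),
    )
    def test_scale_equivariance(self, values, c):
        lhs = biweight_mean([c * v for v in values])
        rhs = c * biweight_mean(values)
        assert lhs == pytest.approx(rhs, abs=1e-7 * (1 + abs(rhs)))


class TestEps:
    def test_perfect_agreement_limit(self):
        assert eps_from_rbar(2, 1.0) == 1.0
        assert eps_from_rbar(50, 1.0) == 1.0

    def test_monotone_in_depth_and_signal(self):
        grid_n = [2, 4, 6, 10, 25, 63]
        grid_r = [0.05, 0.2, 0.4, 0.6, 0.9]
        for r in grid_r:
            vals = [eps_from_rbar(n, r) for n in grid_n]
            assert all(b > a for a, b in zip(vals, vals[1:]))
        for n in grid_n:
            vals = [eps_from_rbar(n, r) for r in grid_r]
            assert all(b > a for a, b in zip(vals, vals[1:]))


class TestBuildChronology:
    def test_two_identical_series(self):
        rng = np.random.default_rng(3)
        values = 1 + 0.2 * rng.standard_normal(80)
        a = _ix("A", "T1", 1900, values)
        b = _ix("B", "T2", 1900, values)
        chron = build_chronology([a, b])
        np.testing.assert_allclose(chron.index, values, rtol=1e-9)
        finite = np.isfinite(chron.rbar)
        np.testing.assert_allclose(chron.rbar[finite], 1.0, atol=1e-12)
        np.testing.assert_allclose(chron.eps[finite], 1.0, atol=1e-12)

    def test_white_noise_rbar_near_zero(self):
        rng = np.random.default_rng(10)
        series = [_ix(f"S{i}", f"T{i}", 1700, 1 + 0.2 * rng.standard_normal(300))
                  for i in range(6)]
        frame = pd.concat([s.to_series() for s in series], axis=1)
        corr = frame.corr().to_numpy()
        rbar = corr[np.triu_indices_from(corr, k=1)].mean()
        assert abs(rbar) < 0.1

    def test_coverage_gap_error(self):
        a = _ix("A", "T1", 1900, np.ones(10))
        b = _ix("B", "T2", 1950, np.ones(10))
        with pytest.raises(CoverageGapError):
            build_chronology([a, b])

    def test_depth_counts_trees_and_cores(self, bench_run):
        chron = bench_run.chronology
        assert np.all(chron.n_trees <= chron.n_cores)
        assert chron.n_trees[-1] == 25
        assert chron.n_cores[-1] == 63

    def test_rbar_recovers_imposed_common_variance(self):
        # one noise tier only, coefficients solving rbar_pop = 0.4 exactly
        cfg = GeneratorConfig(
            seed=21, gamma_t=0.12, gamma_p=-0.144, sigma_tree=0.0, sigma_core=0.2296
        )
        data = make_benchmark_dataset(21, config=cfg)
        assert data.truth.common_variance_fraction == pytest.approx(0.4, abs=0.002)
        indices = detrend_all(data.measurements)
        frame = pd.concat([s.to_series() for s in indices], axis=1)
        corr = frame.corr(min_periods=20).to_numpy()
        pairs = corr[np.triu_indices_from(corr, k=1)]
        rbar = np.nanmean(pairs)
        assert rbar == pytest.approx(0.4, abs=0.05)


class TestRunningWindows:
    def test_undefined_window_flagged(self):
        a = _ix("A", "T1", 1900, np.ones(40) + 0.1 * np.sin(np.arange(40)))
        b = _ix("B", "T2", 1931, np.ones(30) + 0.1 * np.cos(np.arange(30)))
        stats = running_rbar_eps([a, b], window=30, step=15)
        assert any(w.flag == "undefined" for w in stats)

    def test_low_signal_window_reports_zero_eps(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        a = _ix("A", "T1", 1900, 1 + 0.1 * x)
        b = _ix("B", "T2", 1900, 1 - 0.1 * x)  # perfectly anti-correlated
        stats = running_rbar_eps([a, b], window=30, step=15)
        assert all(w.eps == 0.0 and w.flag == "low_signal" for w in stats)

    def test_window_validation(self):
        a = _ix("A", "T1", 1900, np.ones(40))
        b = _ix("B", "T2", 1900, np.ones(40))
        with pytest.raises(InsufficientDataError):
            running_rbar_eps([a, b], window=5)
        with pytest.raises(InsufficientDataError):
            running_rbar_eps([a, b], window=30, step=30)


def _manual_chronology(years, eps, trees, cores):
    n = len(years)
    return Chronology(
        years=np.asarray(years),
        index=np.ones(n),
        n_cores=np.asarray(cores),
        n_trees=np.asarray(trees),
        rbar=np.full(n, 0.5),
        eps=np.asarray(eps, dtype=float),
        windows=[],
    )


class TestTruncation:
    def test_vacuously_reliable_chronology_unchanged(self):
        years = np.arange(1700, 1800)
        chron = _manual_chronology(years, np.full(100, 0.9), np.full(100, 10), np.full(100, 20))
        out = truncate_reliable(chron)
        assert out.reliable_from == 1700
        assert len(out.years) == 100

    def test_override_retains_interior_low_eps_window(self):
        years = np.arange(1700, 1800)
        eps = np.full(100, 0.9)
        eps[11:41] = 0.76  # dips below 0.8 but stays above 0.75 with 4+ trees
        chron = _manual_chronology(years, eps, np.full(100, 4), np.full(100, 7))
        out = truncate_reliable(chron)
        assert out.reliable_from == 1700

    def test_deep_interior_dip_truncates(self):
        years = np.arange(1700, 1800)
        eps = np.full(100, 0.9)
        eps[11:41] = 0.70
        chron = _manual_chronology(years, eps, np.full(100, 6), np.full(100, 12))
        out = truncate_reliable(chron)
        assert out.reliable_from == int(years[41])

    def test_depth_schedule_sets_reliable_from(self):
        # only 3 trees reach the span start; the 4th enters in 1720
        starts = [1666, 1666, 1666, 1720, 1725] + list(
            np.linspace(1730, 1890, 20).round().astype(int)
        )
        cfg = GeneratorConfig(seed=31, tree_start_years=starts)
        data = make_benchmark_dataset(31, config=cfg)
        chron = build_chronology(detrend_all(data.measurements))
        out = truncate_reliable(chron)
        assert out.reliable_from == 1720

    def test_no_reliable_period_error(self):
        years = np.arange(1900, 1950)
        chron = _manual_chronology(years, np.full(50, 0.5), np.full(50, 10), np.full(50, 20))
        with pytest.raises(EmptyReliablePeriodError):
            truncate_reliable(chron)
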