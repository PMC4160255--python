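"""Growth-curve detrending of measurement series (ARSTAN-style standardization).

Tree-ring measurements carry a biologically driven age trend: wide/dense rings
while the cambium is young, decaying towards an asymptote.  Standardization
removes it by dividing each series by a fitted deterministic growth curve,
leaving dimensionless indices that fluctuate around 1 and can be averaged
across trees.

The curve cascade is deterministic:

1. modified negative exponential ``y(t) = a*exp(-b*t) + d`` with ``a > 0``,
   ``b > 0`` and a strictly positive fitted curve over the span;
2. least-squares straight line, accepted only with non-positive slope and a
   strictly positive fit;
3. horizontal line at the series mean.

The time axis ``t = 0, 1, ...`` counts years since the first measured ring
(a cambial-age proxy; no pith offsets are used).  Dated missing rings
(value 0) are excluded from every fit and map to index 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import DegenerateSeriesError, InsufficientDataError
from .io import MeasurementSeries

#: minimum number of non-missing values for a negative-exponential fit
MIN_FIT_VALUES = 10


@dataclass
class GrowthCurve:
    """A fitted deterministic age-trend curve.

    ``kind`` is one of ``neg_exp`` (params a, b, d), ``linear_nonpositive``
    (params slope, intercept) or ``horizontal_mean`` (param mean).
    """

    kind: str
    params: dict[str, float]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "neg_exp":
            return p["a"] * np.exp(-p["b"] * t) + p["d"]
        if self.kind == "linear_nonpositive":
            return p["intercept"] + p["slope"] * t
        if self.kind == "horizontal_mean":
            return np.full_like(t, p["mean"])
        raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass
class IndexSeries:
    """Dimensionless ratio indices for one core, with the curve that made them."""

    series_id: str
    tree_id: str
    first_year: int
    indices: np.ndarray
    curve: GrowthCurve

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.indices) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.indices, index=self.years, name=self.series_id)


def _neg_exp(t: np.ndarray, a: float, b: float, d: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return a * np.exp(np.clip(-b * t, -700.0, 700.0)) + d


def fit_negative_exponential(series: MeasurementSeries) -> GrowthCurve | None:
    """Fit the modified negative exponential; return None on failure.

    Failure (non-convergence, a <= 0, b <= 0, or a non-positive fitted curve
    anywhere on the span) signals the caller to apply the next fallback.
    Fewer than 10 non-missing values is a usage error, not a fit failure.
    """
    values = series.values
    mask = values > 0
    if int(mask.sum()) < MIN_FIT_VALUES:
        raise InsufficientDataError(
            f"series {series.series_id}: {int(mask.sum())} non-missing values, "
            f"need >= {MIN_FIT_VALUES}"
        )
    t_all = np.arange(len(values), dtype=float)
    t, y = t_all[mask], values[mask]

    n_dec = min(10, len(y))
    first_dec = float(np.mean(y[:n_dec]))
    last_dec = float(np.mean(y[-n_dec:]))
    a0 = max(first_dec - last_dec, 1e-3 * max(first_dec, 1e-12))
    b0 = 2.0 / len(values)
    d0 = last_dec
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _neg_exp, t, y, p0=[a0, b0, d0], maxfev=10000, xtol=1e-12, ftol=1e-12
            )
    except (RuntimeError, ValueError):
        return None
    a, b, d = (float(v) for v in popt)
    scale = float(np.mean(y))
    if not np.isfinite([a, b, d]).all():
        return None
    if a <= 1e-8 * scale or b <= 1e-8:
        return None
    # an exponential that barely decays over the span is a disguised straight
    # line; let the linear fallback handle that shape instead
    if b * len(values) < 1e-3:
        return None
    curve = GrowthCurve("neg_exp", {"a": a, "b": b, "d": d})
    if np.any(curve.evaluate(t_all) <= 0):
        return None
    return curve


def _fit_linear(series: MeasurementSeries) -> GrowthCurve | None:
    values = series.values
    mask = values > 0
    t_all = np.arange(len(values), dtype=float)
    slope, intercept = np.polyfit(t_all[mask], values[mask], 1)
    if slope > 0:
        return None
    curve = GrowthCurve(
        "linear_nonpositive", {"slope": float(slope), "intercept": float(intercept)}
    )
    if np.any(curve.evaluate(t_all) <= 0):
        return None
    return curve


def select_growth_curve(series: MeasurementSeries) -> GrowthCurve:
    """Apply the deterministic fallback cascade and return the accepted curve."""
    values = series.values
    mask = values > 0
    if not mask.any():
        raise DegenerateSeriesError(f"series {series.series_id}: all values zero")
    if int(mask.sum()) >= MIN_FIT_VALUES:
        curve = fit_negative_exponential(series)
        if curve is not None:
            return curve
        curve = _fit_linear(series)
        if curve is not None:
            return curve
    return GrowthCurve("horizontal_mean", {"mean": float(values[mask].mean())})


def detrend_series(series: MeasurementSeries) -> IndexSeries:
    """Divide a series by its accepted growth curve; missing rings give index 0."""
    curve = select_growth_curve(series)
    t = np.arange(len(series.values), dtype=float)
    fitted = curve.evaluate(t)
    indices = np.where(series.values > 0, series.values / fitted, 0.0)
    return IndexSeries(
        series_id=series.series_id,
        tree_id=series.tree_id,
        first_year=series.first_year,
        indices=indices,
        curve=curve,
    )


def detrend_all(series: list[MeasurementSeries]) -> list[IndexSeries]:
    """Detrend every series; convenience wrapper used by the pipeline."""
    return [detrend_series(s) for s in series]


def curve_table(indices: list[IndexSeries]) -> pd.DataFrame:
    """Audit table of the curve chosen for each series."""
    rows = []
    for ix in indices:
        row = {"series_id": ix.series_id, "tree_id": ix.tree_id, "kind": ix.curve.kind}
        row.update(ix.curve.params)
        rows.append(row)
    return pd.DataFrame(rows)
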