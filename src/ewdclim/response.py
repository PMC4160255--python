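"""Climate-growth response: bootstrapped correlation and response functions.

The monthly predictor window runs, by default, from July of the year before
growth to September of the growth year (15 slots).  Correlation functions are
plain Pearson correlations per slot; response functions are principal-
component regression coefficients (predictors standardized, components
retained by the Kaiser eigenvalue > 1 rule, coefficients mapped back to month
space).  Significance of both comes from a paired-year bootstrap: years are
resampled with replacement, and a coefficient is flagged when its 95%
percentile interval excludes zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    AlignmentError,
    DegenerateControlError,
    InsufficientDataError,
    RankError,
)
from .io import ClimateTable

_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class MonthWindow:
    """An ordered list of (year-offset, month) slots; offset -1 = prior year."""

    slots: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= 24:
            raise InsufficientDataError("window must contain 1..24 slots")
        keys = [offset * 12 + (month - 1) for offset, month in self.slots]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise InsufficientDataError("window slots must be strictly ordered in time")
        for offset, month in self.slots:
            if offset not in (-1, 0) or not 1 <= month <= 12:
                raise InsufficientDataError(f"bad slot ({offset}, {month})")

    @classmethod
    def span(cls, start: tuple[int, int] = (-1, 7), end: tuple[int, int] = (0, 9)) -> "MonthWindow":
        """Consecutive slots from start to end inclusive (default prior-Jul..Sep)."""
        k0 = start[0] * 12 + start[1] - 1
        k1 = end[0] * 12 + end[1] - 1
        return cls([(k // 12 if k >= 0 else -1, k % 12 + 1) for k in range(k0, k1 + 1)])

    def labels(self) -> list[str]:
        return [
            ("prev_" if off == -1 else "cur_") + _MONTH_ABBR[m - 1]
            for off, m in self.slots
        ]


def default_window() -> MonthWindow:
    """Prior-year July through current September, 15 monthly slots."""
    return MonthWindow.span((-1, 7), (0, 9))


def build_month_matrix(
    climate: ClimateTable, window: MonthWindow, years: Sequence[int]
) -> pd.DataFrame:
    """One row per growth year, one column per window slot.

    Prior-year slots take values from year-1; a growth year whose prior year
    is outside the climate record raises :class:`AlignmentError`.
    """
    years = np.asarray(sorted(years), dtype=int)
    avail = set(int(y) for y in climate.years)
    cols = {}
    for (offset, month), label in zip(window.slots, window.labels()):
        src_years = years + offset
        missing = [int(y) for y in src_years if int(y) not in avail]
        if missing:
            raise AlignmentError(
                f"slot {label}: climate record lacks years {missing[:5]}"
            )
        cols[label] = climate.monthly(month).loc[src_years].to_numpy()
    return pd.DataFrame(cols, index=years)


def seasonal_predictor(
    climate: ClimateTable, months: Sequence[int], years: Sequence[int], how: str = "mean"
) -> pd.Series:
    """Seasonal mean (or sum) of current-year months, indexed by growth year."""
    years = np.asarray(sorted(years), dtype=int)
    agg = climate.seasonal_mean(months) if how == "mean" else climate.seasonal_sum(months)
    missing = sorted(set(years) - set(int(y) for y in climate.years))
    if missing:
        raise AlignmentError(f"climate record lacks years {missing[:5]}")
    return agg.loc[years]


@dataclass
class ResponseResult:
    """Per-slot coefficients with bootstrap 95% bounds and significance flags."""

    kind: str  # "correlation" | "response"
    slots: list[str]
    coef: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    significant: np.ndarray
    p: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None
    retained_components: int | None = None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "slot": self.slots,
                "coefficient": self.coef,
                "lo": self.lo,
                "hi": self.hi,
                "significant": self.significant,
            }
        )
        if self.p is not None:
            out["p"] = self.p
        return out


def _align(chron_index: pd.Series, predictors: pd.DataFrame):
    common = chron_index.index.intersection(predictors.index)
    y = chron_index.loc[common].to_numpy(dtype=float)
    X = predictors.loc[common].to_numpy(dtype=float)
    return common, y, X


def bootstrap_correlations(
    chron_index: pd.Series,
    predictors: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ResponseResult:
    """Pearson correlation per slot with paired-year bootstrap 95% bounds.

    Years are resampled with replacement keeping (index, all slots) rows
    together; bounds are the 2.5/97.5 percentiles of the bootstrap
    correlations.  A zero-variance slot is flagged and returns NaN without
    disturbing the other slots.  Deterministic given ``seed``.
    """
    if n_boot < 500:
        raise InsufficientDataError("n_boot must be >= 500")
    common, y, X = _align(chron_index, predictors)
    n, p = X.shape
    if n < 30:
        raise InsufficientDataError(f"only {n} common years, need >= 30")
    sd_x = X.std(axis=0)
    dead = sd_x == 0
    flags = [f"zero-variance slot {c}" for c, d in zip(predictors.columns, dead) if d]

    with np.errstate(invalid="ignore", divide="ignore"):
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        r = (yc @ Xc) / (np.sqrt((yc**2).sum()) * np.sqrt((Xc**2).sum(axis=0)))
    r[dead] = np.nan
    tval = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    pvals = 2 * sps.t.sf(np.abs(tval), df=n - 2)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Yb = y[idx]
    Xb = X[idx]
    Ybc = Yb - Yb.mean(axis=1, keepdims=True)
    Xbc = Xb - Xb.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.einsum("bn,bnp->bp", Ybc, Xbc)
        den = np.sqrt((Ybc**2).sum(axis=1))[:, None] * np.sqrt((Xbc**2).sum(axis=1))
        rb = num / den
    lo = np.full(p, np.nan)
    hi = np.full(p, np.nan)
    alive = ~dead
    lo[alive] = np.nanpercentile(rb[:, alive], 2.5, axis=0)
    hi[alive] = np.nanpercentile(rb[:, alive], 97.5, axis=0)
    sig = np.where(dead, False, (lo > 0) | (hi < 0))
    return ResponseResult(
        kind="correlation",
        slots=list(predictors.columns),
        coef=r,
        lo=lo,
        hi=hi,
        significant=sig,
        p=pvals,
        n_boot=n_boot,
        seed=seed,
        flags=flags,
    )


def _pcr_coefficients(y: np.ndarray, X: np.ndarray, retention: str, cum: float = 0.85):
    """PC regression coefficients in (standardized) month space."""
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if retention == "kaiser":
        keep = evals > 1.0
        if not keep.any():
            keep = np.zeros(p, dtype=bool)
            keep[0] = True
    else:  # cumulative variance rule
        frac = np.cumsum(evals) / evals.sum()
        k = int(np.searchsorted(frac, cum)) + 1
        keep = np.zeros(p, dtype=bool)
        keep[:k] = True
    V = evecs[:, keep]
    k = V.shape[1]
    if n <= k + 1:
        raise RankError(f"{n} years cannot support {k} retained components")
    scores = Z @ V
    yc = y - y.mean()
    coef_scores = np.linalg.lstsq(scores, yc, rcond=None)[0]
    return V @ coef_scores, k


def response_function(
    chron_index: pd.Series,
    predictors: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    retention: str = "kaiser",
) -> ResponseResult:
    """Principal-component response function with bootstrap significance.

    Predictors are standardized internally, so coefficients are per standard
    deviation of each month's climate and invariant to affine rescaling of
    any column.  The PCA (including component retention) is recomputed in
    every bootstrap replicate.
    """
    if n_boot < 500:
        raise InsufficientDataError("n_boot must be >= 500")
    common, y, X = _align(chron_index, predictors)
    n, p = X.shape
    if n < 30:
        raise InsufficientDataError(f"only {n} common years, need >= 30")
    coef, k = _pcr_coefficients(y, X, retention)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot[b], _ = _pcr_coefficients(y[idx], X[idx], retention)
        except RankError:
            boot[b] = np.nan
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    sig = (lo > 0) | (hi < 0)
    return ResponseResult(
        kind="response",
        slots=list(predictors.columns),
        coef=coef,
        lo=lo,
        hi=hi,
        significant=sig,
        n_boot=n_boot,
        seed=seed,
        retained_components=k,
    )


def partial_correlation(x, y, z) -> tuple[float, float]:
    """First-order partial correlation r_xy.z with its two-sided p-value.

    Uses the closed form (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2)) and a
    t distribution with n-3 degrees of freedom.  Inputs may be pandas Series
    (aligned on their index) or equal-length arrays.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series) and isinstance(z, pd.Series):
        common = x.index.intersection(y.index).intersection(z.index)
        x, y, z = (v.loc[common].to_numpy(dtype=float) for v in (x, y, z))
    else:
        x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    n = len(x)
    if n < 10:
        raise InsufficientDataError(f"only {n} common years, need >= 10")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise DegenerateControlError(f"{name} is constant")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise DegenerateControlError("control variable collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    t = r * np.sqrt(df / max(1 - r**2, 1e-300))
    p = float(2 * sps.t.sf(abs(t), df=df))
    return r, p
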