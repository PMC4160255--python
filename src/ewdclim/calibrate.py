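"""Transfer-function calibration and the dendroclimatic verification battery.

The transfer function is a simple linear regression of the climate target
(here May-June maximum temperature, degC) on the site chronology index.  Its
fidelity is judged with leave-one-out cross-validation and the classical
verification statistics:

* RE, reduction of error: 1 - SSE/SSM against the calibration-mean benchmark
  (RE > 0 indicates skill over climatology);
* sign test: counts of years where predicted and observed departures from
  the calibration mean agree/disagree in strict sign;
* PMT, product-means t: contrasts mean magnitudes of agreeing (positive
  product) and disagreeing (negative product) departure products;
* r_cv: Pearson correlation between observations and the leave-one-out
  predictions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSplitError,
    DegenerateVarianceError,
    InsufficientDataError,
    SingularFitError,
    UndefinedDenominatorError,
)


def f_from_r2(r2: float, n: int) -> float:
    """Regression F statistic implied by r^2 in a simple regression on n years."""
    return r2 * (n - 2) / (1.0 - r2)


@dataclass
class TransferModel:
    """Linear calibration index -> degC with its calibration statistics."""

    intercept: float
    slope: float
    calibration_years: np.ndarray
    r: float
    r2: float
    F: float
    se: float
    n: int

    def predict(self, index) -> np.ndarray | pd.Series:
        if isinstance(index, pd.Series):
            return self.intercept + self.slope * index
        return self.intercept + self.slope * np.asarray(index, dtype=float)

    @property
    def slope_se(self) -> float:
        # from t = slope/se(slope), t^2 = F
        return abs(self.slope) / np.sqrt(self.F) if self.F > 0 else np.inf


@dataclass
class VerificationStats:
    """Leave-one-out verification battery (Table-1-style roles)."""

    re: float
    sign_plus: int
    sign_minus: int
    sign_p: float
    pmt: float
    pmt_p: float
    r_cv: float
    ce: float  # coefficient of efficiency; equals RE under LOO with one period
    pmt_flag: str = ""  # "all-agreement" when the negative-product group is empty


def _align_xy(index, target):
    if isinstance(index, pd.Series) and isinstance(target, pd.Series):
        common = index.index.intersection(target.index)
        x = index.loc[common].to_numpy(dtype=float)
        y = target.loc[common].to_numpy(dtype=float)
        years = np.asarray(common, dtype=int)
    else:
        x = np.asarray(index, dtype=float)
        y = np.asarray(target, dtype=float)
        if len(x) != len(y):
            raise InsufficientDataError("index and target lengths differ")
        years = np.arange(len(x))
    return x, y, years


def fit_transfer(index, target) -> TransferModel:
    """OLS fit of target (degC) on chronology index over common years."""
    x, y, years = _align_xy(index, target)
    n = len(x)
    if n < 20:
        raise InsufficientDataError(f"only {n} common years, need >= 20")
    if np.std(x) == 0:
        raise SingularFitError("chronology index is constant over calibration")
    res = sps.linregress(x, y)
    r = float(res.rvalue)
    r2 = r * r
    resid = y - (res.intercept + res.slope * x)
    se = float(np.sqrt((resid**2).sum() / (n - 2)))
    return TransferModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        calibration_years=years,
        r=r,
        r2=r2,
        F=f_from_r2(r2, n),
        se=se,
        n=n,
    )


def loocv_predict(index, target, min_years: int = 10) -> pd.Series:
    """Out-of-sample prediction of each year from a fit on the other n-1.

    Uses the exact closed form for OLS leave-one-out residuals
    (e_i / (1 - h_ii)); identical to refitting n times, deterministic.
    ``min_years`` guards against meaninglessly short records; lower it
    explicitly for didactic hand cases.
    """
    x, y, years = _align_xy(index, target)
    n = len(x)
    if n < max(min_years, 3):
        raise InsufficientDataError(f"only {n} years, need >= {max(min_years, 3)}")
    if np.std(x) == 0:
        raise SingularFitError("chronology index is constant")
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * xm
    fitted = intercept + slope * x
    h = 1.0 / n + (x - xm) ** 2 / sxx
    e_loo = (y - fitted) / (1.0 - h)
    return pd.Series(y - e_loo, index=years, name="loo_prediction")


def reduction_of_error(observed, predicted, calibration_mean: float) -> float:
    """RE = 1 - sum(o-p)^2 / sum(o - calibration_mean)^2."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(o) != len(p) or len(o) < 2:
        raise InsufficientDataError("observed/predicted need equal lengths >= 2")
    ssm = ((o - calibration_mean) ** 2).sum()
    if ssm == 0:
        raise UndefinedDenominatorError("observed values all equal the calibration mean")
    return float(1.0 - ((o - p) ** 2).sum() / ssm)


def sign_test(observed, predicted, calibration_mean: float) -> tuple[int, int]:
    """Counts of same-sign / opposite-sign departures from the calibration mean.

    Years where either departure is exactly zero enter neither count.
    """
    o = np.asarray(observed, dtype=float) - calibration_mean
    p = np.asarray(predicted, dtype=float) - calibration_mean
    if len(o) != len(p):
        raise InsufficientDataError("observed/predicted lengths differ")
    nonzero = (o != 0) & (p != 0)
    agree = int(np.sum((np.sign(o) == np.sign(p)) & nonzero))
    disagree = int(np.sum((np.sign(o) != np.sign(p)) & nonzero))
    return agree, disagree


def sign_test_p(plus: int, minus: int) -> float:
    """Two-sided binomial p for the sign counts against chance (p=1/2)."""
    n = plus + minus
    if n == 0:
        return 1.0
    return float(sps.binomtest(plus, n, 0.5).pvalue)


@dataclass
class PMTResult:
    t: float
    df: float
    p: float
    n_plus: int
    n_minus: int
    m_plus: float
    m_minus: float


def product_means_test(observed, predicted, calibration_mean: float) -> PMTResult:
    """Fritts' product-means t on departures from the calibration mean.

    Products q_i = (o_i - mean)(p_i - mean) are split by sign; t contrasts
    the mean positive product with the mean magnitude of negative products,
    with a Welch-style standard error and degrees of freedom.
    """
    o = np.asarray(observed, dtype=float) - calibration_mean
    p = np.asarray(predicted, dtype=float) - calibration_mean
    q = o * p
    pos = q[q > 0]
    neg = -q[q < 0]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateSplitError(
            "one product group is empty (all-agreement or all-disagreement)"
        )
    m_plus, m_minus = float(pos.mean()), float(neg.mean())
    s_plus = float(pos.std(ddof=1)) if pos.size > 1 else 0.0
    s_minus = float(neg.std(ddof=1)) if neg.size > 1 else 0.0
    var = s_plus**2 / pos.size + s_minus**2 / neg.size
    if var == 0:
        raise DegenerateVarianceError("zero variance in both product groups")
    t = (m_plus - m_minus) / np.sqrt(var)
    # Welch-Satterthwaite df; guard single-member groups
    num = var**2
    den = 0.0
    if pos.size > 1:
        den += (s_plus**2 / pos.size) ** 2 / (pos.size - 1)
    if neg.size > 1:
        den += (s_minus**2 / neg.size) ** 2 / (neg.size - 1)
    df = num / den if den > 0 else float(pos.size + neg.size - 2)
    pval = float(2 * sps.t.sf(abs(t), df=df))
    return PMTResult(float(t), float(df), pval, int(pos.size), int(neg.size),
                     m_plus, m_minus)


@dataclass
class VerificationReport:
    model: TransferModel
    stats: VerificationStats
    loo_predictions: pd.Series

    def to_frame(self) -> pd.DataFrame:
        m, s = self.model, self.stats
        return pd.DataFrame(
            [
                {
                    "R": m.r,
                    "r2": m.r2,
                    "F": m.F,
                    "sign_plus": s.sign_plus,
                    "sign_minus": s.sign_minus,
                    "RE": s.re,
                    "PMT": s.pmt,
                    "r_cv": s.r_cv,
                    "CE": s.ce,
                    "n": m.n,
                }
            ]
        )

    def to_text(self) -> str:
        m, s = self.model, self.stats
        return (
            "Calibration / leave-one-out verification\n"
            f"  n years        : {m.n}\n"
            f"  R              : {m.r:.3f}\n"
            f"  r^2            : {m.r2:.3f}\n"
            f"  F              : {m.F:.3f}\n"
            f"  sign test      : {s.sign_plus}+/{s.sign_minus}-  (p={s.sign_p:.4g})\n"
            f"  RE             : {s.re:.3f}\n"
            f"  PMT            : {s.pmt:.3f}  (p={s.pmt_p:.4g})\n"
            f"  r (cross-val)  : {s.r_cv:.3f}\n"
        )


def verify(index, target) -> VerificationReport:
    """Full calibration + leave-one-out verification in one deterministic call."""
    model = fit_transfer(index, target)
    loo = loocv_predict(index, target)
    x, y, years = _align_xy(index, target)
    cal_mean = float(y.mean())
    pred = loo.to_numpy()
    re = reduction_of_error(y, pred, cal_mean)
    plus, minus = sign_test(y, pred, cal_mean)
    try:
        pmt_res = product_means_test(y, pred, cal_mean)
        pmt_t, pmt_p, pmt_flag = pmt_res.t, pmt_res.p, ""
    except DegenerateSplitError:
        # every departure product has the same sign: perfect (dis)agreement,
        # reported as such rather than as a failure of skill
        pmt_t, pmt_p, pmt_flag = float("nan"), float("nan"), "all-agreement"
    r_cv = float(np.corrcoef(y, pred)[0, 1])
    # CE uses the verification-period mean; identical to the calibration mean
    # under single-period leave-one-out, so CE == RE here by construction.
    ce = reduction_of_error(y, pred, float(y.mean()))
    stats = VerificationStats(
        re=re,
        sign_plus=plus,
        sign_minus=minus,
        sign_p=sign_test_p(plus, minus),
        pmt=pmt_t,
        pmt_p=pmt_p,
        r_cv=r_cv,
        ce=ce,
        pmt_flag=pmt_flag,
    )
    return VerificationReport(model=model, stats=stats, loo_predictions=loo)
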