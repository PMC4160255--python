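"""Temperature reconstruction: transfer application, event classification,
decadal low-pass filtering and warm/cold period segmentation.

The reconstruction applies the calibrated transfer function to the reliable
span of the chronology.  Years are classified against the full-span mean:
warm above mean + 1 sigma, cold below mean - 1 sigma, normal otherwise.
Decadal structure is exposed with a zero-phase low-pass filter (second-order
Butterworth at 0.1 cycles/yr applied forward-backward, odd-reflection
padding) and maximal runs of the filtered curve above/below the mean of at
least ``min_len`` years (default 5) are reported as warm/cold periods.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .calibrate import TransferModel
from .chronology import Chronology
from .errors import EmptyReliablePeriodError, InsufficientDataError, NyquistError


@dataclass
class Period:
    start: int
    end: int
    phase: str  # "warm" | "cold" | "unclassified"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Reconstruction:
    """Annual reconstructed values with summary and derived products."""

    years: np.ndarray
    values: np.ndarray
    mean: float
    sigma: float
    events: np.ndarray | None = None
    event_percentages: dict | None = None
    filtered: np.ndarray | None = None
    periods: list[Period] = field(default_factory=list)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name="reconstruction")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"year": self.years, "value": self.values})
        if self.filtered is not None:
            out["filtered_value"] = self.filtered
        if self.events is not None:
            out["event_label"] = self.events
        return out


def reconstruct(model: TransferModel, chron: Chronology) -> Reconstruction:
    """Apply the transfer function over the chronology's reliable span."""
    if len(chron.years) == 0:
        raise EmptyReliablePeriodError("chronology has no reliable years")
    values = model.intercept + model.slope * chron.index
    return Reconstruction(
        years=chron.years.copy(),
        values=values,
        mean=float(values.mean()),
        sigma=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )


def classify_events(recon: Reconstruction) -> Reconstruction:
    """Label each year warm/cold/normal against mean +/- 1 sigma.

    Percentages are rounded to whole percent, with the normal share reported
    as the complement 100 - warm% - cold% so the three always sum to 100.
    A zero-sigma reconstruction degenerates to all-normal (warning semantics,
    not an error).
    """
    v, m, s = recon.values, recon.mean, recon.sigma
    if s == 0:
        events = np.full(len(v), "normal", dtype=object)
        pct = {"warm": 0, "cold": 0, "normal": 100}
    else:
        events = np.where(v > m + s, "warm", np.where(v < m - s, "cold", "normal"))
        n = len(v)
        warm_pct = int(round(100.0 * np.sum(events == "warm") / n))
        cold_pct = int(round(100.0 * np.sum(events == "cold") / n))
        pct = {"warm": warm_pct, "cold": cold_pct, "normal": 100 - warm_pct - cold_pct}
    recon.events = events
    recon.event_percentages = pct
    return recon


def lowpass_filter(values, cutoff_years: float = 10.0) -> np.ndarray:
    """Zero-phase low-pass of an annual series.

    Second-order Butterworth designed at 1/cutoff_years cycles per year and
    applied forward-backward (no phase shift, so filtered extrema keep their
    calendar dates).  Edges are handled by odd-reflection padding, which
    passes straight lines through unchanged.
    """
    x = np.asarray(values, dtype=float)
    if cutoff_years <= 2:
        raise NyquistError("cutoff must exceed 2 years for annual data")
    if len(x) < 3 * cutoff_years:
        raise InsufficientDataError(
            f"series of {len(x)} years too short for a {cutoff_years}-yr cutoff"
        )
    b, a = butter(2, (1.0 / cutoff_years) / 0.5)
    padlen = min(len(x) - 1, int(3 * cutoff_years))
    return filtfilt(b, a, x, padtype="odd", padlen=padlen)


def segment_periods(
    filtered: pd.Series, reference_mean: float, min_len: int = 5
) -> list[Period]:
    """Maximal runs of the filtered curve strictly above/below the mean.

    Runs of at least ``min_len`` years become warm/cold periods; shorter
    runs (and years exactly on the mean) are emitted as ``unclassified`` so
    that every year appears exactly once.
    """
    years = np.asarray(filtered.index, dtype=int)
    v = filtered.to_numpy(dtype=float)
    phase = np.where(v > reference_mean, "warm",
                     np.where(v < reference_mean, "cold", "unclassified"))
    periods: list[Period] = []
    start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or phase[i] != phase[start]:
            ph = phase[start]
            if ph != "unclassified" and (i - start) < min_len:
                ph = "unclassified"
            periods.append(Period(int(years[start]), int(years[i - 1]), ph))
            start = i
    # merge adjacent unclassified stretches produced by demotion
    merged: list[Period] = []
    for p in periods:
        if merged and p.phase == "unclassified" and merged[-1].phase == "unclassified":
            merged[-1] = Period(merged[-1].start, p.end, "unclassified")
        else:
            merged.append(p)
    return merged


def periods_frame(periods: list[Period]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"start": p.start, "end": p.end, "phase": p.phase, "length": p.length}
            for p in periods
        ]
    )


def summarize(
    model: TransferModel,
    chron: Chronology,
    cutoff_years: float = 10.0,
    min_len: int = 5,
) -> Reconstruction:
    """reconstruct -> classify -> filter -> segment, in one call."""
    recon = classify_events(reconstruct(model, chron))
    recon.filtered = lowpass_filter(recon.values, cutoff_years)
    recon.periods = segment_periods(
        pd.Series(recon.filtered, index=recon.years), recon.mean, min_len
    )
    return recon
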