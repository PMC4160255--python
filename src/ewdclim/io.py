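"""Reading and writing tree-ring measurement files and station climate tables.

Two in-memory containers defined here are consumed by every downstream module:

* :class:`MeasurementSeries` — one core's dated annual values (ring width in
  file units, or wood density in g/cm3).  The year axis is contiguous; a dated
  missing ring is encoded as the value 0 and is retained.
* :class:`ClimateTable`  — monthly station values (year x 12 months) for one
  variable, wrapped around a pandas DataFrame.

Supported file formats:

* Tucson/RWL decadal text (read + write) for ring widths.  Values followed by
  the stop marker ``999`` are in 0.01 mm, by ``-9999`` in 0.001 mm (ITRDB
  convention).  RWL carries no density convention, so density series travel
  through the long-form CSV instead.
* Long-form measurement CSV with columns ``series_id,tree_id,year,value``
  (canonical interchange for density data).
* Wide climate CSV with columns ``year,m1..m12``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConflictError,
    GapError,
    IdentifierError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: stop markers and the value units they imply (ITRDB dialects)
_STOP_UNITS = {999: "0.01 mm", -9999: "0.001 mm"}

MONTH_COLUMNS = [f"m{i}" for i in range(1, 13)]

TEMPERATURE_BOUNDS = (-90.0, 60.0)


@dataclass
class MeasurementSeries:
    """A single dated core measurement series with a contiguous year axis."""

    series_id: str
    tree_id: str
    first_year: int
    values: np.ndarray
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise SchemaError(f"series {self.series_id}: needs >= 1 value")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"series {self.series_id}: non-finite values")
        if np.any(self.values < 0):
            raise SchemaError(f"series {self.series_id}: negative values")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.series_id)


@dataclass
class ClimateTable:
    """Monthly station climate values by calendar year for one variable."""

    variable: str
    units: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != MONTH_COLUMNS:
            raise SchemaError(
                f"climate table needs columns {MONTH_COLUMNS}, got {list(df.columns)}"
            )
        years = df.index.to_numpy()
        if len(years) == 0:
            raise SchemaError("climate table is empty")
        missing = sorted(set(range(years.min(), years.max() + 1)) - set(years))
        if missing:
            raise GapError(f"climate years not contiguous; missing {missing}")
        if not np.all(np.diff(years) > 0):
            raise SchemaError("climate years must be strictly increasing")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise SchemaError("climate table contains missing cells")
        if self.variable == "precip":
            if (vals < 0).any():
                raise SchemaError("precipitation values must be >= 0")
        elif self.variable in ("tmax", "tmean", "tmin"):
            lo, hi = TEMPERATURE_BOUNDS
            if (vals <= lo).any() or (vals >= hi).any():
                raise SchemaError(f"temperatures outside physical bounds {TEMPERATURE_BOUNDS}")
        else:
            raise SchemaError(f"unknown climate variable {self.variable!r}")

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def monthly(self, month: int) -> pd.Series:
        """Values of one calendar month (1-12) indexed by year."""
        return self.data[f"m{month}"]

    def seasonal_mean(self, months: Sequence[int]) -> pd.Series:
        """Per-year mean over the given calendar months (temperature-style)."""
        return self.data[[f"m{m}" for m in months]].mean(axis=1)

    def seasonal_sum(self, months: Sequence[int]) -> pd.Series:
        """Per-year total over the given calendar months (precipitation-style)."""
        return self.data[[f"m{m}" for m in months]].sum(axis=1)


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

def read_rwl(path: str | Path) -> list[MeasurementSeries]:
    """Parse a Tucson decadal (.rwl) file into measurement series.

    Stop markers (999 / -9999) are consumed, not stored, and fix the units
    dialect.  Header lines (first 8 chars not followed by a numeric year) are
    skipped.  The tree identifier defaults to the series identifier because
    the bare format carries no grouping metadata.
    """
    path = Path(path)
    open_series: dict[str, dict] = {}
    finished: list[MeasurementSeries] = []
    closed_ids: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            sid = line[:8].strip()
            if not sid:
                raise ParseError(f"{path}:{lineno}: missing series id")
            tokens = line[8:].split()
            if not tokens:
                raise ParseError(f"{path}:{lineno}: no decade year")
            try:
                year = int(tokens[0])
            except ValueError:
                # Tucson header lines (site metadata) have non-numeric year field
                logger.debug("skipping header-like line %d of %s", lineno, path)
                continue
            if sid in closed_ids:
                raise ConflictError(
                    f"{path}:{lineno}: series {sid} re-opened after its stop marker"
                )
            state = open_series.get(sid)
            if state is None:
                state = {"first_year": year, "values": [], "next_year": year}
                open_series[sid] = state
            else:
                if year < state["next_year"]:
                    raise ConflictError(
                        f"{path}:{lineno}: duplicate year {year} for series {sid}"
                    )
                if year != state["next_year"]:
                    raise ParseError(
                        f"{path}:{lineno}: series {sid} jumps from "
                        f"{state['next_year']} to {year}"
                    )
            stopped = False
            for tok in tokens[1:]:
                try:
                    val = float(tok)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: bad value {tok!r}") from None
                ival = int(val) if val == int(val) else None
                if ival in _STOP_UNITS:
                    units = _STOP_UNITS[ival]
                    finished.append(
                        MeasurementSeries(
                            series_id=sid,
                            tree_id=sid,
                            first_year=state["first_year"],
                            values=np.array(state["values"], dtype=float),
                            units=units,
                        )
                    )
                    closed_ids.add(sid)
                    del open_series[sid]
                    stopped = True
                    break
                state["values"].append(val)
                state["next_year"] += 1
            if stopped:
                continue

    for sid, state in open_series.items():
        if state["values"]:
            raise ParseError(f"{path}: series {sid} has no stop marker")
    if not finished:
        logger.warning("no series found in %s", path)
    # preserve file order
    return finished


def write_rwl(series: Iterable[MeasurementSeries], path: str | Path) -> None:
    """Write series in Tucson decadal layout (stop marker 999, 0.01 mm dialect).

    Values are written as integers; the format has no fractional field.
    """
    path = Path(path)
    lines: list[str] = []
    for s in series:
        if len(s.series_id) > 8:
            raise IdentifierError(f"series id {s.series_id!r} longer than 8 characters")
        year = s.first_year
        values = list(np.rint(s.values).astype(int)) + [999]
        pos = 0
        while pos < len(values):
            decade_end = (year // 10) * 10 + 9
            room = decade_end - year + 1
            chunk = values[pos : pos + room]
            row = f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6d}" for v in chunk)
            lines.append(row)
            pos += len(chunk)
            year += len(chunk)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_measurement_csv(path: str | Path, units: str = "g/cm3") -> list[MeasurementSeries]:
    """Read long-form measurements (series_id,tree_id,year,value)."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["series_id", "tree_id", "year", "value"]
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: list[MeasurementSeries] = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(np.unique(years)) != len(years):
            raise ConflictError(f"{path}: duplicate year in series {sid}")
        if np.any(np.diff(years) != 1):
            raise GapError(f"{path}: series {sid} has a year gap")
        tree_ids = grp["tree_id"].unique()
        if len(tree_ids) != 1:
            raise SchemaError(f"{path}: series {sid} maps to several trees")
        out.append(
            MeasurementSeries(
                series_id=str(sid),
                tree_id=str(tree_ids[0]),
                first_year=int(years[0]),
                values=grp["value"].to_numpy(dtype=float),
                units=units,
            )
        )
    if not out:
        logger.warning("no series found in %s", path)
    return out


def write_measurement_csv(series: Iterable[MeasurementSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for year, value in zip(s.years, s.values):
            rows.append((s.series_id, s.tree_id, int(year), float(value)))
    pd.DataFrame(rows, columns=["series_id", "tree_id", "year", "value"]).to_csv(
        path, index=False
    )


_DEFAULT_UNITS = {"tmax": "degC", "tmean": "degC", "tmin": "degC", "precip": "mm"}


def read_climate_csv(path: str | Path, variable: str, units: str | None = None) -> ClimateTable:
    """Read a wide climate CSV (year,m1..m12) into a :class:`ClimateTable`."""
    if variable not in _DEFAULT_UNITS:
        raise SchemaError(f"unknown climate variable {variable!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["year"] + MONTH_COLUMNS
    if list(df.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    df = df.set_index(df["year"].astype(int)).drop(columns="year")
    df.index.name = "year"
    return ClimateTable(variable=variable, units=units or _DEFAULT_UNITS[variable], data=df)


def write_climate_csv(table: ClimateTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "year", out.index)
    out.to_csv(path, index=False)
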