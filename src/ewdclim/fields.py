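"""Generic gridded-field diagnostics: detrended spatial correlation maps and
extreme-decile composite anomalies.

These engines take any annual scalar field (temperature, cloud cover, SST, a
wind component) on a year x lat x lon grid.  Vector fields are handled as two
scalar fields composited independently.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import OverlapError, SchemaError, SelectionError


@dataclass
class GriddedField:
    """An annual gridded scalar variable; missing cells are NaN, never zero."""

    years: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray  # (year, lat, lon)
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.years), len(self.lat), len(self.lon)):
            raise SchemaError("field shape does not match its axes")
        if len(np.unique(self.years)) != len(self.years):
            raise SchemaError("duplicated year in field")
        for name, ax in (("lat", self.lat), ("lon", self.lon)):
            d = np.diff(ax)
            if len(d) and not (np.all(d > 0) or np.all(d < 0)):
                raise SchemaError(f"{name} axis must be strictly monotone")

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"year": self.years, "lat": self.lat, "lon": self.lon},
            dims=("year", "lat", "lon"),
            attrs={"units": self.units},
        )

    @classmethod
    def from_dataarray(cls, da: xr.DataArray) -> "GriddedField":
        da = da.transpose("year", "lat", "lon")
        return cls(
            years=da["year"].to_numpy(),
            lat=da["lat"].to_numpy(),
            lon=da["lon"].to_numpy(),
            values=da.to_numpy(),
            units=str(da.attrs.get("units", "")),
        )

    @classmethod
    def from_netcdf(cls, path, var: str) -> "GriddedField":
        with xr.open_dataset(path) as ds:
            return cls.from_dataarray(ds[var].load())

    def to_netcdf(self, path, var: str = "field") -> None:
        self.to_dataarray().to_dataset(name=var).to_netcdf(path)


def _detrend_against_year(y: np.ndarray, years: np.ndarray) -> np.ndarray:
    t = years - years.mean()
    slope = (t * (y - y.mean())).sum() / (t**2).sum()
    return y - y.mean() - slope * t


def detrended_spatial_correlation(
    series: pd.Series, field: GriddedField, min_years: int = 20
) -> np.ndarray:
    """Per-cell Pearson correlation after removing linear-in-time trends.

    Both the series and each grid cell are detrended by OLS against the
    calendar year over their common years; cells with fewer than
    ``min_years`` common years are NaN-masked.
    """
    s_years = np.asarray(series.index, dtype=int)
    common = np.intersect1d(s_years, field.years)
    out = np.full((len(field.lat), len(field.lon)), np.nan)
    if len(common) == 0:
        raise OverlapError("series and field share no years")
    f_pos = {int(y): i for i, y in enumerate(field.years)}
    f_idx = np.array([f_pos[int(y)] for y in common])
    s_all = series.loc[common].to_numpy(dtype=float)
    any_cell = False
    for i in range(len(field.lat)):
        for j in range(len(field.lon)):
            cell = field.values[f_idx, i, j]
            ok = np.isfinite(cell) & np.isfinite(s_all)
            if ok.sum() < min_years:
                continue
            yy = common[ok].astype(float)
            a = _detrend_against_year(s_all[ok], yy)
            b = _detrend_against_year(cell[ok], yy)
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            out[i, j] = float((a * b).mean() / (sa * sb))
            any_cell = True
    if not any_cell:
        raise OverlapError(f"no cell shares >= {min_years} years with the series")
    return out


@dataclass
class CompositeResult:
    high: np.ndarray  # (lat, lon) mean anomaly over the k highest years
    low: np.ndarray
    high_years: list[int]
    low_years: list[int]
    base_mean: np.ndarray
    k: int


def decile_composite(
    series: pd.Series,
    field: GriddedField,
    k: int | str = "decile",
    base_period: tuple[int, int] | None = None,
) -> CompositeResult:
    """Composite field anomalies for the k highest and k lowest series years.

    ``k="decile"`` selects round(n/10) years (round half up).  Anomalies are
    relative to the base-period mean (default: all common years).  Ties in
    the series are broken by earlier year first.
    """
    s_years = np.asarray(series.index, dtype=int)
    common = np.intersect1d(s_years, field.years)
    n = len(common)
    if n == 0:
        raise OverlapError("series and field share no years")
    if k == "decile":
        k_int = int(np.floor(n / 10 + 0.5))
    else:
        k_int = int(k)
    if k_int < 1 or k_int > n // 2:
        raise SelectionError(f"k={k_int} outside 1..{n // 2} for n={n}")
    vals = series.loc[common].to_numpy(dtype=float)
    # stable tie-break: among equal values, earlier year first
    order_hi = np.lexsort((common, -vals))
    order_lo = np.lexsort((common, vals))
    high_years = sorted(int(common[i]) for i in order_hi[:k_int])
    low_years = sorted(int(common[i]) for i in order_lo[:k_int])

    f_pos = {int(y): i for i, y in enumerate(field.years)}
    if base_period is None:
        base_idx = [f_pos[int(y)] for y in common]
    else:
        b0, b1 = base_period
        base_years = [int(y) for y in field.years if b0 <= y <= b1]
        if not base_years:
            raise OverlapError(f"field has no years in base period {base_period}")
        base_idx = [f_pos[y] for y in base_years]
    base_mean = np.nanmean(field.values[base_idx], axis=0)
    hi_idx = [f_pos[y] for y in high_years]
    lo_idx = [f_pos[y] for y in low_years]
    high = np.nanmean(field.values[hi_idx], axis=0) - base_mean
    low = np.nanmean(field.values[lo_idx], axis=0) - base_mean
    return CompositeResult(high, low, high_years, low_years, base_mean, k_int)


def correlation_map_to_frame(corr: np.ndarray, field: GriddedField) -> pd.DataFrame:
    """Tidy CSV-ready export (lat, lon, r) of a correlation map."""
    rows = []
    for i, la in enumerate(field.lat):
        for j, lo in enumerate(field.lon):
            rows.append({"lat": la, "lon": lo, "r": corr[i, j]})
    return pd.DataFrame(rows)
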