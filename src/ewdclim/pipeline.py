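"""End-to-end orchestration: measurements + climate -> chronology -> response
-> calibration/verification -> reconstruction -> reports.

`run_full_analysis` drives the whole study from a :class:`RunConfig` (YAML-
serializable); every numeric artifact is written as CSV next to a resolved
copy of the configuration and a run log, so a run directory is self-
describing and reruns are byte-identical given the same config (the
bootstrap is seeded).  The in-memory core `run_in_memory` is the library
surface used by tests and the acceptance script.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibrate as cal
from . import reconstruct as rec
from .chronology import Chronology, build_chronology, truncate_reliable
from .detrend import curve_table, detrend_all
from .errors import EwdClimError, StageError
from .io import (
    ClimateTable,
    MeasurementSeries,
    read_climate_csv,
    read_measurement_csv,
    read_rwl,
)
from .response import (
    MonthWindow,
    bootstrap_correlations,
    build_month_matrix,
    response_function,
    seasonal_predictor,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one analysis run."""

    measurements: str = ""
    tmax: str = ""
    precip: str = ""
    outdir: str = "ewdclim_run"
    # chronology reliability
    eps_window: int = 30
    eps_step: int = 15
    eps_threshold: float = 0.80
    override_eps: float = 0.75
    override_trees: int = 4
    min_trees: int = 4
    min_cores: int = 6
    # monthly response window (year offset, month), inclusive endpoints
    window_start: tuple[int, int] = (-1, 7)
    window_end: tuple[int, int] = (0, 9)
    # calibration target: seasonal mean of these months of tmax
    calib_months: tuple[int, ...] = (5, 6)
    calibration_span: tuple[int, int] | None = None
    # bootstrap
    n_boot: int = 1000
    seed: int = 0
    # reconstruction
    filter_cutoff: float = 10.0
    min_period_len: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("window_start", "window_end", "calib_months"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        if cfg.calibration_span is not None:
            cfg.calibration_span = tuple(cfg.calibration_span)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        for key, value in payload.items():
            if isinstance(value, tuple):
                payload[key] = list(value)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class RunResult:
    chronology: Chronology
    indices: list
    correlations: dict[str, object] = field(default_factory=dict)
    responses: dict[str, object] = field(default_factory=dict)
    report: cal.VerificationReport | None = None
    reconstruction: rec.Reconstruction | None = None


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except EwdClimError as exc:
                raise StageError(name, exc) from exc

        return inner

    return wrap


def load_measurements(path: str | Path) -> list[MeasurementSeries]:
    path = Path(path)
    if path.suffix.lower() == ".rwl":
        return read_rwl(path)
    return read_measurement_csv(path)


def run_in_memory(
    measurements: list[MeasurementSeries],
    climate: dict[str, ClimateTable],
    config: RunConfig,
) -> RunResult:
    """Run detrending through reconstruction on in-memory inputs."""
    indices = _stage("detrending")(detrend_all)(measurements)
    n_fallback = sum(ix.curve.kind != "neg_exp" for ix in indices)
    if n_fallback:
        logger.info("%d of %d series used a fallback growth curve", n_fallback, len(indices))

    def _chron():
        chron = build_chronology(indices, window=config.eps_window, step=config.eps_step)
        return truncate_reliable(
            chron,
            eps_threshold=config.eps_threshold,
            override_eps=config.override_eps,
            override_trees=config.override_trees,
            min_trees=config.min_trees,
            min_cores=config.min_cores,
        )

    chron = _stage("chronology")(_chron)()
    logger.info("chronology reliable from %d", chron.reliable_from)
    result = RunResult(chronology=chron, indices=indices)

    tmax = climate["tmax"]
    chron_series = chron.series()
    window = MonthWindow.span(config.window_start, config.window_end)
    cal_years = [
        int(y)
        for y in chron_series.index
        if int(y) - 1 in set(int(v) for v in tmax.years) and int(y) in set(int(v) for v in tmax.years)
    ]
    if config.calibration_span is not None:
        y0, y1 = config.calibration_span
        cal_years = [y for y in cal_years if y0 <= y <= y1]

    @_stage("climate_response")
    def _respond():
        for name, table in climate.items():
            if name not in ("tmax", "precip"):
                continue
            X = build_month_matrix(table, window, cal_years)
            result.correlations[name] = bootstrap_correlations(
                chron_series, X, n_boot=config.n_boot, seed=config.seed
            )
            result.responses[name] = response_function(
                chron_series, X, n_boot=config.n_boot, seed=config.seed
            )

    _respond()

    @_stage("calibration")
    def _calibrate():
        target = seasonal_predictor(tmax, list(config.calib_months), cal_years)
        return cal.verify(chron_series, target)

    result.report = _calibrate()

    @_stage("reconstruction")
    def _reconstruct():
        return rec.summarize(
            result.report.model,
            chron,
            cutoff_years=config.filter_cutoff,
            min_len=config.min_period_len,
        )

    result.reconstruction = _reconstruct()
    return result


def run_full_analysis(config: RunConfig) -> RunResult:
    """File-to-file run: load inputs, analyse, write the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ewdclim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        measurements = _stage("io")(load_measurements)(config.measurements)
        climate = {"tmax": _stage("io")(read_climate_csv)(config.tmax, "tmax")}
        if config.precip:
            climate["precip"] = _stage("io")(read_climate_csv)(config.precip, "precip")
        result = run_in_memory(measurements, climate, config)
        _write_outputs(result, config, outdir)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_outputs(result: RunResult, config: RunConfig, outdir: Path) -> None:
    config.to_yaml(outdir / "resolved_config.yaml")
    result.chronology.to_frame().to_csv(outdir / "chronology.csv", index=False)
    (outdir / "chronology.crn.txt").write_text(result.chronology.to_crn_text())
    curve_table(result.indices).to_csv(outdir / "growth_curves.csv", index=False)
    trail = pd.DataFrame(result.chronology.decision_trail)
    trail.to_csv(outdir / "eps_windows.csv", index=False)
    for name, res in result.correlations.items():
        res.to_frame().to_csv(outdir / f"correlation_{name}.csv", index=False)
    for name, res in result.responses.items():
        res.to_frame().to_csv(outdir / f"response_{name}.csv", index=False)
    result.report.to_frame().to_csv(outdir / "verification.csv", index=False)
    (outdir / "verification.txt").write_text(result.report.to_text())
    recon = result.reconstruction
    recon.to_frame().to_csv(outdir / "reconstruction.csv", index=False)
    rec.periods_frame(recon.periods).to_csv(outdir / "periods.csv", index=False)


def read_chronology_csv(path: str | Path) -> pd.Series:
    """Load the site index written by a previous run (year,index,... CSV)."""
    df = pd.read_csv(path)
    return pd.Series(df["index"].to_numpy(), index=df["year"].astype(int).to_numpy())
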