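"""Run configuration: plain-text (INI-style) config files and the pipeline
runner tying simulate -> forecast -> benchmark together.

A config file has ``key = value`` pairs in per-module sections::

    [paths]
    demand = demand.csv
    holidays = holidays.csv
    output = out/

    [run]
    stages = forecast, benchmark
    stream = overall
    test_start = 2019-01-01
    training_years = 1, 2, 3
    alpha = 0.05
    seed = 1

    [rolling_window]
    tau = 1
    theta = 2

    [models]
    families = ROLLING_WINDOW, LINEAR, RANDOM_FOREST, ENSEMBLE

An empty file is valid and yields the documented defaults (tau=1, theta=2,
m=365, level=0.95, alpha=0.05, seed=1). Unknown sections or keys are
configuration errors naming the offender.
"""

from __future__ import annotations

import configparser
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .calendar import CorrespondenceMode, HolidayCalendar
from .errors import ConfigurationError, SurgecastError
from .evaluation import compare_models, mask_kind_for_stream, run_benchmark
from .features import SeasonalityConfig
from .io import OVERALL, read_series, write_series
from .regression import EstimatorSpec
from .rolling import (
    Aggregation,
    HolidayMode,
    RollingWindowConfig,
    Rounding,
    forecast_range,
)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_KNOWN = {
    "paths": {"demand", "holidays", "output"},
    "run": {
        "stages", "stream", "test_start", "horizon_start", "horizon_end",
        "training_years", "alpha", "seed", "scenario",
    },
    "rolling_window": {
        "tau", "theta", "correspondence", "holiday_mode", "aggregation",
        "rounding", "level",
    },
    "season": {"m"},
    "models": {"families"},
}

_VALID_STAGES = ("simulate", "forecast", "benchmark")


@dataclass
class RunConfig:
    """Fully resolved configuration for one pipeline run."""

    demand_path: Path | None = None
    holiday_path: Path | None = None
    output_dir: Path = Path(".")
    stages: tuple[str, ...] = ()
    stream: str = OVERALL
    scenario: str | None = None
    test_start: dt.date = dt.date(2019, 1, 1)
    horizon_start: dt.date | None = None
    horizon_end: dt.date | None = None
    training_years: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    seed: int = 1
    rolling: RollingWindowConfig = field(default_factory=RollingWindowConfig)
    season: SeasonalityConfig = field(default_factory=SeasonalityConfig)
    model_families: tuple[str, ...] = ("ROLLING_WINDOW",)

    def resolved(self) -> dict:
        """Every config key with its resolved value, for the run log."""
        d = {
            "demand_path": str(self.demand_path) if self.demand_path else None,
            "holiday_path": str(self.holiday_path) if self.holiday_path else None,
            "output_dir": str(self.output_dir),
            "stages": list(self.stages),
            "stream": self.stream,
            "scenario": self.scenario,
            "test_start": self.test_start.isoformat(),
            "horizon_start": self.horizon_start.isoformat() if self.horizon_start else None,
            "horizon_end": self.horizon_end.isoformat() if self.horizon_end else None,
            "training_years": list(self.training_years),
            "alpha": self.alpha,
            "seed": self.seed,
            "rolling_window": {
                "tau": self.rolling.tau,
                "theta": self.rolling.theta,
                "correspondence": self.rolling.correspondence.value,
                "holiday_mode": self.rolling.holiday_mode.value,
                "aggregation": self.rolling.aggregation.value,
                "rounding": self.rolling.rounding.value,
                "level": self.rolling.level,
            },
            "season_m": self.season.m,
            "model_families": list(self.model_families),
        }
        return d


def _parse_date(section: str, key: str, value: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ConfigurationError(
            f"[{section}] {key} = {value!r}: expected an ISO date (YYYY-MM-DD)"
        ) from exc


def _parse_int(section: str, key: str, value: str, minimum: int | None = None) -> int:
    try:
        v = int(value)
    except ValueError as exc:
        raise ConfigurationError(f"[{section}] {key} = {value!r}: expected an integer") from exc
    if minimum is not None and v < minimum:
        raise ConfigurationError(f"[{section}] {key} = {v}: must be >= {minimum}")
    return v


def _parse_enum(section: str, key: str, value: str, enum_cls):
    try:
        return enum_cls(value.strip().upper())
    except ValueError as exc:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ConfigurationError(
            f"[{section}] {key} = {value!r}: expected one of {allowed}"
        ) from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a plain-text config file into a :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path, encoding="utf-8")
    except configparser.Error as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc

    for section in parser.sections():
        if section not in _KNOWN:
            raise ConfigurationError(
                f"{path}: unknown section [{section}]; known: {', '.join(_KNOWN)}"
            )
        for key in parser[section]:
            if key not in _KNOWN[section]:
                raise ConfigurationError(
                    f"{path}: unknown key {key!r} in [{section}]; "
                    f"accepted: {', '.join(sorted(_KNOWN[section]))}"
                )

    cfg = RunConfig()

    def get(section: str, key: str) -> str | None:
        return parser.get(section, key, fallback=None)

    if v := get("paths", "demand"):
        cfg.demand_path = Path(v)
    if v := get("paths", "holidays"):
        cfg.holiday_path = Path(v)
    if v := get("paths", "output"):
        cfg.output_dir = Path(v)

    if v := get("run", "stages"):
        stages = tuple(s.strip() for s in v.split(",") if s.strip())
        for s in stages:
            if s not in _VALID_STAGES:
                raise ConfigurationError(
                    f"[run] stages: unknown stage {s!r}; valid: {', '.join(_VALID_STAGES)}"
                )
        cfg.stages = stages
    if v := get("run", "stream"):
        cfg.stream = v.strip()
    if v := get("run", "scenario"):
        cfg.scenario = v.strip().upper()
    if v := get("run", "test_start"):
        cfg.test_start = _parse_date("run", "test_start", v)
    if v := get("run", "horizon_start"):
        cfg.horizon_start = _parse_date("run", "horizon_start", v)
    if v := get("run", "horizon_end"):
        cfg.horizon_end = _parse_date("run", "horizon_end", v)
    if v := get("run", "training_years"):
        years = tuple(_parse_int("run", "training_years", y.strip(), minimum=1)
                      for y in v.split(","))
        cfg.training_years = years
    if v := get("run", "alpha"):
        try:
            cfg.alpha = float(v)
        except ValueError as exc:
            raise ConfigurationError(f"[run] alpha = {v!r}: expected a real in (0,1)") from exc
        if not 0 < cfg.alpha < 1:
            raise ConfigurationError(f"[run] alpha = {cfg.alpha}: must be in (0,1)")
    if v := get("run", "seed"):
        cfg.seed = _parse_int("run", "seed", v)

    rw_kwargs = {}
    if v := get("rolling_window", "tau"):
        rw_kwargs["tau"] = _parse_int("rolling_window", "tau", v, minimum=1)
    if v := get("rolling_window", "theta"):
        rw_kwargs["theta"] = _parse_int("rolling_window", "theta", v, minimum=0)
    if v := get("rolling_window", "correspondence"):
        rw_kwargs["correspondence"] = _parse_enum(
            "rolling_window", "correspondence", v, CorrespondenceMode
        )
    if v := get("rolling_window", "holiday_mode"):
        rw_kwargs["holiday_mode"] = _parse_enum("rolling_window", "holiday_mode", v, HolidayMode)
    if v := get("rolling_window", "aggregation"):
        rw_kwargs["aggregation"] = _parse_enum("rolling_window", "aggregation", v, Aggregation)
    if v := get("rolling_window", "rounding"):
        rw_kwargs["rounding"] = _parse_enum("rolling_window", "rounding", v, Rounding)
    if v := get("rolling_window", "level"):
        try:
            rw_kwargs["level"] = float(v)
        except ValueError as exc:
            raise ConfigurationError(f"[rolling_window] level = {v!r}: expected a real") from exc
    cfg.rolling = RollingWindowConfig(**rw_kwargs)

    if v := get("season", "m"):
        cfg.season = SeasonalityConfig(m=_parse_int("season", "m", v, minimum=2))

    if v := get("models", "families"):
        cfg.model_families = tuple(f.strip().upper() for f in v.split(",") if f.strip())

    for p, label in ((cfg.demand_path, "demand"), (cfg.holiday_path, "holidays")):
        if p is not None and not p.exists():
            raise ConfigurationError(f"[paths] {label}: file not found: {p}")
    return cfg


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; write artifacts and a run log.

    Stages: ``simulate`` writes the scenario fixture into the output
    directory and wires its files into the later stages; ``forecast`` writes a
    rolling-window forecast CSV (``date,point,lower,upper,n_obs``) over the
    test year (or configured horizon); ``benchmark`` writes ``benchmark.csv``
    and ``comparisons.csv``. Reruns with the same config produce identical
    CSVs.
    """
    from . import synthetic

    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stages = config.stages or ("forecast",)

    demand_path = config.demand_path
    holiday_path = config.holiday_path

    if "simulate" in stages:
        if not config.scenario:
            raise ConfigurationError("simulate stage requires [run] scenario")
        paths = synthetic.make_fixture(config.scenario, out, seed=config.seed)
        demand_path = paths["demand"]
        holiday_path = paths["holidays"]
        artifacts.update({"demand": paths["demand"], "holidays": paths["holidays"],
                          "params": paths["params"]})

    needs_data = {"forecast", "benchmark"} & set(stages)
    series_by_stream = {}
    holidays = HolidayCalendar.empty()
    if needs_data:
        if demand_path is None:
            raise ConfigurationError("forecast/benchmark stages require [paths] demand")
        if not Path(demand_path).exists():
            raise ConfigurationError(f"demand CSV not found: {demand_path}")
        series_by_stream = {s.stream: s for s in read_series(demand_path)}
        if config.stream not in series_by_stream:
            raise ConfigurationError(
                f"stream {config.stream!r} not in {sorted(series_by_stream)}"
            )
        if holiday_path is not None:
            if not Path(holiday_path).exists():
                raise ConfigurationError(f"holiday CSV not found: {holiday_path}")
            holidays = HolidayCalendar.read_csv(holiday_path)

    if "forecast" in stages:
        series = series_by_stream[config.stream]
        start = config.horizon_start or config.test_start
        end = config.horizon_end or series.end
        from .io import slice_series

        history = slice_series(series, series.start, start - dt.timedelta(days=1))
        forecasts = forecast_range(history, start, end, config.rolling, holidays)
        fdf = pd.DataFrame(
            {
                "date": [f.date.isoformat() for f in forecasts],
                "point": [f.point for f in forecasts],
                "lower": [round(f.lower, 6) for f in forecasts],
                "upper": [round(f.upper, 6) for f in forecasts],
                "n_obs": [f.n_obs for f in forecasts],
            }
        )
        fpath = out / "forecast.csv"
        fdf.to_csv(fpath, index=False)
        artifacts["forecast"] = fpath

    if "benchmark" in stages:
        models = {}
        for fam in config.model_families:
            if fam == "ROLLING_WINDOW":
                models["ROLLING_WINDOW"] = config.rolling
            else:
                models[fam] = EstimatorSpec(fam, seed=config.seed)
        result = run_benchmark(
            {config.stream: series_by_stream[config.stream]},
            models,
            config.test_start,
            training_years=config.training_years,
            holidays=holidays,
            season=config.season,
        )
        bpath = out / "benchmark.csv"
        result.table.to_csv(bpath, index=False, float_format="%.6f")
        artifacts["benchmark"] = bpath
        comp_rows = []
        for years in config.training_years:
            abs_pe = result.abs_pe_for(config.stream, years)
            for c in compare_models(abs_pe, alpha=config.alpha):
                comp_rows.append(
                    {
                        "training_years": years,
                        "model_a": c.model_a,
                        "model_b": c.model_b,
                        "t": c.t_statistic,
                        "p": c.p_value,
                        "k": c.k,
                        "adjusted_alpha": c.adjusted_alpha,
                        "significant": c.significant,
                    }
                )
        cpath = out / "comparisons.csv"
        pd.DataFrame(
            comp_rows,
            columns=["training_years", "model_a", "model_b", "t", "p", "k",
                     "adjusted_alpha", "significant"],
        ).to_csv(cpath, index=False, float_format="%.6g")
        artifacts["comparisons"] = cpath

    resolved = json.loads(json.dumps(RunConfig.resolved(config)))
    log = {
        "config": resolved,
        "config_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest()[:16],
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "wall_time_s": round(time.time() - t0, 3),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    artifacts["log"] = log_path
    return artifacts
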