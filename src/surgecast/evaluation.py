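"""Backtesting protocol: chronological splits, error metrics, masking,
breakdowns and model comparison.

Forecast accuracy is always assessed out-of-sample on a chronologically
held-out final year — never by random cross-validation, since daily theatre
arrivals are time-dependent. The error measures follow the standard
definitions: with actual count ``Y_t`` and forecast ``F_t``,

* ``e_t = Y_t - F_t``, ``MAE = mean |e_t|``, ``MSE = mean e_t^2``,
  ``RMSE = sqrt(MSE)``;
* percentage error ``PE_t = (Y_t - F_t) / Y_t * 100`` — negative PE means
  over-estimation — and ``MAPE = mean |PE_t|``.

MAPE is undefined on zero-count days, hence the masking rules: elective
evaluations drop weekends and public holidays (electives are not scheduled on
those days), specialty evaluations additionally drop days with no surgery in
that specialty, and any residual zero-count day is dropped with a warning.

Model comparison uses paired two-tailed t-tests on per-day absolute
percentage errors aligned by date, with a Bonferroni-adjusted significance
threshold ``alpha / K`` for ``K`` executed comparisons.
"""

from __future__ import annotations

import datetime as dt
import enum
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import DayType, HolidayCalendar, day_type, weekday_type
from .errors import ValidationError
from .io import ELECTIVE, EMERGENCY, OVERALL, DailyDemandSeries, slice_series
from .regression import EstimatorSpec, fit_forecaster
from .rolling import Forecast, RollingWindowConfig, Rounding, forecast_range

__all__ = [
    "Metrics",
    "ErrorRecord",
    "MaskKind",
    "BreakdownBy",
    "ComparisonResult",
    "chronological_split",
    "error_metrics",
    "percentage_error",
    "apply_mask",
    "build_error_records",
    "breakdown",
    "compare_models",
    "naive_weekday_forecast",
    "BenchmarkResult",
    "run_benchmark",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Metrics:
    mae: float
    mse: float
    rmse: float
    mape: float


@dataclass(frozen=True)
class ErrorRecord:
    """Per-day forecast error: ``error = actual - forecast`` and the
    percentage error on the same sign convention (negative = over-estimate)."""

    date: dt.date
    actual: int
    forecast: float
    error: float
    pe: float
    day_type: DayType
    weekday: DayType
    month: int


class MaskKind(enum.Enum):
    """Which days of a testing year enter the error aggregation.

    ``EMERGENCY_OR_OVERALL`` keeps every day; ``ELECTIVE`` drops weekends and
    public holidays; ``SPECIALTY`` additionally drops days with no surgery in
    the specialty.
    """

    EMERGENCY_OR_OVERALL = "EMERGENCY_OR_OVERALL"
    ELECTIVE = "ELECTIVE"
    SPECIALTY = "SPECIALTY"


class BreakdownBy(enum.Enum):
    DAY_OF_WEEK = "DAY_OF_WEEK"
    MONTH = "MONTH"


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    t_statistic: float
    p_value: float
    k: int
    adjusted_alpha: float
    significant: bool


def percentage_error(actual: float, forecast: float) -> float:
    """PE in percent; negative when the forecast exceeds the actual."""
    if actual == 0:
        raise ValidationError("percentage error undefined for a zero actual; mask such days")
    return (actual - forecast) / actual * 100.0


def error_metrics(
    actuals: Sequence[float], forecasts: Sequence[float]
) -> Metrics:
    """MAE, MSE, RMSE and MAPE (percent) of aligned actual/forecast lists."""
    y = np.asarray(actuals, dtype=float)
    f = np.asarray(forecasts, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValidationError(f"actuals and forecasts must align, got {y.shape} vs {f.shape}")
    if y.size == 0:
        raise ValidationError("cannot compute metrics on an empty day set")
    if (y == 0).any():
        raise ValidationError(
            "zero actual encountered: MAPE is undefined at Y=0; apply a mask first"
        )
    e = y - f
    mae = float(np.abs(e).mean())
    mse = float((e**2).mean())
    mape = float(np.abs(e / y).mean() * 100.0)
    return Metrics(mae=mae, mse=mse, rmse=math.sqrt(mse), mape=mape)


def chronological_split(
    series: DailyDemandSeries, test_start: dt.date, training_years: int
) -> tuple[DailyDemandSeries, DailyDemandSeries]:
    """Last ``training_years`` whole years before ``test_start``, plus the test year.

    Training ends the day before ``test_start``; testing is the year starting
    at ``test_start``. The two never overlap.
    """
    if training_years < 1:
        raise ValidationError(f"training_years must be >= 1, got {training_years}")
    train_start = (pd.Timestamp(test_start) - pd.DateOffset(years=training_years)).date()
    train_end = test_start - dt.timedelta(days=1)
    test_end = (pd.Timestamp(test_start) + pd.DateOffset(years=1)).date() - dt.timedelta(days=1)
    if series.start > train_start or series.end < test_end:
        raise ValidationError(
            f"series covers {series.start}..{series.end} but the split needs "
            f"{train_start}..{test_end}"
        )
    return (
        slice_series(series, train_start, train_end),
        slice_series(series, test_start, test_end),
    )


def apply_mask(
    testing: DailyDemandSeries,
    kind: MaskKind,
    holidays: HolidayCalendar | None = None,
) -> list[dt.date]:
    """The evaluated dates of a testing series under the given masking rule."""
    holidays = holidays or HolidayCalendar.empty()
    kept: list[dt.date] = []
    for d in testing.dates():
        t = day_type(d, holidays)
        if kind in (MaskKind.ELECTIVE, MaskKind.SPECIALTY) and (
            t is DayType.PUBLIC_HOLIDAY or t.is_weekend
        ):
            continue
        if kind is MaskKind.SPECIALTY and testing.count_on(d) == 0:
            continue
        kept.append(d)
    # MAPE is undefined at Y=0: drop residual zero-count days under any mask
    zeros = [d for d in kept if testing.count_on(d) == 0]
    if zeros:
        logger.warning(
            "stream %r: dropping %d residual zero-count day(s) from evaluation (first: %s)",
            testing.stream, len(zeros), zeros[0],
        )
        kept = [d for d in kept if testing.count_on(d) > 0]
    if not kept:
        raise ValidationError(f"mask {kind.value} leaves no evaluable day for {testing.stream!r}")
    return kept


def mask_kind_for_stream(stream: str) -> MaskKind:
    if stream in (EMERGENCY, OVERALL):
        return MaskKind.EMERGENCY_OR_OVERALL
    if stream == ELECTIVE:
        return MaskKind.ELECTIVE
    return MaskKind.SPECIALTY


def build_error_records(
    testing: DailyDemandSeries,
    forecasts: Mapping[dt.date, float],
    mask_dates: Sequence[dt.date],
    holidays: HolidayCalendar | None = None,
) -> list[ErrorRecord]:
    """Join actuals and forecasts on the masked dates into per-day records."""
    records = []
    for d in mask_dates:
        y = testing.count_on(d)
        f = float(forecasts[d])
        records.append(
            ErrorRecord(
                date=d,
                actual=y,
                forecast=f,
                error=y - f,
                pe=percentage_error(y, f),
                day_type=day_type(d, holidays),
                weekday=weekday_type(d),
                month=d.month,
            )
        )
    return records


def breakdown(records: Sequence[ErrorRecord], by: BreakdownBy) -> pd.DataFrame:
    """Group MAPE (mean |PE|) with interquartile spread, by weekday or month.

    The groups partition the records, so recombining group means weighted by
    group sizes reproduces the overall MAPE.
    """
    if not records:
        raise ValidationError("no error records to break down")
    if by is BreakdownBy.DAY_OF_WEEK:
        keys = [r.weekday.value for r in records]
        order = [t.value for t in DayType if t is not DayType.PUBLIC_HOLIDAY]
    else:
        keys = [r.month for r in records]
        order = list(range(1, 13))
    df = pd.DataFrame({"group": keys, "abs_pe": [abs(r.pe) for r in records]})
    agg = (
        df.groupby("group")["abs_pe"]
        .agg(
            n="count",
            mape="mean",
            iqr=lambda s: float(np.subtract(*np.percentile(s, [75, 25]))),
        )
        .reset_index()
    )
    agg["group"] = pd.Categorical(agg["group"], categories=order, ordered=True)
    return agg.sort_values("group").reset_index(drop=True)


def compare_models(
    daily_abs_pe: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> list[ComparisonResult]:
    """Paired two-tailed t-tests on per-day absolute PE for every model pair.

    ``K`` is the number of comparisons actually executed; a difference is
    significant iff ``p < alpha / K`` (Bonferroni).
    """
    names = list(daily_abs_pe)
    lengths = {name: len(daily_abs_pe[name]) for name in names}
    if len(set(lengths.values())) > 1:
        raise ValidationError(f"error lists must align on the same masked days: {lengths}")
    pairs = list(itertools.combinations(names, 2))
    k = len(pairs)
    if k == 0:
        return []
    adjusted = alpha / k
    out = []
    for a, b in pairs:
        xa = np.asarray(daily_abs_pe[a], dtype=float)
        xb = np.asarray(daily_abs_pe[b], dtype=float)
        if np.array_equal(xa, xb):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(xa, xb)
        out.append(
            ComparisonResult(
                model_a=a,
                model_b=b,
                t_statistic=float(t_stat),
                p_value=float(p),
                k=k,
                adjusted_alpha=adjusted,
                significant=bool(p < adjusted),
            )
        )
    return out


# ---------------------------------------------------------------------------
# benchmark harness


def naive_weekday_forecast(
    history: DailyDemandSeries, dates: Sequence[dt.date]
) -> dict[dt.date, float]:
    """Same-weekday persistence baseline: each target date is forecast with the
    count of the most recent same-weekday date in the history."""
    last_by_weekday: dict[int, int] = {}
    for d in history.dates():
        last_by_weekday[d.weekday()] = history.count_on(d)
    return {d: float(last_by_weekday[d.weekday()]) for d in dates}


#: A benchmark model: a rolling-window configuration, an estimator spec, or a
#: callable ``(training_series, dates, holidays) -> mapping date -> forecast``.
ModelSpec = "RollingWindowConfig | EstimatorSpec | Callable"


@dataclass
class BenchmarkResult:
    """Benchmark output: the MAPE table plus the per-day absolute PE lists
    needed for significance testing."""

    table: pd.DataFrame
    daily_abs_pe: dict[tuple[str, str, int], list[float]]  # (model, stream, years)
    records: dict[tuple[str, str, int], list[ErrorRecord]]

    def abs_pe_for(self, stream: str, training_years: int) -> dict[str, list[float]]:
        return {
            model: pes
            for (model, s, yrs), pes in self.daily_abs_pe.items()
            if s == stream and yrs == training_years
        }


def _forecast_with(
    model,
    training: DailyDemandSeries,
    dates: Sequence[dt.date],
    holidays: HolidayCalendar | None,
    season,
    round_rolling_window: bool,
) -> dict[dt.date, float]:
    if isinstance(model, RollingWindowConfig):
        cfg = model
        if round_rolling_window and cfg.rounding is Rounding.NONE:
            cfg = cfg.with_(rounding=Rounding.NEAREST_INT)
        fcs = forecast_range(training, dates[0], dates[-1], cfg, holidays)
        by_date = {f.date: f.point for f in fcs}
        return {d: by_date[d] for d in dates}
    if isinstance(model, EstimatorSpec):
        fitted = fit_forecaster(model, training, holidays=holidays, season=season)
        preds = fitted.predict(dates)
        return dict(zip(dates, (float(p) for p in preds)))
    if callable(model):
        return dict(model(training, dates, holidays))
    raise ValidationError(f"unsupported benchmark model {model!r}")


def run_benchmark(
    series_by_stream: Mapping[str, DailyDemandSeries],
    models: Mapping[str, "ModelSpec"],
    test_start: dt.date,
    training_years: Sequence[int] = (1, 2, 3),
    holidays: HolidayCalendar | None = None,
    season=None,
    round_rolling_window: bool = True,
) -> BenchmarkResult:
    """Backtest every model on every stream and training length.

    For each (stream, training length) the series is split chronologically,
    each model produces year-ahead forecasts from the training slice only,
    and errors are aggregated over the stream's masked day set. Rolling-window
    point forecasts are rounded to integers by default (regression forecasts
    are left unrounded); pass ``round_rolling_window=False`` to override.

    Returns a table with one row per (model, stream, training length) holding
    mape/mae/rmse/n_days and a ``best_in_column`` flag marking the lowest MAPE
    per (stream, training length).
    """
    from .features import SeasonalityConfig

    season = season or SeasonalityConfig()
    rows = []
    daily_abs_pe: dict[tuple[str, str, int], list[float]] = {}
    records_out: dict[tuple[str, str, int], list[ErrorRecord]] = {}
    for stream, series in series_by_stream.items():
        for years in training_years:
            training, testing = chronological_split(series, test_start, years)
            mask_dates = apply_mask(testing, mask_kind_for_stream(stream), holidays)
            horizon = testing.dates()
            for name, model in models.items():
                forecasts = _forecast_with(
                    model, training, horizon, holidays, season, round_rolling_window
                )
                recs = build_error_records(testing, forecasts, mask_dates, holidays)
                m = error_metrics([r.actual for r in recs], [r.forecast for r in recs])
                rows.append(
                    {
                        "model": name,
                        "stream": stream,
                        "training_years": years,
                        "mape": m.mape,
                        "mae": m.mae,
                        "rmse": m.rmse,
                        "n_days": len(recs),
                    }
                )
                daily_abs_pe[(name, stream, years)] = [abs(r.pe) for r in recs]
                records_out[(name, stream, years)] = recs
    table = pd.DataFrame(rows)
    best = table.groupby(["stream", "training_years"])["mape"].transform("min")
    table["best_in_column"] = table["mape"] == best
    return BenchmarkResult(table=table, daily_abs_pe=daily_abs_pe, records=records_out)
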