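"""Calendar-matched rolling-window forecaster.

To predict the caseload of a future day of interest (DOI), the forecaster
collects historic daily counts that are calendar-matched to the DOI and
aggregates them — by default with a uniform (unweighted) mean. Two parameters
control the collection:

* ``tau`` — how many preceding years of history to query. For each lag year
  ``k = 1..tau`` the *corresponding day* (same day-of-week and approximately
  the same week-of-year, see :func:`surgecast.calendar.corresponding_day`) is
  located and a symmetric window of same-weekday dates around it is collected.
* ``theta`` — the half-width of those windows in whole weeks. In the DOI's own
  year only the ``theta`` same-weekday dates strictly *preceding* the DOI are
  collected (future dates are unobservable at application time).

With complete history coverage, no holiday filtering, the collection size is
exactly ``theta + tau * (2*theta + 1)``.

The forecaster is deterministic: there is no random component, and identical
inputs always produce identical forecasts. A long horizon (up to a year) is
forecast in a single pass, each day independently, using only history strictly
before the horizon start.

Prediction intervals use a t-based formula on the collected counts
(``point ± t_{(1+level)/2, n-1} * s * sqrt(1 + 1/n)``), an implementation
default chosen for its standard coverage behaviour on approximately normal
counts; it is not intrinsic to the collection algorithm.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .calendar import (
    CorrespondenceMode,
    DayType,
    Direction,
    HolidayCalendar,
    corresponding_day,
    day_type,
    weekly_neighbors,
)
from .errors import ConfigurationError, InsufficientHistoryError, ValidationError
from .io import DailyDemandSeries

__all__ = [
    "HolidayMode",
    "Aggregation",
    "Rounding",
    "RollingWindowConfig",
    "Observation",
    "ObservationSet",
    "Forecast",
    "collect_observations",
    "predict_point",
    "predict_interval",
    "forecast_range",
]

logger = logging.getLogger(__name__)


class HolidayMode(enum.Enum):
    """Whether observation collection is purely date-offset based or holiday-aware.

    ``CALENDAR_ONLY`` (the default) collects by date offsets alone.
    ``HOLIDAY_AWARE`` additionally filters: for a holiday DOI, only holiday or
    weekend source dates are kept (augmented with all holidays in the lookback
    when fewer than three survive); for a non-holiday DOI, holiday source dates
    are dropped.
    """

    CALENDAR_ONLY = "CALENDAR_ONLY"
    HOLIDAY_AWARE = "HOLIDAY_AWARE"


class Aggregation(enum.Enum):
    UNIFORM_MEAN = "UNIFORM_MEAN"
    MEDIAN = "MEDIAN"
    MIN = "MIN"
    MAX = "MAX"
    #: mean of per-lag-year means rather than the pooled mean
    PER_YEAR_MEAN = "PER_YEAR_MEAN"


class Rounding(enum.Enum):
    NONE = "NONE"
    NEAREST_INT = "NEAREST_INT"


@dataclass(frozen=True)
class RollingWindowConfig:
    """Configuration of the rolling-window forecaster.

    Defaults follow the study configuration: one year of history, weekly
    window half-width of 2, calendar-only collection, uniform mean, 95%
    interval level.
    """

    tau: int = 1
    theta: int = 2
    correspondence: CorrespondenceMode = CorrespondenceMode.WEEKDAY_364
    holiday_mode: HolidayMode = HolidayMode.CALENDAR_ONLY
    aggregation: Aggregation = Aggregation.UNIFORM_MEAN
    rounding: Rounding = Rounding.NONE
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ConfigurationError(f"tau must be >= 1, got {self.tau}")
        if self.theta < 0:
            raise ConfigurationError(f"theta must be >= 0, got {self.theta}")
        if not 0.0 < self.level < 1.0:
            raise ConfigurationError(f"interval level must be in (0,1), got {self.level}")

    def with_(self, **kwargs) -> "RollingWindowConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Observation:
    """One collected historic count: source date, count, and lag in years
    (0 = the DOI's own year)."""

    date: dt.date
    count: int
    lag_years: int


@dataclass
class ObservationSet:
    """The historic counts collected for one day of interest.

    ``n_requested`` is the number of source dates the collection rule asked
    for; ``n_missing`` counts those skipped because the series did not cover
    them (or, degenerately, because a window reached past the DOI), so
    ``coverage = 1 - n_missing / n_requested`` is a diagnostic of how complete
    the history was.
    """

    doi: dt.date
    items: list[Observation]
    n_requested: int = 0
    n_missing: int = 0

    def counts(self) -> np.ndarray:
        return np.array([o.count for o in self.items], dtype=float)

    def source_dates(self) -> list[dt.date]:
        return [o.date for o in self.items]

    @property
    def coverage(self) -> float:
        if self.n_requested == 0:
            return 1.0
        return 1.0 - self.n_missing / self.n_requested

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Forecast:
    """A point forecast with its prediction interval for one date."""

    date: dt.date
    point: float
    lower: float
    upper: float
    level: float
    n_obs: int

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValidationError(
                f"forecast for {self.date}: interval [{self.lower}, {self.upper}] "
                f"does not bracket point {self.point}"
            )


def _collection_anchors(
    doi: dt.date, config: RollingWindowConfig
) -> list[tuple[dt.date, int]]:
    """(source date, lag year) pairs the collection rule asks for."""
    anchors: list[tuple[dt.date, int]] = [
        (d, 0) for d in weekly_neighbors(doi, config.theta, Direction.BEFORE)
    ]
    for k in range(1, config.tau + 1):
        corr = corresponding_day(doi, k, config.correspondence)
        anchors.extend(
            (d, k) for d in weekly_neighbors(corr, config.theta, Direction.SYMMETRIC)
        )
    return anchors


def collect_observations(
    series: DailyDemandSeries,
    doi: dt.date,
    config: RollingWindowConfig,
    holidays: HolidayCalendar | None = None,
) -> ObservationSet:
    """Collect the calendar-matched historic counts for ``doi``.

    Source dates outside the series coverage are silently skipped and counted
    in the coverage diagnostic, so short histories (e.g. one year with
    ``tau=1``) still work. Raises :class:`InsufficientHistoryError` when
    nothing at all survives.
    """
    if doi <= series.start:
        raise InsufficientHistoryError(
            f"day of interest {doi} is not after the series start {series.start}"
        )
    holidays = holidays or HolidayCalendar.empty()
    anchors = _collection_anchors(doi, config)
    items: list[Observation] = []
    n_missing = 0
    for d, lag in anchors:
        if d >= doi or not series.covers(d):
            n_missing += 1
            continue
        items.append(Observation(d, series.count_on(d), lag))

    if config.holiday_mode is HolidayMode.HOLIDAY_AWARE:
        items = _holiday_filter(series, doi, config, holidays, items)

    if not items:
        raise InsufficientHistoryError(
            f"no usable historic observations for {doi}; increase theta or tau, "
            f"extend the history, or use CALENDAR_ONLY mode"
        )
    obs = ObservationSet(doi, items, n_requested=len(anchors), n_missing=n_missing)
    if obs.coverage < 1.0:
        logger.debug("DOI %s: coverage %.2f (%d/%d sources available)",
                     doi, obs.coverage, len(items), len(anchors))
    return obs


def _holiday_filter(
    series: DailyDemandSeries,
    doi: dt.date,
    config: RollingWindowConfig,
    holidays: HolidayCalendar,
    items: list[Observation],
) -> list[Observation]:
    """HOLIDAY_AWARE filtering (see :class:`HolidayMode`)."""

    def is_offday(d: dt.date) -> bool:
        t = day_type(d, holidays)
        return t is DayType.PUBLIC_HOLIDAY or t.is_weekend

    if day_type(doi, holidays) is DayType.PUBLIC_HOLIDAY:
        kept = [o for o in items if is_offday(o.date)]
        if len(kept) < 3:
            # too few matched off-days in the date-offset windows: fall back to
            # every public holiday observable in the tau-year lookback
            lookback_start = doi - dt.timedelta(days=364 * config.tau + 7 * config.theta)
            seen = {o.date for o in kept}
            for h in holidays.between(max(lookback_start, series.start), doi - dt.timedelta(days=1)):
                if h in seen or not series.covers(h):
                    continue
                lag = min(config.tau, (doi - h).days // 364)
                kept.append(Observation(h, series.count_on(h), lag))
            kept.sort(key=lambda o: o.date)
        return kept
    return [o for o in items if day_type(o.date, holidays) is not DayType.PUBLIC_HOLIDAY]


def _round_half_away(x: float) -> float:
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def predict_point(obs: ObservationSet, config: RollingWindowConfig) -> float:
    """Aggregate the collected counts into a point forecast.

    ``UNIFORM_MEAN`` is the unweighted arithmetic mean of all counts pooled
    across years; ``PER_YEAR_MEAN`` averages the per-lag-year means instead.
    ``NEAREST_INT`` rounding rounds half away from zero.
    """
    if len(obs) == 0:
        raise InsufficientHistoryError(f"empty observation set for {obs.doi}")
    counts = obs.counts()
    agg = config.aggregation
    if agg is Aggregation.UNIFORM_MEAN:
        point = float(counts.mean())
    elif agg is Aggregation.MEDIAN:
        point = float(np.median(counts))
    elif agg is Aggregation.MIN:
        point = float(counts.min())
    elif agg is Aggregation.MAX:
        point = float(counts.max())
    elif agg is Aggregation.PER_YEAR_MEAN:
        by_lag: dict[int, list[int]] = {}
        for o in obs.items:
            by_lag.setdefault(o.lag_years, []).append(o.count)
        point = float(np.mean([np.mean(v) for v in by_lag.values()]))
    else:  # pragma: no cover - enum is closed
        raise ConfigurationError(f"unknown aggregation {agg!r}")
    if config.rounding is Rounding.NEAREST_INT:
        point = _round_half_away(point)
    return point


def predict_interval(obs: ObservationSet, config: RollingWindowConfig) -> Forecast:
    """Point forecast plus a t-based prediction interval, clipped at zero.

    A singleton or zero-variance observation set yields the degenerate
    interval ``[point, point]``.
    """
    point = predict_point(obs, config)
    counts = obs.counts()
    n = len(counts)
    s = float(counts.std(ddof=1)) if n >= 2 else 0.0
    if n < 2 or s == 0.0:
        lower = upper = point
    else:
        tq = float(stats.t.ppf((1 + config.level) / 2, df=n - 1))
        half = tq * s * math.sqrt(1 + 1 / n)
        lower = max(0.0, point - half)
        upper = point + half
    # rounding the point must never push it outside the interval
    lower = min(lower, point)
    upper = max(upper, point)
    return Forecast(obs.doi, point, lower, upper, config.level, n)


def forecast_range(
    series: DailyDemandSeries,
    start: dt.date,
    end: dt.date,
    config: RollingWindowConfig,
    holidays: HolidayCalendar | None = None,
) -> list[Forecast]:
    """One forecast per date in [start, end], using only history before ``start``.

    The whole horizon is forecast in a single pass with no refitting: the
    history series must end strictly before the horizon start, which rules out
    any leakage of horizon counts into the collection step by construction.
    """
    if start > end:
        raise ValidationError(f"horizon start {start} after end {end}")
    if series.end >= start:
        raise ValidationError(
            f"history must end before the horizon start: history ends {series.end}, "
            f"horizon starts {start}"
        )
    out: list[Forecast] = []
    d = start
    while d <= end:
        obs = collect_observations(series, d, config, holidays)
        out.append(predict_interval(obs, config))
        d += dt.timedelta(days=1)
    return out
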