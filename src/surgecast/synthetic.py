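"""Synthetic daily surgical-demand generator.

The original hospital extract behind this line of work cannot be shared, so
the package ships a generator that emulates its calendar structure: high
weekday volumes with a Friday peak, weekend volumes around a quarter of
weekday levels, holidays that behave like weekends, elective surgery absent
on weekends and holidays, a mild annual seasonal cycle, a specialty mixture
with day-of-week profiles, and an optional pandemic-style shock interval.

The mean structure is log-linear (multiplicative), mirroring the count-GLM
feature model used by the regression forecasters and guaranteeing positive
rates::

    rate(d) = baseline * daytype_mult(d)
              * exp(amplitude * cos(2*pi*(t - phase)/365))
              * exp(trend * t/365) * shock_mult(d)

with ``t`` the day index from the generator origin. Daily overall counts are
Poisson draws from that rate (negative-binomial or noiseless variants are
available); elective counts are a binomial thinning of the overall count with
a day-type-dependent share; emergency is the remainder; specialties are a
multinomial split with day-of-week-modulated weights. Identical parameters
and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from dateutil import easter

from .calendar import DayType, HolidayCalendar, day_type
from .errors import ConfigurationError, ValidationError
from .io import ELECTIVE, EMERGENCY, OVERALL, DailyDemandSeries, write_series

__all__ = [
    "ShockInterval",
    "SpecialtyProfile",
    "GeneratorParams",
    "expected_rate",
    "sample_series",
    "synthetic_holidays",
    "make_fixture",
    "oracle_model",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ShockInterval:
    """A date range whose rate is multiplied by ``multiplier`` (e.g. a
    pandemic lockdown month with multiplier 0.3)."""

    start: dt.date
    end: dt.date
    multiplier: float

    def __contains__(self, date: dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass(frozen=True)
class SpecialtyProfile:
    """Mixture weight of one specialty plus its day-of-week modulation
    (Mon..Sun multipliers applied before per-day renormalisation)."""

    weight: float
    dow_mult: tuple[float, float, float, float, float, float, float] = (1.0,) * 7


def _default_day_type_multipliers() -> dict[DayType, float]:
    # back-solved from the study hospital's descriptive day-of-week means:
    # a Friday peak, Mon-Thu slightly below it, weekends and holidays at
    # roughly a quarter of weekday volume. Values are means in surgeries/day
    # divided by the baseline (69).
    means = {
        DayType.MON: 84.0,
        DayType.TUE: 85.0,
        DayType.WED: 86.0,
        DayType.THU: 87.0,
        DayType.FRI: 97.0,
        DayType.SAT: 22.0,
        DayType.SUN: 22.0,
        DayType.PUBLIC_HOLIDAY: 21.0,
    }
    return {k: v / 69.0 for k, v in means.items()}


def _default_elective_share() -> dict[DayType, float]:
    share = {t: 0.65 for t in DayType}
    share[DayType.SAT] = 0.0
    share[DayType.SUN] = 0.0
    share[DayType.PUBLIC_HOLIDAY] = 0.0
    return share


def _default_specialties() -> dict[str, SpecialtyProfile]:
    # top-10 specialty mixture with day-of-week habits: GAS peaks Mon/Fri,
    # ORT Tue/Fri, PLA Mon/Wed/Fri; BUR/CTS/GYN near-absent on weekends.
    return {
        "ORT": SpecialtyProfile(0.20, (1.0, 1.25, 1.0, 1.0, 1.25, 1.3, 1.3)),
        "GES": SpecialtyProfile(0.18, (1.0, 1.0, 1.0, 1.0, 1.0, 1.3, 1.3)),
        "GAS": SpecialtyProfile(0.12, (1.25, 1.0, 1.0, 1.0, 1.25, 1.0, 1.0)),
        "PLA": SpecialtyProfile(0.10, (1.2, 1.0, 1.2, 1.0, 1.2, 0.6, 0.6)),
        "OBS": SpecialtyProfile(0.08, (1.0,) * 7),
        "VAS": SpecialtyProfile(0.07, (1.0,) * 7),
        "URO": SpecialtyProfile(0.07, (1.0, 1.0, 1.0, 1.0, 1.0, 0.5, 0.5)),
        "BUR": SpecialtyProfile(0.06, (1.0, 1.0, 1.0, 1.0, 1.0, 0.2, 0.2)),
        "CTS": SpecialtyProfile(0.06, (1.0, 1.0, 1.0, 1.0, 1.0, 0.2, 0.2)),
        "GYN": SpecialtyProfile(0.06, (1.0, 1.0, 1.0, 1.0, 1.0, 0.2, 0.2)),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the demand generator; the defaults are calibrated to the
    published descriptive statistics of the study hospital (grand mean ~68
    surgeries/day over four years, Friday peak ~95, weekends/holidays ~22,
    annual seasonal swing of a few percent peaking around the start of
    November).
    """

    baseline: float = 69.0
    day_type_multipliers: Mapping[DayType, float] = field(
        default_factory=_default_day_type_multipliers
    )
    seasonal_amplitude: float = 0.06
    seasonal_phase: float = 305.0  # day index of the seasonal peak (~1 Nov)
    trend_per_year: float = 0.0  # log-scale slope per 365 days
    noise: str = "poisson"  # "poisson" | "negbin" | "none"
    dispersion: float = 1.0  # negbin size k (var = mu + mu^2/k); used iff noise="negbin"
    elective_share: Mapping[DayType, float] = field(default_factory=_default_elective_share)
    specialties: Mapping[str, SpecialtyProfile] = field(default_factory=_default_specialties)
    shocks: tuple[ShockInterval, ...] = ()
    origin: dt.date = dt.date(2016, 1, 1)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigurationError("baseline rate must be positive")
        if self.noise not in ("poisson", "negbin", "none"):
            raise ConfigurationError(f"unknown noise kind {self.noise!r}")
        if any(m <= 0 for m in self.day_type_multipliers.values()):
            raise ConfigurationError("day-type multipliers must be positive")
        if self.specialties:
            total = sum(p.weight for p in self.specialties.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"specialty weights must sum to 1, got {total}")

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


def expected_rate(
    date: dt.date, params: GeneratorParams, holidays: HolidayCalendar | None = None
) -> float:
    """The generator's true mean surgeries/day on ``date``."""
    t = (date - params.origin).days
    rate = params.baseline * params.day_type_multipliers[day_type(date, holidays)]
    rate *= math.exp(
        params.seasonal_amplitude * math.cos(2 * math.pi * (t - params.seasonal_phase) / 365.0)
    )
    rate *= math.exp(params.trend_per_year * t / 365.0)
    for shock in params.shocks:
        if date in shock:
            rate *= shock.multiplier
    return rate


def _date_range(start: dt.date, end: dt.date) -> list[dt.date]:
    return [ts.date() for ts in pd.date_range(start, end, freq="D")]


def sample_series(
    params: GeneratorParams,
    start: dt.date,
    end: dt.date,
    holidays: HolidayCalendar | None = None,
    include_specialties: bool = True,
) -> dict[str, DailyDemandSeries]:
    """Sample overall, emergency, elective and (optionally) per-specialty
    daily series over [start, end].

    Overall counts are drawn from the noise model around :func:`expected_rate`;
    elective is a binomial thinning with the day-type elective share (zero on
    weekends and holidays by default); emergency is the remainder; specialty
    streams are a multinomial split of the overall count, so all streams are
    additive and nonnegative by construction.
    """
    if start > end:
        raise ValidationError(f"start {start} after end {end}")
    dates = _date_range(start, end)
    day_types = [day_type(d, holidays) for d in dates]
    rates = np.array([expected_rate(d, params, holidays) for d in dates])
    rng = np.random.default_rng(params.seed)

    if params.noise == "poisson":
        overall = rng.poisson(rates)
    elif params.noise == "negbin":
        k = params.dispersion
        lam = rng.gamma(shape=k, scale=rates / k)
        overall = rng.poisson(lam)
    else:  # deterministic
        overall = np.rint(rates).astype(np.int64)

    shares = np.array([params.elective_share[t] for t in day_types])
    if params.noise == "none":
        elective = np.rint(overall * shares).astype(np.int64)
    else:
        elective = rng.binomial(overall, shares)
    emergency = overall - elective

    out = {
        OVERALL: DailyDemandSeries.from_values(OVERALL, start, overall),
        ELECTIVE: DailyDemandSeries.from_values(ELECTIVE, start, elective),
        EMERGENCY: DailyDemandSeries.from_values(EMERGENCY, start, emergency),
    }

    if include_specialties and params.specialties:
        codes = list(params.specialties)
        weights = np.array([params.specialties[c].weight for c in codes])
        dow_mult = np.array([params.specialties[c].dow_mult for c in codes])  # (S, 7)
        counts = np.zeros((len(dates), len(codes)), dtype=np.int64)
        for i, d in enumerate(dates):
            p = weights * dow_mult[:, d.weekday()]
            p = p / p.sum()
            n = int(overall[i])
            if params.noise == "none":
                counts[i] = _largest_remainder(n, p)
            else:
                counts[i] = rng.multinomial(n, p)
        for j, code in enumerate(codes):
            out[code] = DailyDemandSeries.from_values(code, start, counts[:, j])
    return out


def _largest_remainder(n: int, p: np.ndarray) -> np.ndarray:
    """Deterministic integer apportionment of ``n`` by proportions ``p``."""
    raw = n * p
    base = np.floor(raw).astype(np.int64)
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# holiday calendar and canned scenarios


def _first_weekday_of(year: int, month: int, weekday: int) -> dt.date:
    d = dt.date(year, month, 1)
    return d + dt.timedelta(days=(weekday - d.weekday()) % 7)


def _last_weekday_of(year: int, month: int, weekday: int) -> dt.date:
    nxt = dt.date(year + (month == 12), month % 12 + 1, 1)
    d = nxt - dt.timedelta(days=1)
    return d - dt.timedelta(days=(d.weekday() - weekday) % 7)


def synthetic_holidays(years: Iterable[int], region: str = "synthetic-AU") -> HolidayCalendar:
    """An Australian-style public-holiday calendar, ~10 holidays per year:
    fixed dates plus Easter (computed) and two Monday holidays."""
    dates: set[dt.date] = set()
    for y in years:
        e = easter.easter(y)
        dates.update(
            {
                dt.date(y, 1, 1),
                dt.date(y, 1, 26),
                _first_weekday_of(y, 3, 0),  # Labour-day-like Monday
                e - dt.timedelta(days=2),  # Good Friday
                e + dt.timedelta(days=1),  # Easter Monday
                dt.date(y, 4, 25),
                _first_weekday_of(y, 6, 0),  # June Monday holiday
                _last_weekday_of(y, 9, 0),  # September Monday holiday
                dt.date(y, 12, 25),
                dt.date(y, 12, 26),
            }
        )
    return HolidayCalendar(frozenset(dates), region)


def _weekday_only_params(seed: int = 1) -> GeneratorParams:
    # noiseless, weekday-determined, integer rates: every same-weekday day has
    # an identical count, so a calendar-matched forecaster is exact.
    means = {
        DayType.MON: 80.0,
        DayType.TUE: 82.0,
        DayType.WED: 84.0,
        DayType.THU: 86.0,
        DayType.FRI: 94.0,
        DayType.SAT: 20.0,
        DayType.SUN: 20.0,
        DayType.PUBLIC_HOLIDAY: 20.0,
    }
    return GeneratorParams(
        baseline=1.0,
        day_type_multipliers=means,
        seasonal_amplitude=0.0,
        noise="none",
        elective_share={t: (0.0 if t.is_weekend or t is DayType.PUBLIC_HOLIDAY else 0.5)
                        for t in DayType},
        specialties={},
        seed=seed,
    )


@dataclass(frozen=True)
class Scenario:
    name: str
    start: dt.date
    end: dt.date
    holiday_years: tuple[int, ...]
    make_params: "staticmethod"
    include_specialties: bool = False


def _calibrated_params(seed: int = 1) -> GeneratorParams:
    return GeneratorParams(seed=seed)


def _shock_params(seed: int = 1) -> GeneratorParams:
    return GeneratorParams(
        seed=seed,
        shocks=(ShockInterval(dt.date(2020, 4, 1), dt.date(2020, 4, 30), 0.3),),
    )


SCENARIOS: dict[str, Scenario] = {
    "WEEKDAY_ONLY": Scenario(
        "WEEKDAY_ONLY",
        dt.date(2016, 1, 1),
        dt.date(2019, 12, 31),
        holiday_years=(),
        make_params=staticmethod(_weekday_only_params),
    ),
    "CALIBRATED_DEFAULT": Scenario(
        "CALIBRATED_DEFAULT",
        dt.date(2016, 1, 1),
        dt.date(2019, 12, 31),
        holiday_years=tuple(range(2016, 2020)),
        make_params=staticmethod(_calibrated_params),
    ),
    "PANDEMIC_SHOCK": Scenario(
        "PANDEMIC_SHOCK",
        dt.date(2016, 1, 1),
        dt.date(2020, 6, 30),
        holiday_years=tuple(range(2016, 2021)),
        make_params=staticmethod(_shock_params),
    ),
    "SPECIALTY_SPLIT": Scenario(
        "SPECIALTY_SPLIT",
        dt.date(2016, 1, 1),
        dt.date(2019, 12, 31),
        holiday_years=tuple(range(2016, 2020)),
        make_params=staticmethod(_calibrated_params),
        include_specialties=True,
    ),
}


def scenario_data(
    name: str, seed: int = 1
) -> tuple[GeneratorParams, HolidayCalendar, dict[str, DailyDemandSeries]]:
    """In-memory version of :func:`make_fixture`: params, holidays and series."""
    if name not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]
    params = sc.make_params(seed=seed)
    holidays = synthetic_holidays(sc.holiday_years)
    series = sample_series(params, sc.start, sc.end, holidays,
                           include_specialties=sc.include_specialties)
    return params, holidays, series


def make_fixture(name: str, out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write the named scenario's demand CSV, holiday CSV and parameter file.

    Returns the paths under keys ``demand``, ``holidays`` and ``params``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params, holidays, series = scenario_data(name, seed=seed)
    demand_path = out_dir / "demand.csv"
    holiday_path = out_dir / "holidays.csv"
    params_path = out_dir / "params.json"
    write_series(list(series.values()), demand_path)
    holidays.write_csv(holiday_path)
    params_path.write_text(json.dumps(_params_to_jsonable(params), indent=2))
    return {"demand": demand_path, "holidays": holiday_path, "params": params_path}


def _params_to_jsonable(params: GeneratorParams) -> dict:
    d = dataclasses.asdict(params)
    d["day_type_multipliers"] = {k.value: v for k, v in params.day_type_multipliers.items()}
    d["elective_share"] = {k.value: v for k, v in params.elective_share.items()}
    d["specialties"] = {
        code: {"weight": p.weight, "dow_mult": list(p.dow_mult)}
        for code, p in params.specialties.items()
    }
    d["shocks"] = [
        {"start": s.start.isoformat(), "end": s.end.isoformat(), "multiplier": s.multiplier}
        for s in params.shocks
    ]
    d["origin"] = params.origin.isoformat()
    return d


def oracle_model(params: GeneratorParams, holidays: HolidayCalendar | None = None):
    """A benchmark model that forecasts the generator's true mean rate.

    Usable as a callable model in :func:`surgecast.evaluation.run_benchmark`;
    it represents the irreducible-error reference any estimator is compared
    against on synthetic data.
    """

    def forecast(training, dates, _holidays=None):
        return {d: expected_rate(d, params, holidays) for d in dates}

    return forecast
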