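"""Calendar arithmetic and day classification.

Daily surgical demand is driven almost entirely by the calendar: which weekday
a date falls on, whether it is a public holiday, and where it sits in the year.
This module provides the three primitives everything else builds on:

* :func:`day_type` — classify a date as one of the seven weekdays or as a
  public holiday (the holiday classification overrides the weekday, i.e. a
  holiday Monday is ``PUBLIC_HOLIDAY``, not ``MON``);
* :func:`corresponding_day` — map a future day of interest onto the date with
  the same day-of-week and (approximately) the same week-of-year in a
  preceding year;
* :func:`weekly_neighbors` — enumerate the same-weekday dates in a window of
  whole weeks around an anchor date.

Dates are plain :class:`datetime.date` values in the proleptic Gregorian
calendar; differences in whole days are therefore exact.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, ValidationError

__all__ = [
    "DayType",
    "CorrespondenceMode",
    "Direction",
    "HolidayCalendar",
    "day_type",
    "corresponding_day",
    "weekly_neighbors",
]


class DayType(enum.Enum):
    """Day classification: the seven weekdays plus public holiday.

    ``PUBLIC_HOLIDAY`` is an eighth, mutually exclusive category: exactly one
    value applies to any date under a given holiday calendar.
    """

    MON = "MON"
    TUE = "TUE"
    WED = "WED"
    THU = "THU"
    FRI = "FRI"
    SAT = "SAT"
    SUN = "SUN"
    PUBLIC_HOLIDAY = "PUBLIC_HOLIDAY"

    @property
    def is_weekend(self) -> bool:
        return self in (DayType.SAT, DayType.SUN)


_WEEKDAY_TYPES = (
    DayType.MON,
    DayType.TUE,
    DayType.WED,
    DayType.THU,
    DayType.FRI,
    DayType.SAT,
    DayType.SUN,
)


class CorrespondenceMode(enum.Enum):
    """How "same day of week and week of year, one year earlier" is realized.

    ``WEEKDAY_364`` subtracts 364 days (52 whole weeks) per lag year, which
    preserves the weekday exactly and the week-of-year approximately — the
    corresponding date's month and day drift by one or two days per year.
    ``ISO_WEEK`` keeps the ISO week number and ISO weekday and decrements the
    ISO year; when the target year has no week 53, week 52 is used instead.
    """

    WEEKDAY_364 = "WEEKDAY_364"
    ISO_WEEK = "ISO_WEEK"


class Direction(enum.Enum):
    """Window orientation for :func:`weekly_neighbors`."""

    BEFORE = "BEFORE"
    SYMMETRIC = "SYMMETRIC"


@dataclass(frozen=True)
class HolidayCalendar:
    """A set of public-holiday dates with an optional region label.

    The calendar is always an explicit input (typically a CSV file), never
    derived from a locale library at run time, so that runs are reproducible
    across regions and library versions.
    """

    dates: frozenset[dt.date] = field(default_factory=frozenset)
    region: str = ""

    def __contains__(self, date: dt.date) -> bool:
        return date in self.dates

    def __len__(self) -> int:
        return len(self.dates)

    def between(self, start: dt.date, end: dt.date) -> list[dt.date]:
        """Holidays in the closed interval [start, end], sorted."""
        return sorted(d for d in self.dates if start <= d <= end)

    @classmethod
    def empty(cls) -> "HolidayCalendar":
        return cls(frozenset())

    @classmethod
    def from_dates(cls, dates: Iterable[dt.date], region: str = "") -> "HolidayCalendar":
        return cls(frozenset(dates), region)

    @classmethod
    def read_csv(cls, path: str | Path, region: str = "") -> "HolidayCalendar":
        """Read a ``date,name`` CSV (ISO 8601 dates, UTF-8)."""
        path = Path(path)
        dates: set[dt.date] = set()
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "date" not in reader.fieldnames:
                raise ValidationError(
                    f"{path}: holiday CSV must have a 'date' column (header 'date,name')"
                )
            for i, row in enumerate(reader, start=2):
                try:
                    d = dt.date.fromisoformat(row["date"].strip())
                except ValueError as exc:
                    raise ValidationError(f"{path} row {i}: invalid date {row['date']!r}") from exc
                if d in dates:
                    raise ValidationError(f"{path} row {i}: duplicate holiday date {d}")
                dates.add(d)
        return cls(frozenset(dates), region)

    def write_csv(self, path: str | Path, names: dict[dt.date, str] | None = None) -> None:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["date", "name"])
            for d in sorted(self.dates):
                writer.writerow([d.isoformat(), (names or {}).get(d, "public holiday")])


def day_type(date: dt.date, holidays: HolidayCalendar | None = None) -> DayType:
    """Classify ``date`` as a weekday or, if it is in ``holidays``, as a holiday."""
    if holidays is not None and date in holidays:
        return DayType.PUBLIC_HOLIDAY
    return _WEEKDAY_TYPES[date.weekday()]


def weekday_type(date: dt.date) -> DayType:
    """The plain weekday of ``date``, ignoring any holiday calendar."""
    return _WEEKDAY_TYPES[date.weekday()]


def corresponding_day(
    doi: dt.date,
    lag_years: int,
    mode: CorrespondenceMode = CorrespondenceMode.WEEKDAY_364,
) -> dt.date:
    """The date with the same weekday and approximate week-of-year ``lag_years`` back.

    Parameters
    ----------
    doi:
        The day of interest.
    lag_years:
        Number of years to step back; must be >= 1.
    mode:
        See :class:`CorrespondenceMode`.
    """
    if lag_years < 1:
        raise ConfigurationError(f"lag_years must be >= 1, got {lag_years}")
    if mode is CorrespondenceMode.WEEKDAY_364:
        return doi - dt.timedelta(days=364 * lag_years)
    if mode is CorrespondenceMode.ISO_WEEK:
        iso = doi.isocalendar()
        target_year = iso[0] - lag_years
        week = iso[1]
        try:
            return dt.date.fromisocalendar(target_year, week, iso[2])
        except ValueError:
            # week-53 DOI, target year has 52 weeks: fall back to the nearest
            # existing week.
            return dt.date.fromisocalendar(target_year, 52, iso[2])
    raise ConfigurationError(f"unknown correspondence mode {mode!r}")


def weekly_neighbors(
    anchor: dt.date,
    theta: int,
    direction: Direction = Direction.SYMMETRIC,
) -> list[dt.date]:
    """Same-weekday dates in a window of ``theta`` whole weeks around ``anchor``.

    ``SYMMETRIC`` returns ``anchor + 7j`` for ``j = -theta..+theta`` (the anchor
    included, ``2*theta + 1`` dates, ascending). ``BEFORE`` returns
    ``anchor - 7j`` for ``j = 1..theta`` (the anchor excluded, ``theta`` dates,
    most recent first). All returned dates share the anchor's weekday.
    """
    if theta < 0:
        raise ConfigurationError(f"theta must be >= 0, got {theta}")
    if direction is Direction.SYMMETRIC:
        return [anchor + dt.timedelta(days=7 * j) for j in range(-theta, theta + 1)]
    if direction is Direction.BEFORE:
        return [anchor - dt.timedelta(days=7 * j) for j in range(1, theta + 1)]
    raise ConfigurationError(f"unknown direction {direction!r}")
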