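"""Calendar feature construction for the regression forecasters.

Each calendar day is encoded as:

* ``t`` — a relative day index, whole days since the training origin, which
  carries the sequential order (and any trend) of the series;
* a day-type indicator — one-hot over eight mutually exclusive categories,
  the seven weekdays plus ``PUBLIC_HOLIDAY`` (a holiday overrides its
  weekday);
* first-order Fourier seasonal terms ``sin(2*pi*t/m)`` and ``cos(2*pi*t/m)``
  with seasonal period ``m`` (default 365 days). Only the first harmonic is
  used.

The eight indicators sum to one on every row, so design matrices are built
without a separate intercept column.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calendar import DayType, HolidayCalendar, day_type
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SeasonalityConfig",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "build_feature_vector",
    "design_matrix",
]

DAY_TYPE_ORDER = [t.value for t in DayType]

FEATURE_COLUMNS = ["t", *DAY_TYPE_ORDER, "season_sin", "season_cos"]


@dataclass(frozen=True)
class SeasonalityConfig:
    """Seasonal period in days for the Fourier terms (365 = annual)."""

    m: int = 365

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigurationError(f"seasonal period m must be >= 2, got {self.m}")


@dataclass(frozen=True)
class FeatureVector:
    """The regression features of a single calendar day."""

    t: int
    day_type: DayType
    season_sin: float
    season_cos: float

    def as_array(self) -> np.ndarray:
        onehot = [1.0 if self.day_type.value == name else 0.0 for name in DAY_TYPE_ORDER]
        return np.array([float(self.t), *onehot, self.season_sin, self.season_cos])


def build_feature_vector(
    date: dt.date,
    origin: dt.date,
    holidays: HolidayCalendar | None = None,
    season: SeasonalityConfig = SeasonalityConfig(),
) -> FeatureVector:
    """Feature vector for ``date`` relative to a training ``origin`` (t = 0)."""
    if date < origin:
        raise ValidationError(f"date {date} precedes the feature origin {origin}")
    t = (date - origin).days
    angle = 2 * math.pi * t / season.m
    return FeatureVector(
        t=t,
        day_type=day_type(date, holidays),
        season_sin=math.sin(angle),
        season_cos=math.cos(angle),
    )


def design_matrix(
    dates: Sequence[dt.date] | Iterable[dt.date],
    origin: dt.date,
    holidays: HolidayCalendar | None = None,
    season: SeasonalityConfig = SeasonalityConfig(),
) -> pd.DataFrame:
    """Row-per-day feature matrix with columns :data:`FEATURE_COLUMNS`."""
    rows = [build_feature_vector(d, origin, holidays, season).as_array() for d in dates]
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(FEATURE_COLUMNS))),
                        columns=FEATURE_COLUMNS)
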