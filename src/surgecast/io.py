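"""Daily demand series container and CSV I/O.

The unit of analysis is a *stream*: one daily count time series, e.g. all
surgeries ("overall"), emergency-only, elective-only, or a single clinical
specialty (ORT, GES, GAS, ...). A demand CSV holds any number of streams in
long format with header ``date,stream,count``.

Counts are surgeries per day: nonnegative integers on a contiguous date range.
Dates missing from the file are zero-filled with a warning — hospital extracts
typically omit zero-activity days, and weekend elective counts genuinely are
zero.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EMERGENCY",
    "ELECTIVE",
    "OVERALL",
    "DailyDemandSeries",
    "read_series",
    "write_series",
    "slice_series",
]

logger = logging.getLogger(__name__)

EMERGENCY = "emergency"
ELECTIVE = "elective"
OVERALL = "overall"

#: Specialty codes used by the synthetic generator and accepted anywhere a
#: stream label is; arbitrary free-text codes are also allowed.
SPECIALTY_CODES = ("ORT", "GES", "GAS", "PLA", "OBS", "VAS", "BUR", "URO", "CTS", "GYN")


@dataclass
class DailyDemandSeries:
    """A contiguous dated sequence of nonnegative integer daily counts.

    ``counts`` is a pandas Series indexed by a daily :class:`pandas.DatetimeIndex`
    with integer values. Every date between ``start`` and ``end`` has an entry
    (possibly 0).
    """

    stream: str
    counts: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValidationError(f"stream {self.stream!r}: empty series is invalid")
        idx = pd.DatetimeIndex(self.counts.index)
        if not idx.is_monotonic_increasing:
            idx_sorted = idx.sort_values()
            self.counts = self.counts.reindex(idx_sorted)
            idx = idx_sorted
        expected = pd.date_range(idx[0], idx[-1], freq="D")
        if len(idx) != len(expected) or not (idx == expected).all():
            raise ValidationError(
                f"stream {self.stream!r}: date range not contiguous "
                f"({idx[0].date()}..{idx[-1].date()} should hold {len(expected)} days, "
                f"got {len(idx)})"
            )
        values = np.asarray(self.counts.values)
        if not np.issubdtype(values.dtype, np.integer):
            as_int = values.astype(np.int64)
            if not np.array_equal(as_int, values):
                raise ValidationError(f"stream {self.stream!r}: counts must be integers")
            values = as_int
        if (values < 0).any():
            bad = idx[values < 0][0].date()
            raise ValidationError(f"stream {self.stream!r}: negative count on {bad}")
        self.counts = pd.Series(values.astype(np.int64), index=expected)

    # -- basic accessors ---------------------------------------------------
    @property
    def start(self) -> dt.date:
        return self.counts.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.counts.index[-1].date()

    def __len__(self) -> int:
        return len(self.counts)

    def covers(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def count_on(self, date: dt.date) -> int:
        """Count on ``date``; raises KeyError outside the covered range."""
        if not self.covers(date):
            raise KeyError(f"{date} outside series range {self.start}..{self.end}")
        return int(self.counts.loc[pd.Timestamp(date)])

    def dates(self) -> list[dt.date]:
        return [ts.date() for ts in self.counts.index]

    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DailyDemandSeries):
            return NotImplemented
        return self.stream == other.stream and self.counts.equals(other.counts)

    @classmethod
    def from_dict(cls, stream: str, counts: dict[dt.date, int]) -> "DailyDemandSeries":
        ser = pd.Series(
            {pd.Timestamp(d): int(c) for d, c in counts.items()}, dtype=np.int64
        ).sort_index()
        return cls(stream, ser)

    @classmethod
    def from_values(
        cls, stream: str, start: dt.date, values: "np.ndarray | list[int]"
    ) -> "DailyDemandSeries":
        idx = pd.date_range(pd.Timestamp(start), periods=len(values), freq="D")
        return cls(stream, pd.Series(np.asarray(values), index=idx))


def read_series(path: str | Path) -> list[DailyDemandSeries]:
    """Read a ``date,stream,count`` CSV into one series per distinct stream.

    Gaps inside each stream's date range are filled with 0 and logged as a
    warning. Negative or non-integer counts and duplicate (date, stream) rows
    are validation errors naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"stream": str}, keep_default_na=False)
    required = {"date", "stream", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected header date,stream,count, got {list(df.columns)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except ValueError as exc:
        raise ValidationError(f"{path}: unparseable ISO date: {exc}") from exc
    counts_numeric = pd.to_numeric(df["count"], errors="coerce")
    bad = counts_numeric.isna() | (counts_numeric != counts_numeric.round()) | (counts_numeric < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 2  # header is row 1
        raise ValidationError(
            f"{path} row {row}: count must be a nonnegative integer, got {df['count'].iloc[row - 2]!r}"
        )
    df["count"] = counts_numeric.astype(np.int64)
    dupes = df.duplicated(subset=["date", "stream"])
    if dupes.any():
        row = int(np.flatnonzero(dupes.values)[0]) + 2
        d = df["date"].iloc[row - 2].date()
        raise ValidationError(f"{path} row {row}: duplicate entry for ({d}, {df['stream'].iloc[row - 2]})")

    out: list[DailyDemandSeries] = []
    for stream, grp in df.groupby("stream", sort=True):
        ser = grp.set_index("date")["count"].sort_index()
        full = pd.date_range(ser.index[0], ser.index[-1], freq="D")
        if len(full) != len(ser):
            missing = full.difference(ser.index)
            logger.warning(
                "%s stream %r: %d missing date(s) zero-filled (first: %s)",
                path, stream, len(missing), missing[0].date(),
            )
            ser = ser.reindex(full, fill_value=0)
        out.append(DailyDemandSeries(str(stream), ser))
    return out


def read_single_series(path: str | Path, stream: str) -> DailyDemandSeries:
    """Read one named stream from a demand CSV."""
    for s in read_series(path):
        if s.stream == stream:
            return s
    raise ValidationError(f"{path}: stream {stream!r} not found")


def write_series(
    series: DailyDemandSeries | list[DailyDemandSeries], path: str | Path
) -> None:
    """Write one or more series to a ``date,stream,count`` CSV (round-trippable)."""
    if isinstance(series, DailyDemandSeries):
        series = [series]
    if not series:
        raise ValidationError("nothing to write: empty series list")
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "date": [d.isoformat() for d in s.dates()],
                    "stream": s.stream,
                    "count": s.counts.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def slice_series(series: DailyDemandSeries, start: dt.date, end: dt.date) -> DailyDemandSeries:
    """Contiguous sub-series over [start, end], inclusive on both ends."""
    if start > end:
        raise ValidationError(f"slice start {start} after end {end}")
    if not (series.covers(start) and series.covers(end)):
        raise ValidationError(
            f"slice {start}..{end} outside series range {series.start}..{series.end}"
        )
    sub = series.counts.loc[pd.Timestamp(start) : pd.Timestamp(end)]
    return DailyDemandSeries(series.stream, sub.copy())
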