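"""Reading, writing and reshaping DAM-style activity monitor records.

Trikinetics DAM monitors count infrared-beam crossings per channel in fixed
time bins (typically 5 min) and write one tab-separated row per bin for all
32 channels of a monitor.  This module parses that dialect into
:class:`ActivitySeries` objects, rebins counts to coarser intervals, maps
clock time onto Zeitgeber time (ZT, hours since lights-on), and splits a
recording into its entrained (LD) and free-running (DD) segments.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "LightSchedule",
    "ChannelMap",
    "DamDialect",
    "DamParseError",
    "parse_monitor_file",
    "write_monitor_file",
    "rebin",
    "to_zt",
    "split_regimes",
    "long_format",
]


class DamParseError(ValueError):
    """Raised when a monitor file does not conform to the expected dialect."""


@dataclass(frozen=True)
class DamDialect:
    """Column layout of a DAM text file.

    The DAMSystem3 default is 42 tab-separated columns: reading index, date
    (``"dd mon yy"``), time (``"HH:MM:SS"``), machine status, six metadata
    columns (including the on-board light sensor), then 32 channel counts.
    """

    n_meta: int = 6
    n_channels: int = 32
    valid_status: int = 1
    date_format: str = "%d %b %y"
    #: "drop" silently excludes rows with an invalid status; "keep" retains
    #: them; "error" aborts parsing.
    status_policy: str = "drop"

    @property
    def n_columns(self) -> int:
        return 4 + self.n_meta + self.n_channels

    @property
    def first_count_column(self) -> int:
        return 4 + self.n_meta


DEFAULT_DIALECT = DamDialect()


@dataclass
class ActivitySeries:
    """One channel's beam-crossing counts on a regular time grid.

    Timestamps label the *start* of each bin; bins are half-open
    ``[t, t + bin_width)``.
    """

    channel_id: int
    timestamps: np.ndarray  # datetime64[ns], strictly increasing, even grid
    counts: np.ndarray  # non-negative integers
    bin_width: float  # minutes

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.counts = np.asarray(self.counts)
        if self.channel_id < 1:
            raise ValueError(f"channel_id must be >= 1, got {self.channel_id}")
        if self.timestamps.shape != self.counts.shape:
            raise ValueError("timestamps and counts must have equal length")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps)
            expected = np.timedelta64(int(round(self.bin_width * 60_000)), "ms")
            if np.any(steps != expected):
                raise ValueError(
                    "timestamps must be strictly increasing with spacing "
                    f"equal to bin_width ({self.bin_width} min)"
                )

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def start(self) -> datetime:
        return pd.Timestamp(self.timestamps[0]).to_pydatetime()

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class LightSchedule:
    """Light regime of an experiment: LD entrainment followed by DD free run.

    ``lights_on`` is the clock time at which lights turn on during LD; it
    anchors ZT0 and continues to define (subjective) ZT0 during DD, where
    lights never come on.  ``start_date`` is the calendar date of the first
    lights-on, i.e. of experimental day 1.
    """

    lights_on: time = time(8, 0)
    ld_days: int = 4
    dd_days: int = 11
    photoperiod_hours: float = 12.0
    start_date: date = date(2024, 1, 1)

    def __post_init__(self) -> None:
        if self.ld_days < 0 or self.dd_days < 0 or self.ld_days + self.dd_days < 1:
            raise ValueError("need ld_days >= 0, dd_days >= 0, total >= 1 day")
        if not 0 < self.photoperiod_hours < 24:
            raise ValueError("photoperiod_hours must lie in (0, 24)")

    @property
    def n_days(self) -> int:
        return self.ld_days + self.dd_days

    @property
    def anchor(self) -> datetime:
        """First lights-on instant: experiment start, day 1, ZT0."""
        return datetime.combine(self.start_date, self.lights_on)

    def regime_of_day(self, day_index: int) -> str:
        return "LD" if day_index <= self.ld_days else "DD"


@dataclass
class ChannelMap:
    """Assignment of monitor channels to treatment groups."""

    treatment: dict[int, str] = field(default_factory=dict)
    include: dict[int, bool] = field(default_factory=dict)

    def assign(self, channel_id: int, treatment: str, include: bool = True) -> None:
        self.treatment[channel_id] = treatment
        self.include[channel_id] = include

    def included_channels(self) -> list[int]:
        return [c for c in sorted(self.treatment) if self.include.get(c, True)]

    def __getitem__(self, channel_id: int) -> str:
        return self.treatment[channel_id]


def _as_stream(source: TextIO | str) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    return _io.StringIO(source)


def parse_monitor_file(
    source: TextIO | str,
    dialect: DamDialect = DEFAULT_DIALECT,
) -> list[ActivitySeries]:
    """Parse one DAM monitor file into 32 (``dialect.n_channels``) series.

    Parameters
    ----------
    source:
        Open text stream, file path, or the file content itself.
    dialect:
        Column layout and row-status policy.

    Returns
    -------
    One :class:`ActivitySeries` per channel, in channel order (1-based ids).

    Raises
    ------
    DamParseError
        On a malformed row (wrong column count, non-integer count, bad
        date/time), non-monotonic timestamps, or an invalid status when the
        dialect's policy is ``"error"``.  Messages name the offending line.
    """
    if isinstance(source, str) and "\t" not in source and "\n" not in source:
        with open(source) as fh:
            return parse_monitor_file(fh, dialect)
    stream = _as_stream(source)

    timestamps: list[datetime] = []
    rows: list[list[int]] = []
    n_dropped = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != dialect.n_columns:
            raise DamParseError(
                f"line {lineno}: expected {dialect.n_columns} tab-separated "
                f"columns, found {len(parts)}"
            )
        try:
            status = int(parts[3])
        except ValueError as exc:
            raise DamParseError(f"line {lineno}: non-integer status {parts[3]!r}") from exc
        if status != dialect.valid_status:
            if dialect.status_policy == "drop":
                n_dropped += 1
                continue
            if dialect.status_policy == "error":
                raise DamParseError(f"line {lineno}: invalid status code {status}")
        try:
            ts = datetime.strptime(
                f"{parts[1]} {parts[2]}", f"{dialect.date_format} %H:%M:%S"
            )
        except ValueError as exc:
            raise DamParseError(
                f"line {lineno}: cannot parse date/time {parts[1]!r} {parts[2]!r}"
            ) from exc
        try:
            counts = [int(v) for v in parts[dialect.first_count_column :]]
        except ValueError as exc:
            raise DamParseError(f"line {lineno}: non-integer count value") from exc
        if any(c < 0 for c in counts):
            raise DamParseError(f"line {lineno}: negative count value")
        timestamps.append(ts)
        rows.append(counts)

    if not rows:
        raise DamParseError("no valid data rows found")
    ts_arr = np.array(timestamps, dtype="datetime64[ns]")
    if np.any(np.diff(ts_arr) <= np.timedelta64(0, "ns")):
        raise DamParseError("timestamps are not strictly increasing")
    steps = np.unique(np.diff(ts_arr)) if len(ts_arr) > 1 else np.array([])
    if len(steps) > 1:
        raise DamParseError("timestamps are not on a constant-width grid")
    bin_width = (
        float(steps[0] / np.timedelta64(1, "m")) if len(steps) == 1 else 5.0
    )
    matrix = np.array(rows, dtype=np.int64)
    series = [
        ActivitySeries(
            channel_id=ch + 1,
            timestamps=ts_arr,
            counts=matrix[:, ch],
            bin_width=bin_width,
        )
        for ch in range(dialect.n_channels)
    ]
    for s in series:
        s.n_dropped_rows = n_dropped  # type: ignore[attr-defined]
    return series


def write_monitor_file(
    series: Sequence[ActivitySeries],
    dest: TextIO | str,
    dialect: DamDialect = DEFAULT_DIALECT,
) -> None:
    """Write up to 32 channels back to DAM text, inverse of the parser.

    Channels must share one time grid; missing channels are zero-filled so
    the file always carries ``dialect.n_channels`` count columns.
    """
    if not series:
        raise ValueError("no series to write")
    if len(series) > dialect.n_channels:
        raise ValueError(f"at most {dialect.n_channels} channels per monitor file")
    grid = series[0].timestamps
    for s in series:
        if not np.array_equal(s.timestamps, grid):
            raise ValueError("all channels must share one time grid")
        if not 1 <= s.channel_id <= dialect.n_channels:
            raise ValueError(
                f"channel_id {s.channel_id} outside 1..{dialect.n_channels}"
            )
    matrix = np.zeros((len(grid), dialect.n_channels), dtype=np.int64)
    for s in series:
        matrix[:, s.channel_id - 1] = s.counts

    close = False
    if isinstance(dest, str):
        dest = open(dest, "w")
        close = True
    try:
        meta = ["0"] * dialect.n_meta
        for i, ts in enumerate(pd.DatetimeIndex(grid)):
            row = [
                str(i + 1),
                ts.strftime(dialect.date_format),
                ts.strftime("%H:%M:%S"),
                str(dialect.valid_status),
                *meta,
                *(str(v) for v in matrix[i]),
            ]
            dest.write("\t".join(row) + "\n")
    finally:
        if close:
            dest.close()


def rebin(series: ActivitySeries, factor: int, truncate: bool = False) -> ActivitySeries:
    """Sum ``factor`` consecutive bins into one coarser bin.

    The paper's pipeline records at 5 min and analyses at 30 min
    (``factor=6``).  Total counts are conserved exactly.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    n = len(series)
    remainder = n % factor
    if remainder and not truncate:
        raise ValueError(
            f"series length {n} not divisible by factor {factor}; "
            "pass truncate=True to drop the trailing partial window"
        )
    usable = n - remainder
    counts = series.counts[:usable].reshape(-1, factor).sum(axis=1)
    timestamps = series.timestamps[:usable][::factor]
    return ActivitySeries(
        channel_id=series.channel_id,
        timestamps=timestamps,
        counts=counts,
        bin_width=series.bin_width * factor,
    )


def to_zt(
    timestamp: datetime | np.datetime64, schedule: LightSchedule
) -> tuple[int, float]:
    """Map a clock timestamp to (day index, Zeitgeber time).

    ZT is hours elapsed since the most recent (possibly subjective)
    lights-on anchor; the day index counts 24-h cycles from experiment
    start, beginning at 1.
    """
    ts = pd.Timestamp(timestamp).to_pydatetime()
    elapsed = (ts - schedule.anchor).total_seconds() / 3600.0
    if elapsed < 0:
        raise ValueError(f"timestamp {ts} precedes experiment start {schedule.anchor}")
    day = int(elapsed // 24) + 1
    zt = elapsed - (day - 1) * 24.0
    return day, zt


def _zt_vector(series: ActivitySeries, schedule: LightSchedule) -> tuple[np.ndarray, np.ndarray]:
    elapsed = (series.timestamps - np.datetime64(schedule.anchor, "ns")) / np.timedelta64(
        1, "h"
    )
    if np.any(elapsed < -1e-9):
        raise ValueError("series starts before the experiment's first lights-on")
    days = (elapsed // 24).astype(int) + 1
    zt = elapsed - (days - 1) * 24.0
    return days, zt


def split_regimes(
    series: ActivitySeries, schedule: LightSchedule
) -> tuple[ActivitySeries, ActivitySeries]:
    """Partition a series into its LD (days 1..ld_days) and DD segments."""
    days, _ = _zt_vector(series, schedule)
    if days.max(initial=0) < schedule.n_days:
        raise ValueError(
            f"series spans {days.max(initial=0)} days; schedule requires "
            f"{schedule.n_days}"
        )
    in_ld = days <= schedule.ld_days

    def _segment(mask: np.ndarray) -> ActivitySeries:
        seg = ActivitySeries.__new__(ActivitySeries)
        seg.channel_id = series.channel_id
        seg.timestamps = series.timestamps[mask]
        seg.counts = series.counts[mask]
        seg.bin_width = series.bin_width
        return seg

    return _segment(in_ld), _segment(~in_ld)


def long_format(
    series_list: Iterable[ActivitySeries],
    schedule: LightSchedule,
    channel_map: ChannelMap | None = None,
) -> pd.DataFrame:
    """Normalized long table: channel, timestamp, day, ZT, regime, count."""
    frames = []
    for s in series_list:
        days, zt = _zt_vector(s, schedule)
        frames.append(
            pd.DataFrame(
                {
                    "channel": s.channel_id,
                    "timestamp": s.timestamps,
                    "day": days,
                    "zt": zt,
                    "regime": np.where(days <= schedule.ld_days, "LD", "DD"),
                    "count": s.counts,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if channel_map is not None:
        out["treatment"] = out["channel"].map(channel_map.treatment)
    return out
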