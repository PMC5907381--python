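"""William's-mean daily activity profiles and per-individual activity totals.

Activity counts are heavily skewed with many zeros, so daily profiles are
averaged with the William's mean — the back-transformed arithmetic mean of
log(n + 1) — rather than the arithmetic mean.  Two averaging paths exist:

* per individual: William's mean across days (default 2-4) at each 30-min
  ZT bin, used for individual-level peak parameters (E1, E2, PMI);
* per group: William's mean across individuals within each day, then an
  arithmetic mean across days, used for the group's plotted average profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ActivitySeries, LightSchedule, _zt_vector

__all__ = [
    "DailyProfile",
    "ActivityTotals",
    "williams_mean",
    "individual_profile",
    "group_profile",
    "activity_totals",
    "profile_table",
]

DEFAULT_DAYS = (2, 3, 4)


@dataclass
class DailyProfile:
    """Average activity over one 24-h cycle on a fixed ZT bin grid.

    ``zt_bins`` are bin-start labels (0.0, 0.5, ..., 23.5 for 30-min bins),
    ``values`` the William's-mean activity per bin, ``sem`` the per-bin
    standard error across the averaged units (None when only one unit).
    """

    zt_bins: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    n_units: int = 1

    def __post_init__(self) -> None:
        self.zt_bins = np.asarray(self.zt_bins, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.zt_bins.shape != self.values.shape:
            raise ValueError("zt_bins and values must have equal length")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.zt_bins)

    def value_at(self, zt: float) -> float:
        idx = np.flatnonzero(np.isclose(self.zt_bins, zt))
        if len(idx) != 1:
            raise KeyError(f"no bin with start ZT {zt}")
        return float(self.values[idx[0]])


@dataclass
class ActivityTotals:
    """Per-individual activity totals: LD, DD, overall, and DD fraction.

    ``prop_dd`` is NaN when the individual has no activity at all (the
    fraction is then undefined and the individual is excluded from group
    statistics on this parameter).
    """

    channel_id: int
    ta_ld: int
    ta_dd: int

    @property
    def ta(self) -> int:
        return self.ta_ld + self.ta_dd

    @property
    def prop_dd(self) -> float:
        if self.ta == 0:
            return float("nan")
        return self.ta_dd / self.ta


def williams_mean(values: Sequence[float] | np.ndarray) -> float:
    """William's mean: exp(mean(ln(v + 1))) - 1.

    A geometric-style average that tolerates zeros and damps the influence
    of occasional very large counts; never exceeds the arithmetic mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("williams_mean of an empty sequence is undefined")
    if np.any(arr < 0):
        raise ValueError("williams_mean requires non-negative values")
    return float(np.expm1(np.mean(np.log1p(arr))))


def _binned_days(
    series: ActivitySeries, schedule: LightSchedule, days: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Return (zt_bins, matrix) with one row per requested day.

    The series must already be at the analysis bin width (e.g. 30 min after
    rebinning); each row holds that day's counts in ZT-bin order.
    """
    day_vec, zt_vec = _zt_vector(series, schedule)
    bins_per_day = int(round(24 * 60 / series.bin_width))
    zt_bins = np.arange(bins_per_day) * (series.bin_width / 60.0)
    matrix = np.empty((len(days), bins_per_day), dtype=float)
    for i, d in enumerate(days):
        mask = day_vec == d
        if mask.sum() != bins_per_day:
            raise ValueError(
                f"day {d} has {int(mask.sum())} bins, expected {bins_per_day} "
                "(day missing or incomplete)"
            )
        order = np.argsort(zt_vec[mask])
        matrix[i] = series.counts[mask][order]
    return zt_bins, matrix


def individual_profile(
    series: ActivitySeries,
    schedule: LightSchedule,
    days: Sequence[int] = DEFAULT_DAYS,
) -> DailyProfile:
    """One individual's William's-mean daily profile across the given days.

    Day 1 is excluded by default: animals are still adapting to the tubes.
    """
    if len(days) == 0:
        raise ValueError("need at least one day")
    zt_bins, matrix = _binned_days(series, schedule, days)
    values = np.expm1(np.mean(np.log1p(matrix), axis=0))
    return DailyProfile(zt_bins=zt_bins, values=values, n_units=len(days))


def group_profile(
    series_list: Iterable[ActivitySeries],
    schedule: LightSchedule,
    days: Sequence[int] = DEFAULT_DAYS,
    sem: bool = True,
) -> DailyProfile:
    """Group average profile: William's mean across individuals per day,
    then arithmetic mean across days.

    Error bars (``sem``) are the standard error across individuals of the
    per-individual day-averaged profiles.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one individual")
    per_day = []  # (n_days, n_bins) William's mean across individuals
    per_indiv = []  # (n_indiv, n_bins) day-averaged individual profiles
    zt_bins = None
    day_stack = []
    for s in series_list:
        zt, matrix = _binned_days(s, schedule, days)
        if zt_bins is None:
            zt_bins = zt
        elif not np.array_equal(zt, zt_bins):
            raise ValueError("individuals are on mismatched bin grids")
        day_stack.append(matrix)
        per_indiv.append(np.expm1(np.mean(np.log1p(matrix), axis=0)))
    stack = np.stack(day_stack)  # (n_indiv, n_days, n_bins)
    per_day = np.expm1(np.mean(np.log1p(stack), axis=0))  # (n_days, n_bins)
    values = per_day.mean(axis=0)
    sem_arr = None
    if sem and len(series_list) > 1:
        sem_arr = np.std(np.stack(per_indiv), axis=0, ddof=1) / np.sqrt(
            len(series_list)
        )
    return DailyProfile(
        zt_bins=zt_bins, values=values, sem=sem_arr, n_units=len(series_list)
    )


def activity_totals(
    series: ActivitySeries, schedule: LightSchedule
) -> ActivityTotals:
    """Total activity in LD and DD for one individual (whole-regime sums)."""
    day_vec, _ = _zt_vector(series, schedule)
    in_ld = day_vec <= schedule.ld_days
    return ActivityTotals(
        channel_id=series.channel_id,
        ta_ld=int(series.counts[in_ld].sum()),
        ta_dd=int(series.counts[~in_ld].sum()),
    )


def profile_table(profiles: dict[str, DailyProfile]) -> pd.DataFrame:
    """Long TSV-ready table (treatment, zt_bin, W, sem, n) of group profiles."""
    rows = []
    for treatment, p in profiles.items():
        sem = p.sem if p.sem is not None else np.full(len(p), np.nan)
        for zt, w, se in zip(p.zt_bins, p.values, sem):
            rows.append(
                {"treatment": treatment, "zt_bin": zt, "W": w, "sem": se, "n": p.n_units}
            )
    return pd.DataFrame(rows)
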