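"""Evening peak calling (E1/E2) and the Peak Matching Index.

Male mosquitoes show two evening activity bouts inside ZT8.5-ZT12: an early
peak (E1) and a later one (E2) that aligns with the female evening peak.
The Peak Matching Index

    PMI = (E2 - E1) / ((E1 + E2) / 2)

summarizes their balance in one dimensionless number in [-2, 2]: positive
when the later peak dominates, i.e. when the male's main evening activity
has shifted toward the female's peak time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profile import DailyProfile

__all__ = ["PeakCall", "detect_evening_peaks", "compute_pmi", "EVENING_WINDOW"]

#: Default evening search window (ZT hours, bin-start labels, inclusive).
EVENING_WINDOW = (8.5, 12.0)


@dataclass
class PeakCall:
    """E1/E2 magnitudes and phases plus the PMI for one individual.

    Phases are bin-start ZT values.  ``pmi`` is NaN when both magnitudes
    are zero (no evening activity: the index is undefined, not 0).
    """

    e1: float
    e1_phase: float
    e2: float
    e2_phase: float

    @property
    def pmi(self) -> float:
        if self.e1 == 0.0 and self.e2 == 0.0:
            return float("nan")
        return compute_pmi(self.e1, self.e2)


def compute_pmi(e1: float, e2: float) -> float:
    """(E2 - E1) / mean(E1, E2); antisymmetric, scale-invariant, in [-2, 2]."""
    if e1 < 0 or e2 < 0:
        raise ValueError("peak magnitudes must be non-negative")
    if e1 == 0 and e2 == 0:
        raise ValueError("PMI undefined when both peaks are zero")
    return 2.0 * (e2 - e1) / (e1 + e2)


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima using only in-window neighbours.

    An edge bin qualifies when it is >= its single neighbour, so a profile
    rising through the window peaks at the window's last bin.
    """
    n = len(values)
    if n == 1:
        return [0]
    out = []
    for i in range(n):
        left_ok = i == 0 or values[i] >= values[i - 1]
        right_ok = i == n - 1 or values[i] >= values[i + 1]
        if left_ok and right_ok:
            out.append(i)
    return out


def _prominences(values: np.ndarray, maxima: list[int]) -> list[float]:
    """Topographic prominence of each local maximum within the window."""
    proms = []
    for i in maxima:
        h = values[i]
        # lowest point before meeting a strictly higher bin, on each side
        left_min = h
        j = i - 1
        while j >= 0 and values[j] <= h:
            left_min = min(left_min, values[j])
            j -= 1
        left_base = left_min if j >= 0 else values[: i + 1].min()
        right_min = h
        j = i + 1
        while j < len(values) and values[j] <= h:
            right_min = min(right_min, values[j])
            j += 1
        right_base = right_min if j < len(values) else values[i:].min()
        proms.append(h - max(left_base, right_base))
    return proms


def detect_evening_peaks(
    profile: DailyProfile,
    window: tuple[float, float] = EVENING_WINDOW,
    require_local_max: bool = True,
) -> PeakCall:
    """Call E1 and E2 in the evening window of an individual's profile.

    E1 and E2 are the earliest and latest of the two most prominent local
    maxima in the window (prominence ties broken by magnitude, then by
    earlier phase).  If the window holds a single maximum it is assigned to
    the sub-window containing it (split at the window midpoint) and the
    other peak takes the plain maximum of its own sub-window.  With
    ``require_local_max=False`` the two sub-window maxima are reported
    directly.

    An all-zero window yields magnitudes 0 and an undefined (NaN) PMI.
    """
    lo, hi = window
    mask = (profile.zt_bins >= lo - 1e-9) & (profile.zt_bins <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"profile does not cover window [{lo}, {hi}]")
    zt = profile.zt_bins[mask]
    vals = profile.values[mask]
    if not (math.isclose(zt[0], lo) and math.isclose(zt[-1], hi)):
        raise ValueError("window bounds must lie on the profile's bin grid")

    midpoint = (lo + hi) / 2.0
    first = zt <= midpoint
    second = ~first

    def submax(sel: np.ndarray) -> tuple[float, float]:
        i = int(np.argmax(vals[sel]))
        return float(vals[sel][i]), float(zt[sel][i])

    if np.all(vals == 0):
        return PeakCall(0.0, float(zt[0]), 0.0, float(zt[-1]))

    if not require_local_max:
        (m1, p1), (m2, p2) = submax(first), submax(second)
        return PeakCall(m1, p1, m2, p2)

    maxima = _local_maxima(vals)
    proms = _prominences(vals, maxima)
    # rank: prominence desc, magnitude desc, earlier phase first
    order = sorted(range(len(maxima)), key=lambda k: (-proms[k], -vals[maxima[k]], zt[maxima[k]]))
    if len(maxima) >= 2:
        picked = sorted(maxima[k] for k in order[:2])
        i1, i2 = picked
        return PeakCall(float(vals[i1]), float(zt[i1]), float(vals[i2]), float(zt[i2]))

    # single local maximum: assign by sub-window, fill the other side
    i = maxima[0]
    if zt[i] <= midpoint:
        m2, p2 = submax(second)
        return PeakCall(float(vals[i]), float(zt[i]), m2, p2)
    m1, p1 = submax(first)
    return PeakCall(m1, p1, float(vals[i]), float(zt[i]))
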