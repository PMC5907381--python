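"""Synthetic DAM actogram cohorts with the structure the pipeline assumes.

The generator draws per-5-min beam-crossing counts from a Poisson (or
negative-binomial) distribution around a deterministic rate profile built
from the qualitative features of Aedes aegypti activity records:

* a sharp startle burst right after lights-on, present only under LD;
* low daytime baseline activity and a higher (subjective-)night level;
* a bimodal evening rise: two circular-Gaussian bumps (E1, E2) whose
  relative amplitude differs by treatment — roughly balanced for males
  alone, E2-dominant when a female is confined nearby, and strongly
  E2-dominant for females;
* a free-running rhythm in DD: the whole diurnal shape (minus the startle)
  shifts earlier by (24 - tau) hours on each successive DD day, so
  successive activity bouts are exactly tau apart (default tau = 23 h).

Bump centres sit mid-bin on the 30-min analysis grid (e.g. 10.75 for a
peak reported at bin ZT10.5), so the rebinned group profile peaks on the
intended bin label.  Per-individual total-amplitude heterogeneity is a
lognormal multiplier (CV configurable) mimicking the large between-animal
spread of real records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ActivitySeries, ChannelMap, LightSchedule

__all__ = [
    "Bump",
    "SimulationConfig",
    "PRESETS",
    "rate_function",
    "simulate_individual",
    "simulate_cohort",
]


@dataclass(frozen=True)
class Bump:
    """One circular-Gaussian activity bout on the 24-h cycle."""

    phase: float  # ZT hours of the bump centre
    amplitude: float  # extra expected counts per 5-min bin at the centre
    sigma: float  # hours

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("bump sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("bump amplitude must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Rates (expected counts per 5-min bin) and rhythm parameters."""

    schedule: LightSchedule = field(default_factory=LightSchedule)
    baseline_rate: float = 0.3
    night_rate: float = 1.2  # added from night_onset to ZT24 ((subjective) night)
    night_onset: float = 12.5  # after the evening bumps, which model early night
    startle_amplitude: float = 12.0
    startle_duration_min: float = 30.0
    bump1: Bump = Bump(10.75, 5.0, 0.45)
    bump2: Bump = Bump(12.25, 4.5, 0.45)
    tau: float = 23.0  # free-running period, hours
    dispersion: str = "poisson"  # "poisson" | "nb" | "none" (deterministic)
    nb_shape: float = 5.0  # gamma shape for the NB mixture (smaller = wider)
    amplitude_cv: float = 0.5  # lognormal CV of per-individual multiplier
    bin_width: float = 5.0  # minutes

    def __post_init__(self) -> None:
        if not 16.0 <= self.tau <= 32.0:
            raise ValueError("tau must lie in [16, 32] hours")
        for r in (self.baseline_rate, self.night_rate, self.startle_amplitude):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.dispersion not in ("poisson", "nb", "none"):
            raise ValueError(f"unknown dispersion {self.dispersion!r}")


def _amplitude_ratio(r: float, a1: float = 4.5) -> tuple[Bump, Bump]:
    return Bump(10.75, a1, 0.45), Bump(12.25, a1 * r, 0.45)


def _preset(r: float, a1: float) -> SimulationConfig:
    b1, b2 = _amplitude_ratio(r, a1)
    return SimulationConfig(bump1=b1, bump2=b2)


#: Treatment presets.  Only the evening-bump amplitudes (and thereby the
#: E2:E1 ratio r, hence the expected PMI ~ 2(r-1)/(r+1)) differ:
#: males alone are nearly balanced (r = 0.9, PMI ~ -0.1), males with a
#: confined female are E2-dominant (r = 1.5, PMI ~ 0.4), females strongly
#: so (r = 3, PMI ~ 1.0, evening maximum at bin ZT12.0 instead of ZT10.5).
PRESETS: dict[str, SimulationConfig] = {
    "males_alone": _preset(0.9, 5.0),
    "males_virgin_female": _preset(1.5, 4.5),
    "males_inseminated_female": _preset(1.5, 4.0),
    "females": _preset(3.0, 3.5),
}


def preset_amplitude_ratio(name: str) -> float:
    cfg = PRESETS[name]
    return cfg.bump2.amplitude / cfg.bump1.amplitude


def _circular_gaussian(zt: np.ndarray, bump: Bump) -> np.ndarray:
    d = np.abs((zt - bump.phase + 12.0) % 24.0 - 12.0)
    return bump.amplitude * np.exp(-0.5 * (d / bump.sigma) ** 2)


def rate_function(
    zt: float | np.ndarray,
    day: int,
    config: SimulationConfig,
    regime: str,
) -> np.ndarray:
    """Expected counts per 5-min bin at ZT on the given experimental day.

    Under LD the shape is anchored to the light cycle and includes the
    lights-on startle.  Under DD the startle disappears and every phase
    term evaluates at the drifted phase zt + d*(24 - tau), where d >= 1 is
    the DD day index, so a bump centred at phi occurs at zt = phi - d*(24 -
    tau): one hour earlier per day for tau = 23.
    """
    zt = np.asarray(zt, dtype=float)
    if regime not in ("LD", "DD"):
        raise ValueError(f"regime must be 'LD' or 'DD', got {regime!r}")
    if regime == "DD":
        d_dd = day - config.schedule.ld_days  # 1 for the first DD day
        phase = (zt + d_dd * (24.0 - config.tau)) % 24.0
    else:
        phase = zt % 24.0

    lam = np.full_like(phase, config.baseline_rate)
    lam += np.where(phase >= config.night_onset, config.night_rate, 0.0)
    lam += _circular_gaussian(phase, config.bump1)
    lam += _circular_gaussian(phase, config.bump2)
    if regime == "LD":
        dur_h = config.startle_duration_min / 60.0
        in_startle = zt % 24.0 < dur_h
        lam += np.where(
            in_startle, config.startle_amplitude * (1.0 - (zt % 24.0) / dur_h), 0.0
        )
    return np.clip(lam, 0.0, None)


def simulate_individual(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence = 0,
    channel_id: int = 1,
) -> ActivitySeries:
    """Draw one individual's full LD+DD recording at 5-min bins.

    The series starts at the first lights-on and spans ld_days + dd_days.
    With ``dispersion="none"`` counts are the rounded rate (noise-free
    limit); the per-individual amplitude multiplier is then fixed at 1.
    """
    sched = config.schedule
    rng = np.random.default_rng(seed)
    bins_per_day = int(round(24 * 60 / config.bin_width))
    n_days = sched.n_days
    zt_day = (np.arange(bins_per_day) + 0.0) * config.bin_width / 60.0

    lam = np.empty(n_days * bins_per_day)
    for day in range(1, n_days + 1):
        regime = "LD" if day <= sched.ld_days else "DD"
        sl = slice((day - 1) * bins_per_day, day * bins_per_day)
        lam[sl] = rate_function(zt_day, day, config, regime)

    deterministic = config.dispersion == "none"
    if not deterministic and config.amplitude_cv > 0:
        sigma = np.sqrt(np.log1p(config.amplitude_cv**2))
        lam = lam * rng.lognormal(-0.5 * sigma**2, sigma)

    if deterministic:
        counts = np.round(lam).astype(np.int64)
    elif config.dispersion == "poisson":
        counts = rng.poisson(lam)
    else:  # negative binomial via gamma-Poisson mixture
        counts = rng.poisson(rng.gamma(config.nb_shape, lam / config.nb_shape))

    start = np.datetime64(sched.anchor, "ns")
    step = np.timedelta64(int(config.bin_width * 60_000), "ms")
    timestamps = start + step * np.arange(len(lam))
    return ActivitySeries(
        channel_id=channel_id,
        timestamps=timestamps,
        counts=counts.astype(np.int64),
        bin_width=config.bin_width,
    )


def simulate_cohort(
    preset: str | SimulationConfig,
    n: int,
    seed: int = 0,
    treatment: str | None = None,
    schedule: LightSchedule | None = None,
) -> tuple[list[ActivitySeries], ChannelMap]:
    """Simulate n independent individuals of one treatment.

    Per-individual seeds are spawned deterministically from the cohort
    seed, so a cohort is byte-reproducible and individuals are independent.
    Channel ids run 1..n (ids above 32 span multiple monitor files when
    written to disk).
    """
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise KeyError(
                f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
            )
        config = PRESETS[preset]
        label = treatment or preset
    else:
        config = preset
        label = treatment or "treatment"
    if schedule is not None:
        config = replace(config, schedule=schedule)

    cmap = ChannelMap()
    series = []
    children = np.random.SeedSequence(seed).spawn(max(n, 1))
    for i in range(n):
        series.append(simulate_individual(config, children[i], channel_id=i + 1))
        cmap.assign(i + 1, label)
    return series, cmap
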