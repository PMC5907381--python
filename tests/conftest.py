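import numpy as np
import pytest
from hypothesis import settings

from damrhythm import ActivitySeries, LightSchedule

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def schedule() -> LightSchedule:
    """The standard experiment: 4 days LD 12:12 followed by 11 days DD."""
    return LightSchedule()


@pytest.fixture
def ld_only_schedule() -> LightSchedule:
    return LightSchedule(ld_days=4, dd_days=0)


def make_series(
    counts, schedule: LightSchedule | None = None, bin_width: float = 5.0, channel_id: int = 1
) -> ActivitySeries:
    """Series starting at the experiment's first lights-on."""
    sched = schedule or LightSchedule()
    start = np.datetime64(sched.anchor, "ns")
    step = np.timedelta64(int(bin_width * 60_000), "ms")
    n = len(counts)
    return ActivitySeries(
        channel_id=channel_id,
        timestamps=start + step * np.arange(n),
        counts=np.asarray(counts, dtype=np.int64),
        bin_width=bin_width,
    )


@pytest.fixture
def random_series(schedule) -> ActivitySeries:
    rng = np.random.default_rng(42)
    n = schedule.n_days * 288  # 15 days at 5-min bins
    return make_series(rng.poisson(2.0, size=n), schedule)
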