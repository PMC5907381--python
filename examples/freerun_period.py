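"""Free-running period (tau) from the DD segment via Lomb-Scargle.

After 4 days of LD entrainment the simulated animals free-run for 11 days
in constant darkness with an endogenous period of 23 h; the periodogram
recovers tau per individual and flags rhythm significance.
"""

import numpy as np

from damrhythm import (
    LightSchedule,
    estimate_freerun,
    lomb_scargle,
    rebin,
    split_regimes,
)
from damrhythm.simulate import simulate_cohort

schedule = LightSchedule(ld_days=4, dd_days=11)
series, _ = simulate_cohort("males_alone", 10, seed=33, schedule=schedule)

taus = []
for s in series:
    _, dd = split_regimes(rebin(s, 6), schedule)
    pg = lomb_scargle(dd, period_range=(16.0, 32.0), alpha=0.05)
    est = estimate_freerun(pg)
    taus.append(est.tau)
    print(
        f"channel {s.channel_id:2d}: tau = {est.tau:5.2f} h, "
        f"power = {est.power:6.1f}, significant = {est.significant}"
    )
print(f"\ncohort mean tau = {np.mean(taus):.2f} h (generator: 23.0 h)")
# tau < 24 h: in constant darkness the activity bout starts about an hour
# earlier every day. Power is the periodogram peak height above the 5%
# false-alarm line; values this large indicate a very robust rhythm.
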