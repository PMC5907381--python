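"""Parse DAM monitor text, rebin 5-min counts to 30 min, map to ZT.

Builds a tiny two-channel monitor file in memory, parses it back, and shows
the rebinned counts with their Zeitgeber-time labels.
"""

import io

import numpy as np

from damrhythm import (
    LightSchedule,
    parse_monitor_file,
    rebin,
    to_zt,
    write_monitor_file,
)
from damrhythm.simulate import simulate_cohort

schedule = LightSchedule(ld_days=1, dd_days=0)  # one LD day for brevity
series, _ = simulate_cohort("males_alone", 2, seed=1, schedule=schedule)

buf = io.StringIO()
write_monitor_file(series, buf)
print("first DAM row:", buf.getvalue().splitlines()[0][:60], "...")

channels = parse_monitor_file(io.StringIO(buf.getvalue()))
ch1 = channels[0]
print(f"parsed {len(channels)} channels, {len(ch1)} x {ch1.bin_width:g}-min bins")

half_hour = rebin(ch1, 6)
print("rebin conserves counts:", ch1.total() == half_hour.total())

print("\nfirst evening bins (ZT, counts/30min):")
for ts, c in zip(half_hour.timestamps[17:25], half_hour.counts[17:25]):
    day, zt = to_zt(ts, schedule)
    print(f"  day {day}  ZT{zt:4.1f}  {c:3d}")
# The counts rise toward the evening activity peak; ZT is hours since
# lights-on, so ZT12 is lights-off in a 12:12 cycle.
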