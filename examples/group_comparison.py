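"""Treatment comparison with the Bartlett-gated test scheme.

Compares PMI across the four treatment presets: Bartlett's test picks the
analysis path (ANOVA + Tukey after an optional variance-stabilizing
transform, else Kruskal-Wallis + Dunn) and the pairwise outcomes are
summarized as compact letters — groups sharing a letter do not differ
significantly at alpha = 0.05.
"""

import numpy as np

from damrhythm import (
    LightSchedule,
    compare_groups,
    detect_evening_peaks,
    individual_profile,
    rebin,
    split_regimes,
)
from damrhythm.simulate import simulate_cohort

schedule = LightSchedule(ld_days=4, dd_days=0)
groups = {}
for i, preset in enumerate(
    ("males_alone", "males_virgin_female", "males_inseminated_female", "females")
):
    series, _ = simulate_cohort(preset, 60, seed=11 + i, schedule=schedule)
    pmis = []
    for s in series:
        ld, _ = split_regimes(rebin(s, 6), schedule)
        pmis.append(detect_evening_peaks(individual_profile(ld, schedule)).pmi)
    groups[preset] = np.array(pmis)

res = compare_groups(groups, alpha=0.05, parameter="PMI")
print(f"test: {res.test_used} (transform: {res.transform_used})")
print(f"omnibus statistic = {res.statistic:.2f}, p = {res.p_value:.2e}\n")
for g in res.groups:
    vals = groups[g]
    print(
        f"{g:26s} n={len(vals):3d}  PMI {np.nanmean(vals):+.2f} "
        f"+/- {np.nanstd(vals):.2f}  '{res.letters[g]}'"
    )
# Distinct letters separate males alone from males with females and from
# females; the two with-female arms share a letter (statistically alike).
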