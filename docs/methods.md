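# Methods

## Data model

A monitor channel is an `ActivitySeries`: non-negative integer beam-crossing
counts on a regular grid (5-min bins as recorded; 30-min bins for analysis,
obtained by exact summation). Bins are labelled by their start time and are
half-open `[t, t + width)`, which makes rebinning unambiguous. A
`LightSchedule` carries the lights-on clock time (the ZT0 anchor), the
number of LD days (default 4) and DD days (default 11), and the photoperiod
(12 h light). ZT is hours since the most recent lights-on anchor; in DD the
same clock anchor keeps defining subjective ZT0 — the standard actogram
convention — rather than re-anchoring to the free-running phase. The DAM
text dialect is the 42-column DAMSystem3 layout (index, date, time, status,
six metadata columns, 32 counts); rows whose status is not the valid code
are dropped by default (with a count kept for the log), configurable to
keep or to fail. An optional dead-animal filter (exclude channels silent
over the final LD day) exists but is off by default.

## Averaging: the William's mean

Activity counts are zero-inflated and heavy-tailed, so profiles use the
William's mean, `W(v) = exp(mean(ln(v + 1))) − 1` — a geometric-style
average finite at zero and never larger than the arithmetic mean. The
natural logarithm is used; any base gives the same value after
back-transform. Two averaging paths are deliberately distinct:

* **individual profile** (input to E1/E2/PMI): for each 30-min ZT bin, the
  William's mean of that individual's counts across days 2–4. Day 1 is
  excluded by default as acclimation; the day set is a parameter.
* **group profile** (the plotted average): the William's mean across
  individuals within each day and bin, then the arithmetic mean across
  days 2–4. For one individual with identical days the two paths coincide;
  in general they do not, and the group path is used only for the group
  curve. Error bars are the per-bin SEM across individuals' day-averaged
  profiles (SD/√n is configurable in principle by post-processing; SEM is
  the default display).

## Evening peaks and PMI

Peaks are called per individual on the days-2–4 profile inside the window
ZT8.5–ZT12.0, endpoints inclusive on the 30-min grid (8 bins). A peak is a
local maximum using only in-window neighbours (so a profile rising through
the window peaks at ZT12.0); candidates are ranked by topographic
prominence, ties broken by magnitude and then earlier phase, and the two
best become E1 (earlier) and E2 (later). When the window holds a single
local maximum, it is assigned to the sub-window containing it — the window
midpoint ZT10.25 splits the sub-windows — and the other peak takes the
plain maximum of its own sub-window; a mode that reports the two sub-window
maxima directly (`require_local_max=False`) is also provided, since the
operational definition of "peak" admits both readings. An all-zero window
yields zero magnitudes and an undefined PMI (propagated as NaN and dropped
listwise from comparisons, never coerced to 0).

`PMI = (E2 − E1) / ((E1 + E2)/2)` is antisymmetric, scale-invariant and
bounded in [−2, 2]. Group PMI is always the mean of individual PMIs, never
a PMI of group means.

## Free-running period

The DD segment (30-min bins, hours since segment start) is analysed with a
Lomb-Scargle periodogram over periods 16–32 h, grid step 0.1 h (both
configurable); power carries the classical Scargle normalization
(periodogram divided by the sample variance), under which single-frequency
noise power is approximately Exp(1). The significance line at alpha = 0.05
solves `1 − (1 − e^{−z})^M = alpha` with M equal to the number of scanned
grid frequencies — the classical, mildly conservative choice; treating
only the band's Fourier spacings as independent was measured to
under-correct on oversampled grids (≈12% realized false-alarm at nominal
5% on Poisson white noise), while the grid-size choice keeps the realized
rate below nominal. `tau` is the argmax period, `power` the peak height
minus the threshold (reported as-is when negative), `significant` its sign.
Constant or near-empty segments are rejected rather than scored. At least
~10 days of DD data are recommended; the LD→DD transition day is included.

## Group statistics

For each parameter (E1, E2, PMI, TALD, TADD, TA, PROPDD, tau, power):
Bartlett's test at alpha = 0.05 on the raw data, then — if heteroscedastic —
on log(x+1), then √x, then arcsin(√x) (the last only when all values lie
in [0, 1]; it is a proportion transform and is never offered raw counts).
The first transform that passes routes to one-way ANOVA with Tukey's HSD;
if none passes, to Kruskal-Wallis with Dunn's pairwise z-test
(tie-corrected, Holm-adjusted by default; the adjustment method is a
parameter). Pairwise outcomes become compact letters via an exact minimal
clique cover of the non-significance graph (treatment counts are small
enough for exhaustive search), so the display uses the fewest letters with
the share-a-letter ⇔ not-significant semantics. Parameters that are
constant across all individuals (e.g. PROPDD in an LD-only design) are
skipped rather than fed to degenerate tests. Individuals are treated as
independent replicates; no blocking factor across repeated experiments is
modelled, which is a known caveat of the pooled design.

## Synthetic actogram generator

The generator emulates the count statistics the analysis consumes — not
any mechanistic clock model. The expected rate per 5-min bin is

`λ(ZT) = baseline + night·1[phase ≥ 12.5] + A1·G(phase; φ1, σ) + A2·G(phase; φ2, σ) + startle (LD only)`

with circular (wrap-around) Gaussian bumps G. Defaults: baseline 0.3,
night level 1.2 (from ZT12.5, i.e. after the evening bumps, which
themselves model early-night activity — this keeps the evening window
uncontaminated by the plateau term), startle 12.0 decaying linearly over
30 min after lights-on, bump σ = 0.45 h, φ1 = 10.75 and φ2 = 12.25 (bin
centres of the 30-min bins labelled ZT10.5 and ZT12.0). In DD the startle
disappears and the whole shape shifts earlier by (24 − tau)·d hours on the
d-th DD day (d from 1), so successive activity bouts are exactly tau
apart; tau defaults to 23.0 h. Counts are Poisson by default, with a
negative-binomial (gamma-Poisson) option for overdispersion and a
deterministic mode (`dispersion="none"`, counts = round(λ)) for exact
checks. Per-individual heterogeneity is a lognormal multiplier on the whole
rate (mean 1, CV 0.5), mimicking the large between-animal spread of real
records while leaving each individual's E2:E1 ratio intact.

Treatment presets differ only in the evening-bump amplitudes: males alone
(A1 = 5.0, A2 = 4.5; E2:E1 r = 0.9), males with a virgin female (4.5/6.75,
r = 1.5), males with an inseminated female (4.0/6.0, r = 1.5), females
(3.5/10.5, r = 3). In the noise-free limit the cohort PMI approaches
2(r − 1)/(r + 1) up to a small compression from the shared baseline inside
the window; under noise the individual-level peak search adds a modest
positive bias (selecting maxima of noisy bins), so cohort means sit near
0, +0.45, +0.5 and +1.2 respectively. These presets reproduce structure —
male group peak on bin ZT10.5, female on ZT12.0 (1.5 h apart), tau ≈ 23 h,
clearly separated PMI between males alone and males with a virgin female —
not any particular real cohort's numbers.

What the generator does **not** emulate: within-day autocorrelation beyond
the rate shape, day-to-day drift of individual amplitude, weather/handling
artefacts, death or sensor dropout, and phase (as opposed to amplitude)
variation between individuals. Passing tests therefore demonstrate that
the pipeline recovers the parameters of data satisfying its own
assumptions, not that those assumptions hold for any particular recording.

## Numerical choices and problem sizes

Rebinning is exact integer summation. ZT mapping uses nanosecond-resolution
timestamps with a 1e-9 h tolerance at the experiment start. Peak-call ties
prefer prominence, then magnitude, then earlier phase. The acceptance
script and recovery tests use cohorts of 90 individuals (peak phases) and
30 individuals (free run) over the standard 4 + 11 day design, and the
type-I-error calibration uses 5000 simulated 4 × 80 null datasets — sizes
at which every checked quantity is stable across seeds while the whole
suite runs in well under a minute. The run summary JSON is
schema-versioned (`schema_version: 1`) and byte-stable for a fixed config
and seed.
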