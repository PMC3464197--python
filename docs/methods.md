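# Methods

## Sleep scoring

Sleep is scored from 1-minute binned beam-crossing counts: a minute is
asleep iff it lies in a maximal run of ≥ 5 consecutive zero-count,
non-missing minutes (the run is the *bout*). The threshold is inclusive
(a run of exactly 5 is a bout) and configurable. Scoring decisions:

- **Missing minutes** (invalid monitor status, timestamp gaps, post-mortem
  censoring) break inactivity runs. This is conservative: an outage can
  cost sleep minutes but can never create them.
- **Day attribution.** Days are ZT-aligned ([ZT0, ZT24) half-open minute
  bins). A bout straddling midnight-ZT contributes its clipped minutes to
  each day but increments the bout count only of its onset day, so bout
  numbers are never double-counted. Consequently a day's
  `ABL × bout_count = sleep` identity holds exactly only when no bout
  straddles its boundaries; per-fly ABL is therefore *pooled* — total
  sleep over the analysis days divided by total bout count — yielding one
  statistic per fly for group tests rather than a mean of daily ratios.
- **Analysis horizon.** The leading partial day (loading) is discarded and
  the next 4 complete days are analyzed, within a 5-day recording.
- **Latency** (lights-off → first dark-bout onset) is censored at 720 min
  with a flag when a fly never sleeps in the dark, rather than excluded;
  excluding non-sleepers would bias short-sleeper genotypes toward
  apparently normal latencies.
- **Dead flies** (no beam crossing over a trailing 24 h window) are
  censored from their last activity onward before any cohort statistic.
- Files sampled faster than 1/min are re-binned by summation; coarser
  sampling is rejected rather than interpolated.

## Deprivation and rebound

The 12-h design deprives ZT11–ZT23; the 24-h design ZT0–ZT0. Recovery
windows (defaults 6 h and 9 h) are anchored at deprivation end and
compared against the *same ZT window* of the baseline day, controlling
for circadian sleep placement. For the 12-h design the baseline window
(ZT23 → onward) runs into the pre-deprivation morning of the deprivation
day, which is undisturbed; overlap with the deprivation window is checked
and rejected.

Per deprived fly, adjusted Δsleep = (recovery − baseline) − mean
(recovery − baseline) over non-deprived controls. %Δsleep divides each
fly's adjusted Δ by its own baseline-window sleep: the percentage is then
interpretable per fly and per window (the alternative denominator, total
daily baseline sleep, conflates window placement with rebound size; this
is a documented convention). Cohort significance uses the package's gated
two-group procedure on deprived vs control Δsleep.

Efficacy = 100 × (1 − deprivation-window sleep / same-ZT-window baseline
sleep); flies with zero baseline-window sleep are excluded (undefined).

## Arousability

`p_stim` is the fraction of flies asleep at the stimulus minute that show
≥ 1 beam crossing in the following 5 minutes (window (t, t+5] over whole
minutes; a crossing in the stimulus minute itself would precede the
response and is not counted). `p_spont` applies the identical gating and
window at a probe 10 min earlier. The normalization
(p_stim − p_spont)/(1 − p_spont) is the unique form that recovers the
stimulus-response probability *a* under a model where a sleeping fly wakes
by an independent OR of spontaneous waking (prob s) and stimulus response
(prob a): observed p_stim = s + (1 − s)a. It is undefined when every
sleeper wakes spontaneously (p_spont = 1).

## Screen statistics

Population mean/SD are computed over *genotype means within one
experiment batch* (not pooled flies): screen z-scores describe
genotype-level deviation, and batches differ in handling. A hit requires
|z| ≥ 2 on sleep duration and/or ABL in ≥ 3 experiments with the same
sign — a genotype alternating long/short across replicates is noise, not
a phenotype. No multiple-testing correction is applied (screen practice);
the expected null flag and replicated-hit counts are reported so the
false-positive background is explicit: for a Gaussian population the
per-experiment flag rate is 2Φ(−2) ≈ 4.6% while the same-direction
triple-replicate rate is 2Φ(−2)³ ≈ 2.4 × 10⁻⁵.

Group comparisons: bout-length metrics always use Mann-Whitney U (bout
lengths are strongly right-skewed); other metrics use Shapiro-Wilk at
α = 0.05 on each group, choosing the two-tailed Welch t-test (unequal
variances assumed — group sizes and spreads differ routinely) when both
pass, otherwise Mann-Whitney U.

## The simulator

A minute-stepped two-state process, native to 1-min DAM binning
(semi-Markov bout structure emerges from state- and time-dependent
per-minute hazards):

- Onset hazard: `p_onset_base · circ_on(ZT) · (1 + g·H)`, clamped to
  [0, 1]; waking hazard: `p_wake_base · circ_wake(ZT)`.
- Circadian factor: `s(t) = 0.7·square(ZT) + 0.3·sin(2π(ZT−720)/1440)`
  (square = +1 in dark, −1 in light; the sinusoid peaks mid-night);
  `circ_on = 1 + A_on·s`, `circ_wake = 1 − A_wk·s`. Darkness therefore
  raises onset and lowers waking. Anticipatory activity is deliberately
  not modeled.
- Homeostat: pressure `H += α` per awake minute, `H = max(0, H − β)` per
  asleep minute; gain `g` converts pressure into onset boost. Defaults
  α = 1/720 (12 h of enforced waking accrues one pressure unit) and
  β = 1/180 (pressure cleared by ~3 h of sleep), so baseline H stays
  small and a 12-h deprivation produces a multi-hour onset boost. g = 0
  removes the feedback loop entirely: the "no rebound" phenotype is
  generative, not asserted.
- Emission: an awake minute emits a zero-truncated Poisson(λ) count with
  probability `active_frac`, else 0; asleep minutes emit 0. Forced-wake
  minutes (deprivation hardware, every 2 min inside the window) and the
  minute after a stimulus response always emit ≥ 1 count, as the jostling
  itself trips the beam.
- Arousal stimulus: a truly-asleep fly responds with probability
  `p_arouse`, waking the next minute; non-responders may still wake
  spontaneously through the ordinary waking hazard, which is what the
  spontaneous probe corrects for.
- Reproducibility: each fly uses the substream `(seed, fly_index)`, so
  cohorts are bit-identical regardless of generation order or cohort
  size.

### Preset calibration

Presets were fixed once by coarse grid search over
(`p_onset_base`, `p_wake_base`) (`calibrate_presets`) against bands
encoding the study's printed cohort contrasts, with absolute wild-type
levels set to field-typical values (only differences are printed in the
source study): wt daily sleep 900–1000 min and ABL 40–80 min; inc-like
250–400 min and ABL 5–15 min (wt − inc ≥ 600 min ≈ 10 h); arousal
response probabilities 0.25 / 0.90 / 0.85 (wt / inc-like / Cul3-RNAi-like);
wild-type dark-period spontaneous 5-min waking ≈ 0.05. Achieved values
(n = 50, 4 scored days, seed 1): wt 963 min, ABL 56 min; inc-like 311 min,
ABL 14 min; difference 652 min = 10.9 h. Latency and waking activity are
held to the study's *directions* (inc-like latency > wt; waking activity
slightly < wt): with minute-Bernoulli onset hazards, any parameterization
matching the inc-like sleep band yields mean dark latency ~30 min, so an
absolute latency band is not simultaneously attainable and the direction
is the meaningful constraint. The `p_spont_wake_5min` preset field
documents the emergent dark-period spontaneous-waking probability implied
by `p_wake_base`; it is not an independent dial.

### What the generator does and does not emulate

It reproduces: minute-binned counts with realistic zero-inflation,
light/dark sleep placement, genotype-dependent fragmentation, homeostatic
rebound with a tunable gain, deprivation-rig forced waking, and
stimulus-response arousal. It does **not** model: anticipation of light
transitions, ultradian structure beyond the two-state process,
inter-individual parameter heterogeneity within a genotype, drug
pharmacokinetics (drug arms are alternative presets, e.g. a short-sleeper
preset with restored gain), temperature, or death. Passing tests
therefore demonstrate correctness of the *pipeline arithmetic and
estimators* under a plausible generative model — not that the presets are
faithful digital twins of any real genotype.

## Numerical and edge-case conventions

- A day with no bouts reports ABL as missing (NaN), never 0; a fully
  asleep window reports waking activity as missing.
- Sleepers at the arousal probes are gated by *scored* sleep (inside a
  ≥ 5-min zero run containing the probe minute). A small fraction of
  scored sleepers are quiet-wake flies (true-awake, zero-count minutes
  inside a scored bout); at the calibrated emission rates this biases the
  normalized estimate by well under the binomial sampling error (measured
  in the test suite).
- Shapiro-Wilk on a constant sample is undefined; constant samples are
  routed to the rank test.
- Problem sizes in the shipped checks (chosen for tight Monte-Carlo error
  at interactive runtimes): baseline cohorts n = 50 × 5 days; rebound
  n = 40 deprived + 40 control per genotype with 2 acclimation days, one
  baseline day, deprivation on day 3 and recovery on day 4; arousal
  cohorts 250–800 flies × 3 days (≥ 60 sleepers at the stimulus); scorer
  oracle 10⁴ random sequences.

## Known limitations

- The rebound effect size of the wild-type preset (~+40 min adjusted
  Δsleep in the 6-h window) was tuned through the homeostat gain; the
  real magnitude is not printed in the source material, only its
  significance pattern, so only sign and significance should be compared.
- The 24-h deprivation design anchors its baseline window at ZT0 of the
  baseline day; with only one baseline day this window coincides with the
  baseline day itself, so acclimation must be clean.
- Monitor files at intervals coarser than 1 min are rejected; re-binning
  them would require inventing sub-interval structure.
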