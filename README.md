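# flysleep

Sleep analysis for *Drosophila* activity-monitor (DAM/Trikinetics) data:
sleep scoring from infrared beam-crossing counts, sleep-architecture
metrics, sleep-deprivation rebound, normalized arousability, and
reverse-genetics screen hit calling — plus a mechanistic per-fly activity
simulator so every stage of the pipeline can be validated against planted
ground truth without any external recordings.

It is written for behavioral neurogeneticists and chronobiologists who run
DAM experiments: single flies in glass tubes, one infrared beam per tube,
beam crossings binned per minute, 32 channels per monitor, under a
12 h:12 h light:dark cycle (ZT0 = lights-on, ZT12 = lights-off).

## What it computes

**Sleep scoring.** Fly sleep is defined operationally as ≥ 5 consecutive
minutes with zero beam crossings. A *sleep bout* is a maximal such run;
minutes flagged invalid by the monitor break runs, so outages never
fabricate sleep. Per fly-day the package reports total sleep, bout count,
average sleep bout length (ABL = total sleep / bout count), latency from
lights-off to the first dark-period bout, waking activity (crossings per
awake minute), and a 48-bin (30-min) sleep profile.

**Homeostasis.** After mechanical deprivation (ZT11–ZT23 for 12 h, ZT0–ZT0
for 24 h), per-fly Δsleep in a recovery window is recovery sleep minus
sleep in the recovery-matched ZT window of the baseline day; the adjusted
Δsleep subtracts the mean Δsleep of non-deprived controls, and %Δsleep
divides by the fly's baseline-window sleep. Deprivation efficacy (percent
of baseline-window sleep abolished; target ≥ 90%) is reported alongside.

**Arousability.** At ZT16 the monitors are rotated and the fraction of
sleeping flies waking within 5 min (`p_stim`) is corrected for spontaneous
waking measured at ZT15:50 (`p_spont`):

```
normalized % = 100 · (p_stim − p_spont) / (1 − p_spont)
```

which exactly recovers the stimulus-response probability under an
independent-OR waking model.

**Screen statistics.** Genotype means are z-scored against the population
of genotype means within each experiment; a genotype is a hit when
|z| ≥ 2 for sleep duration and/or ABL in ≥ 3 experiments with consistent
direction. Two-group comparisons use a Shapiro-Wilk-gated choice between
the two-tailed Welch t-test and Mann-Whitney U (bout lengths always use
the rank test).

**Simulator.** A minute-stepped two-state (awake/asleep) process with
circadian modulation and a sleep homeostat (pressure H accrues while
awake, decays while asleep, and boosts sleep onset with gain *g*; *g* = 0
generates the rebound-less mutant phenotype). Frozen presets `wt`,
`inc_like`, `cul3_rnai_like`, and `dat_fmn_like` reproduce the cohort-level
contrasts of a strong short-sleep mutant and its pathway partners.

## Worked example

```python
import numpy as np
from flysleep import sleep_core
from flysleep.synthetic import PRESETS, simulate_cohort

for name in ("wt", "inc_like"):
    flies = simulate_cohort(PRESETS[name], n=16, days=5, seed=0)
    s = [sleep_core.fly_summary(f.series) for f in flies]
    sl = [x.sleep_min_per_day for x in s]
    abl = [x.abl_min for x in s]
    print(f"{name:10s} sleep {np.mean(sl):6.1f} ± {np.std(sl)/len(sl)**.5:4.1f} "
          f"min/day   ABL {np.mean(abl):5.1f} min")
```

prints

```
wt         sleep  962.8 ±  8.9 min/day   ABL  56.5 min
inc_like   sleep  312.5 ±  8.4 min/day   ABL  14.3 min
```

i.e. the short-sleeper cohort loses ~650 min (~11 h) of daily sleep and
its bouts collapse from ~56 min to ~14 min — reduced *and* fragmented
sleep, the signature phenotype this pipeline quantifies. The same
analyses are available from the shell via `flysleep simulate | score |
rebound | arousal | screen` (see `flysleep --help`).

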