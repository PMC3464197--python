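"""Mechanistic generator of per-fly minute-resolution beam-crossing counts.

The generator is a minute-stepped two-state (awake/asleep) stochastic
process with a circadian modulation and a sleep homeostat, designed so every
pipeline stage can be exercised against planted ground truth:

* While awake, a fly falls asleep in a given minute with probability
  ``p_onset_base * circ_onset(zt) * (1 + g * H)`` (clamped to [0, 1]);
  while asleep it wakes with probability ``p_wake_base * circ_wake(zt)``.
  Darkness raises sleep onset and lowers waking (square-wave factor plus a
  smooth sinusoid peaking mid-night); state-dependent per-minute hazards make
  bout lengths semi-Markov at the day scale.
* The homeostat tracks sleep pressure H: H += alpha per awake minute,
  H = max(0, H - beta) per asleep minute.  Gain g scales how pressure boosts
  sleep onset; g = 0 removes homeostatic feedback entirely, which is the
  "no rebound" mutant phenotype — generative, not asserted.
* An awake minute emits a zero-truncated Poisson(lambda) count with
  probability ``active_frac`` (else 0); asleep minutes emit 0.  Forced-wake
  minutes (deprivation hardware) and stimulus-response waking emit >= 1.

Protocols schedule forced-wake events (every 2 min during a deprivation
window) and a single arousal stimulus: a sleeping fly responds with
probability ``p_arouse``, waking in the next minute.

Presets named after the study's cohorts (``wt``, ``inc_like``,
``cul3_rnai_like``, ``dat_fmn_like``) are frozen outputs of
:func:`calibrate_presets`; their emergent cohort statistics sit inside the
documented calibration bands (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .dam_io import N_CHANNELS, ChannelSeries, write_dam_file
from .sleep_core import fly_summary, score_sleep

__all__ = [
    "GenotypePreset",
    "Protocol",
    "SimulatedFly",
    "PRESETS",
    "simulate_fly",
    "simulate_cohort",
    "write_cohort",
    "CalibrationError",
    "calibrate_presets",
]


@dataclass(frozen=True)
class GenotypePreset:
    """Simulator parameters for one genotype.

    Probabilities are per minute; ``lambda_wake`` is the mean of the
    zero-truncated Poisson emitted on active awake minutes; ``active_frac``
    is the fraction of awake minutes with any beam crossing;
    ``pressure_accrual``/``pressure_decay`` are the homeostat rates per awake
    and asleep minute; ``homeostat_gain`` scales the onset boost per unit
    pressure.  ``p_spont_wake_5min`` records the emergent dark-period 5-min
    spontaneous waking probability implied by ``p_wake_base`` (documentation
    of the preset's arousal baseline, not an independent dial).
    """

    name: str
    p_onset_base: float
    p_wake_base: float
    circ_amp_onset: float
    circ_amp_wake: float
    lambda_wake: float
    active_frac: float
    homeostat_gain: float
    pressure_accrual: float
    pressure_decay: float
    p_arouse: float
    p_spont_wake_5min: float
    version: str = "1"

    def __post_init__(self) -> None:
        for f in (
            "p_onset_base",
            "p_wake_base",
            "active_frac",
            "p_arouse",
            "p_spont_wake_5min",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside [0, 1]")
        if self.lambda_wake <= 0:
            raise ValueError("lambda_wake must be > 0")
        if self.pressure_accrual < 0 or self.pressure_decay < 0:
            raise ValueError("pressure rates must be >= 0")
        if self.circ_amp_onset < 0 or self.circ_amp_wake < 0:
            raise ValueError("circadian amplitudes must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypePreset":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GenotypePreset":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Frozen calibration output (see calibrate_presets and docs/methods.md).
PRESETS: dict[str, GenotypePreset] = {
    p.name: p
    for p in (
        GenotypePreset(
            name="wt",
            p_onset_base=0.058,
            p_wake_base=0.023,
            circ_amp_onset=0.6,
            circ_amp_wake=0.6,
            lambda_wake=2.2,
            active_frac=0.80,
            homeostat_gain=1.2,
            pressure_accrual=1.0 / 720.0,
            pressure_decay=1.0 / 180.0,
            p_arouse=0.25,
            p_spont_wake_5min=0.05,
        ),
        GenotypePreset(
            name="inc_like",
            p_onset_base=0.030,
            p_wake_base=0.125,
            circ_amp_onset=0.4,
            circ_amp_wake=0.4,
            lambda_wake=1.8,
            active_frac=0.75,
            homeostat_gain=0.0,
            pressure_accrual=1.0 / 720.0,
            pressure_decay=1.0 / 180.0,
            p_arouse=0.90,
            p_spont_wake_5min=0.34,
        ),
        GenotypePreset(
            name="cul3_rnai_like",
            p_onset_base=0.040,
            p_wake_base=0.060,
            circ_amp_onset=0.5,
            circ_amp_wake=0.5,
            lambda_wake=1.9,
            active_frac=0.76,
            homeostat_gain=0.0,
            pressure_accrual=1.0 / 720.0,
            pressure_decay=1.0 / 180.0,
            p_arouse=0.85,
            p_spont_wake_5min=0.16,
        ),
        GenotypePreset(
            name="dat_fmn_like",
            p_onset_base=0.035,
            p_wake_base=0.075,
            circ_amp_onset=0.5,
            circ_amp_wake=0.5,
            lambda_wake=2.1,
            active_frac=0.78,
            homeostat_gain=0.0,
            pressure_accrual=1.0 / 720.0,
            pressure_decay=1.0 / 180.0,
            p_arouse=0.85,
            p_spont_wake_5min=0.19,
        ),
    )
}


@dataclass(frozen=True)
class Protocol:
    """Schedule of forced-wake events and arousal stimuli (absolute minutes)."""

    forced_wake_start: int | None = None
    forced_wake_end: int | None = None
    forced_wake_interval: int = 2
    stimulus_minutes: tuple[int, ...] = ()

    @classmethod
    def baseline(cls) -> "Protocol":
        return cls()

    @classmethod
    def deprivation_12h(cls, dep_day: int, interval: int = 2) -> "Protocol":
        start = dep_day * 1440 + 660  # ZT11
        return cls(forced_wake_start=start, forced_wake_end=start + 720,
                   forced_wake_interval=interval)

    @classmethod
    def deprivation_24h(cls, dep_day: int, interval: int = 2) -> "Protocol":
        start = dep_day * 1440
        return cls(forced_wake_start=start, forced_wake_end=start + 1440,
                   forced_wake_interval=interval)

    @classmethod
    def arousal(cls, day: int, stimulus_zt: int = 960) -> "Protocol":
        return cls(stimulus_minutes=(day * 1440 + stimulus_zt,))

    def forced_wake_at(self, abs_minute: int) -> bool:
        if self.forced_wake_start is None:
            return False
        return (
            self.forced_wake_start <= abs_minute < self.forced_wake_end
            and (abs_minute - self.forced_wake_start) % self.forced_wake_interval == 0
        )


@dataclass
class SimulatedFly:
    """A simulated recording plus its ground truth."""

    series: ChannelSeries
    truth_asleep: np.ndarray  # true (un-thresholded) sleep state per minute
    asleep_at_stimulus: dict[int, bool]  # abs stimulus minute -> truth
    responded: dict[int, bool]  # abs stimulus minute -> drew a response


def _circadian_factors(T: int, start_zt: int, preset: GenotypePreset):
    """Per-minute onset/wake probabilities before homeostat modulation."""
    zt = (start_zt + np.arange(T)) % 1440
    square = np.where(zt >= 720, 1.0, -1.0)
    s = 0.7 * square + 0.3 * np.sin(2.0 * math.pi * (zt - 720) / 1440.0)
    p_on = np.clip(preset.p_onset_base * (1.0 + preset.circ_amp_onset * s), 0.0, 1.0)
    p_wk = np.clip(preset.p_wake_base * (1.0 - preset.circ_amp_wake * s), 0.0, 1.0)
    return p_on, p_wk


def _ztp(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw (rejection; cheap for lambda >= 1)."""
    k = rng.poisson(lam)
    while k == 0:
        k = rng.poisson(lam)
    return int(k)


def simulate_fly(
    preset: GenotypePreset,
    days: int,
    seed: int,
    protocol: Protocol | None = None,
    fly_index: int = 0,
    start_zt: int = 0,
    start_asleep: bool = False,
    genotype: str | None = None,
) -> SimulatedFly:
    """Simulate one fly for ``days`` days starting at ``start_zt``.

    Reproducible through per-fly substreams: the random stream is seeded
    with ``(seed, fly_index)``, so cohorts are identical whether generated
    serially or in parallel.
    """
    protocol = protocol or Protocol.baseline()
    rng = np.random.default_rng([int(seed), int(fly_index)])
    T = days * 1440
    p_on, p_wk = _circadian_factors(T, start_zt, preset)
    u_move = rng.random(T)
    u_act = rng.random(T)
    counts = np.zeros(T, dtype=np.int64)
    truth = np.zeros(T, dtype=bool)

    g, alpha, beta = preset.homeostat_gain, preset.pressure_accrual, preset.pressure_decay
    lam, af = preset.lambda_wake, preset.active_frac
    stim_set = set(protocol.stimulus_minutes)
    asleep_at_stim: dict[int, bool] = {}
    responded: dict[int, bool] = {}

    asleep = start_asleep
    H = 0.0
    pending_wake = -1  # minute at which a stimulus response forces waking
    for t in range(T):
        a = start_zt + t
        forced = protocol.forced_wake_at(a)
        if forced or t == pending_wake:
            asleep = False
        if a in stim_set:
            asleep_at_stim[a] = asleep
            if asleep:
                hit = rng.random() < preset.p_arouse
                responded[a] = bool(hit)
                if hit:
                    pending_wake = t + 1
            else:
                responded[a] = False
        truth[t] = asleep
        if not asleep:
            if forced or t == pending_wake:
                counts[t] = _ztp(rng, lam)
            elif u_act[t] < af:
                counts[t] = _ztp(rng, lam)
            H += alpha
            p = p_on[t] * (1.0 + g * H)
            if u_move[t] < (p if p < 1.0 else 1.0) and not forced:
                asleep = True
        else:
            H = H - beta if H > beta else 0.0
            if u_move[t] < p_wk[t]:
                asleep = False

    series = ChannelSeries(
        fly_id=f"{preset.name}:{fly_index:03d}",
        counts=counts,
        start_zt=start_zt,
        genotype=genotype if genotype is not None else preset.name,
    )
    return SimulatedFly(
        series=series,
        truth_asleep=truth,
        asleep_at_stimulus=asleep_at_stim,
        responded=responded,
    )


def simulate_cohort(
    preset: GenotypePreset,
    n: int,
    days: int,
    seed: int,
    protocol: Protocol | None = None,
    start_zt: int = 0,
) -> list[SimulatedFly]:
    """Simulate ``n`` independent flies (per-fly substreams of one seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        simulate_fly(preset, days, seed, protocol, fly_index=i, start_zt=start_zt)
        for i in range(n)
    ]


def write_cohort(
    cohort: list[SimulatedFly],
    out_dir: str | Path,
    experiment_id: str = "sim",
    start_clock: str = "08:00",
) -> list[Path]:
    """Write a cohort as DAM monitor files plus a layout YAML and truth CSV.

    Flies fill monitors 32 channels at a time (spillover opens a new
    monitor); the files round-trip through :func:`flysleep.dam_io.read_dam_file`.
    Assumes all flies share one start and length and start at ZT0 (lights-on
    at ``start_clock``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T = len(cohort[0].series)
    import datetime as dt

    hh, mm = (int(x) for x in start_clock.split(":"))
    start = dt.datetime(2012, 1, 2, hh, mm)
    layout: dict = {"experiment_id": experiment_id, "lights_on": start_clock,
                    "monitors": {}}
    paths = []
    truth_rows = []
    for m in range(0, len(cohort), N_CHANNELS):
        mon_flies = cohort[m : m + N_CHANNELS]
        mon_id = f"Monitor{m // N_CHANNELS + 1}"
        counts = np.zeros((T, N_CHANNELS), dtype=np.int64)
        chan_meta = {}
        for ch, fly in enumerate(mon_flies, start=1):
            counts[:, ch - 1] = fly.series.counts
            chan_meta[ch] = {
                "genotype": fly.series.genotype,
                "sex": fly.series.sex or "male",
                "treatment": fly.series.treatment,
            }
            truth_rows.append(
                {
                    "monitor_id": mon_id,
                    "channel": ch,
                    "fly_id": fly.series.fly_id,
                    "genotype": fly.series.genotype,
                    "true_sleep_min": int(fly.truth_asleep.sum()),
                }
            )
        layout["monitors"][mon_id] = chan_meta
        p = out_dir / f"{mon_id}.txt"
        write_dam_file(p, counts, start)
        paths.append(p)
    (out_dir / "layout.yaml").write_text(yaml.safe_dump(layout, sort_keys=False))
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return paths


class CalibrationError(RuntimeError):
    """No parameter setting reached the target bands; carries the best found."""

    def __init__(self, message: str, best: GenotypePreset, achieved: dict):
        super().__init__(message)
        self.best = best
        self.achieved = achieved


def _cohort_metrics(preset: GenotypePreset, n: int, days: int, seed: int) -> dict:
    flies = simulate_cohort(preset, n, days, seed)
    sleep, abl = [], []
    for f in flies:
        s = fly_summary(f.series, n_days=days - 1 if days > 4 else days)
        sleep.append(s.sleep_min_per_day)
        if math.isfinite(s.abl_min):
            abl.append(s.abl_min)
    return {
        "sleep_min_per_day": float(np.mean(sleep)),
        "abl_min": float(np.mean(abl)) if abl else math.nan,
    }


def calibrate_presets(
    targets: dict[str, tuple[float, float]],
    onset_range: tuple[float, float],
    wake_range: tuple[float, float],
    seed: int,
    base: GenotypePreset,
    grid: int = 6,
    n: int = 12,
    days: int = 4,
) -> tuple[GenotypePreset, dict]:
    """Grid search over (p_onset_base, p_wake_base) toward cohort-metric bands.

    ``targets`` maps metric names (``sleep_min_per_day``, ``abl_min``) to
    (lo, hi) bands.  Returns the best preset and its achieved metrics; raises
    :class:`CalibrationError` (carrying the best found) if no grid point lands
    inside every band.
    """
    best, best_metrics, best_dist = None, None, math.inf
    for po in np.linspace(*onset_range, grid):
        for pw in np.linspace(*wake_range, grid):
            cand = dataclasses.replace(base, p_onset_base=float(po),
                                       p_wake_base=float(pw))
            m = _cohort_metrics(cand, n, days, seed)
            dist = 0.0
            inside = True
            for key, (lo, hi) in targets.items():
                v = m[key]
                mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
                excess = max(0.0, abs(v - mid) - half)
                inside &= excess == 0.0
                dist += (excess / max(half, 1e-9)) ** 2
            if dist < best_dist:
                best, best_metrics, best_dist = cand, m, dist
            if inside:
                return cand, m
    raise CalibrationError(
        f"no parameter setting inside target bands; best achieved {best_metrics}",
        best=best,
        achieved=best_metrics,
    )
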