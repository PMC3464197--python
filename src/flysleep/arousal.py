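"""Normalized arousability from a timed mechanical stimulus.

Arousal threshold is probed by mechanically rotating the monitors at ZT16
and counting how many flies that were asleep at the stimulus wake (show at
least one beam crossing) within 5 minutes.  Because some sleeping flies
would have woken anyway, a spontaneous-waking probe at ZT15:50 measures the
fraction of sleepers that wake within 5 minutes with no stimulus, and the
stimulus response is corrected to

    normalized % = 100 * (p_stim - p_spont) / (1 - p_spont).

Under an independent-OR waking model — a sleeping fly wakes if it wakes
spontaneously (probability s) or responds to the stimulus (probability a) —
the observed p_stim equals s + (1 - s) * a, so this normalization recovers
the stimulus-response probability a exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dam_io import ChannelSeries
from .sleep_core import SLEEP_THRESHOLD_MIN, score_sleep

__all__ = [
    "ArousalResult",
    "is_asleep_at",
    "waking_response",
    "normalized_arousal",
    "arousal_assay",
]

STIMULUS_ZT = 960  # ZT16
SPONTANEOUS_PROBE_ZT = 950  # ZT15:50
RESPONSE_WINDOW_MIN = 5


def is_asleep_at(
    series: ChannelSeries, sleep_state: np.ndarray, abs_minute: int
) -> bool:
    """True iff the minute lies inside a scored sleep bout (>= 5-min run)."""
    return bool(sleep_state[series.index_of(abs_minute)])


def waking_response(
    series: ChannelSeries, abs_minute: int, window_min: int = RESPONSE_WINDOW_MIN
) -> bool:
    """True iff >= 1 beam crossing occurs in the window (t, t + window].

    The window is half-open over whole minutes: a crossing in minute t+1
    through t+window counts, one at t+window+1 does not.
    """
    i = series.index_of(abs_minute)
    j = i + 1 + window_min
    if j > len(series):
        raise ValueError("response window extends past end of recording")
    return bool(series.counts[i + 1 : j].any())


def normalized_arousal(p_stim: float, p_spont: float) -> float:
    """Spontaneous-waking-corrected percent awoken by the stimulus."""
    for p in (p_stim, p_spont):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if p_spont >= 1.0:
        raise ValueError("normalization undefined when all sleepers wake spontaneously")
    return 100.0 * (p_stim - p_spont) / (1.0 - p_spont)


@dataclass(frozen=True)
class ArousalResult:
    p_stim: float
    p_spont: float
    normalized_pct: float
    n_stim_sleepers: int
    n_probe_sleepers: int
    se_stim: float
    se_spont: float


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n else math.nan


def arousal_assay(
    cohort: list[ChannelSeries] | list[tuple[ChannelSeries, np.ndarray]],
    day: int,
    stimulus_zt: int = STIMULUS_ZT,
    probe_zt: int = SPONTANEOUS_PROBE_ZT,
    window_min: int = RESPONSE_WINDOW_MIN,
    threshold_min: int = SLEEP_THRESHOLD_MIN,
) -> ArousalResult:
    """Run the arousal computation over a cohort for the night of ``day``.

    Only flies asleep at each probe enter that probe's denominator; awake
    flies never influence the result.  The spontaneous probe must precede the
    stimulus and the two 5-min windows must not overlap.
    """
    if probe_zt + window_min > stimulus_zt:
        raise ValueError("spontaneous probe window must end before the stimulus")
    stim_abs = day * 1440 + stimulus_zt
    probe_abs = day * 1440 + probe_zt
    n_stim = woke_stim = n_probe = woke_probe = 0
    for item in cohort:
        if isinstance(item, tuple):
            series, sleep_state = item
        else:
            series = item
            sleep_state, _ = score_sleep(series, threshold_min)
        if is_asleep_at(series, sleep_state, probe_abs):
            n_probe += 1
            woke_probe += waking_response(series, probe_abs, window_min)
        if is_asleep_at(series, sleep_state, stim_abs):
            n_stim += 1
            woke_stim += waking_response(series, stim_abs, window_min)
    if n_stim == 0 or n_probe == 0:
        raise ValueError("no sleeping flies at stimulus and/or probe time")
    p_stim = woke_stim / n_stim
    p_spont = woke_probe / n_probe
    return ArousalResult(
        p_stim=p_stim,
        p_spont=p_spont,
        normalized_pct=normalized_arousal(p_stim, p_spont),
        n_stim_sleepers=n_stim,
        n_probe_sleepers=n_probe,
        se_stim=_binomial_se(p_stim, n_stim),
        se_spont=_binomial_se(p_spont, n_probe),
    )
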