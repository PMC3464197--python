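"""Sleep scoring and sleep-architecture metrics.

Fly sleep is defined operationally as any maximal run of at least 5
consecutive minutes with zero beam crossings.  Scoring is done at 1-minute
resolution; a minute flagged missing breaks an inactivity run, so sleep is
never scored across monitor outages.

Architecture metrics per fly-day: total sleep, bout count, average sleep
bout length (ABL), latency to sleep after lights-off, and waking activity
(beam crossings per awake minute).  Bouts that straddle a day boundary are
clipped — their minutes are credited to each day they touch, while the bout
itself increments the bout count only of its onset day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import ChannelSeries

__all__ = [
    "SleepBout",
    "ArchitectureMetrics",
    "FlySummary",
    "score_sleep",
    "daily_metrics",
    "sleep_profile",
    "latency_after_lights_off",
    "waking_activity",
    "analysis_days",
    "fly_summary",
    "cohort_table",
]

SLEEP_THRESHOLD_MIN = 5
LIGHTS_OFF_ZT = 720


@dataclass(frozen=True)
class SleepBout:
    """A maximal inactivity run of at least the sleep threshold.

    ``onset``/``offset`` are absolute minutes (half-open end) on the same
    axis as :attr:`ChannelSeries.abs_minutes`; truncation flags mark bouts
    clipped by the recording edges.
    """

    onset: int
    offset: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def duration_min(self) -> int:
        return self.offset - self.onset

    @property
    def onset_zt(self) -> int:
        return self.onset % 1440

    @property
    def offset_zt(self) -> int:
        return self.offset % 1440

    def contains(self, abs_minute: int) -> bool:
        return self.onset <= abs_minute < self.offset


def score_sleep(
    series: ChannelSeries, threshold_min: int = SLEEP_THRESHOLD_MIN
) -> tuple[np.ndarray, list[SleepBout]]:
    """Score sleep for one fly.

    A minute is asleep iff it belongs to a maximal run of >= ``threshold_min``
    consecutive zero-count, non-missing minutes.  Returns the boolean
    sleep-state sequence and the list of :class:`SleepBout`.
    """
    if threshold_min < 1:
        raise ValueError("threshold_min must be >= 1")
    counts = series.counts
    if (counts < 0).any():
        raise ValueError("negative counts")
    inactive = (counts == 0) & ~series.missing
    z = inactive.astype(np.int8)
    edges = np.diff(np.concatenate(([0], z, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    keep = (ends - starts) >= threshold_min

    sleep = np.zeros(len(series), dtype=bool)
    bouts: list[SleepBout] = []
    n = len(series)
    for i, j in zip(starts[keep], ends[keep]):
        sleep[i:j] = True
        bouts.append(
            SleepBout(
                onset=int(series.start_zt + i),
                offset=int(series.start_zt + j),
                truncated_start=(i == 0),
                truncated_end=(j == n),
            )
        )
    return sleep, bouts


@dataclass(frozen=True)
class ArchitectureMetrics:
    """Per-fly, per-day sleep architecture."""

    fly_id: str
    day: int
    sleep_min: int
    bout_count: int
    abl_min: float  # NaN when the day has no bouts
    latency_min: int
    latency_censored: bool
    waking_activity: float  # NaN when the day has no waking minutes
    missing_min: int
    excluded: bool = False


def _day_slice(series: ChannelSeries, day: int) -> slice:
    lo = day * 1440
    hi = lo + 1440
    if lo < series.start_zt or hi > series.start_zt + len(series):
        raise ValueError(f"day {day} not fully covered by recording")
    return slice(lo - series.start_zt, hi - series.start_zt)


def latency_after_lights_off(
    bouts: list[SleepBout], day: int, lights_off_zt: int = LIGHTS_OFF_ZT
) -> tuple[int, bool]:
    """Minutes from lights-off to the first dark-period bout onset.

    A bout already ongoing at lights-off gives latency 0.  A fly with no
    dark-period sleep is censored at the dark-period length (flag set) rather
    than excluded, so short-sleeping genotypes still contribute.
    """
    loff = day * 1440 + lights_off_zt
    day_end = (day + 1) * 1440
    for b in bouts:
        if b.contains(loff):
            return 0, False
        if loff <= b.onset < day_end:
            return b.onset - loff, False
    return day_end - loff, True


def waking_activity(
    series: ChannelSeries, sleep_state: np.ndarray, sel: slice | None = None
) -> float:
    """Beam crossings per awake, non-missing minute (NaN if always asleep)."""
    sel = sel if sel is not None else slice(None)
    awake = ~sleep_state[sel] & ~series.missing[sel]
    n_awake = int(awake.sum())
    if n_awake == 0:
        return math.nan
    return float(series.counts[sel][awake].sum()) / n_awake


def daily_metrics(
    series: ChannelSeries,
    day: int,
    sleep_state: np.ndarray | None = None,
    bouts: list[SleepBout] | None = None,
    threshold_min: int = SLEEP_THRESHOLD_MIN,
    dead_from_abs: int | None = None,
) -> ArchitectureMetrics:
    """All architecture metrics for one fly-day (absolute day index ``day``).

    ``dead_from_abs`` marks the fly's last-activity minute; a day overlapping
    it is marked excluded.  ABL for a day with no bouts is NaN (missing, not
    zero).
    """
    if sleep_state is None or bouts is None:
        sleep_state, bouts = score_sleep(series, threshold_min)
    sel = _day_slice(series, day)
    lo, hi = day * 1440, (day + 1) * 1440
    sleep_min = int(sleep_state[sel].sum())
    day_bouts = [b for b in bouts if lo <= b.onset < hi]
    n_bouts = len(day_bouts)
    abl = sleep_min / n_bouts if n_bouts else math.nan
    latency, censored = latency_after_lights_off(bouts, day)
    excluded = dead_from_abs is not None and dead_from_abs < hi
    return ArchitectureMetrics(
        fly_id=series.fly_id,
        day=day,
        sleep_min=sleep_min,
        bout_count=n_bouts,
        abl_min=abl,
        latency_min=latency,
        latency_censored=censored,
        waking_activity=waking_activity(series, sleep_state, sel),
        missing_min=int(series.missing[sel].sum()),
        excluded=excluded,
    )


def analysis_days(series: ChannelSeries, n_days: int = 4) -> list[int]:
    """Absolute day indices used for analysis.

    Any leading partial day (loading/acclimation) is discarded; the next
    ``n_days`` complete days are used.  Raises if fewer are available.
    """
    first_abs = series.start_zt
    first_day = -(-first_abs // 1440)  # ceil: first day fully covered
    last_abs = series.start_zt + len(series)
    avail = last_abs // 1440 - first_day
    if avail < n_days:
        raise ValueError(f"only {avail} complete days available, need {n_days}")
    return list(range(first_day, first_day + n_days))


def sleep_profile(
    series: ChannelSeries,
    sleep_state: np.ndarray,
    days: list[int] | None = None,
    bin_min: int = 30,
) -> np.ndarray:
    """Mean sleep minutes per ZT bin (48 bins of 30 min by default).

    Bin *b* is the mean over the analysis days of sleep minutes in
    ``[bin_min*b, bin_min*(b+1))``; the vector sums to mean daily sleep.
    """
    if 1440 % bin_min:
        raise ValueError("bin_min must divide 1440")
    if days is None:
        n = (series.start_zt + len(series)) // 1440 - -(-series.start_zt // 1440)
        if n < 1:
            raise ValueError("need at least one complete day")
        days = analysis_days(series, n)
    tail = (series.start_zt + len(series)) % 1440
    if tail:
        warnings.warn("partial final day excluded from profile", stacklevel=2)
    per_day = []
    for d in days:
        sel = _day_slice(series, d)
        per_day.append(sleep_state[sel].reshape(1440 // bin_min, bin_min).sum(axis=1))
    return np.mean(per_day, axis=0)


@dataclass(frozen=True)
class FlySummary:
    """Per-fly summary over the analysis days.

    ABL is pooled (total sleep over analysis days / total bout count), giving
    a single per-fly statistic for group tests rather than a mean of daily
    ABLs.
    """

    fly_id: str
    genotype: str
    sex: str
    treatment: str
    experiment_id: str
    n_days: int
    sleep_min_per_day: float
    abl_min: float
    bout_count_per_day: float
    latency_min: float
    n_latency_censored: int
    waking_activity: float
    excluded: bool


def fly_summary(
    series: ChannelSeries,
    n_days: int = 4,
    threshold_min: int = SLEEP_THRESHOLD_MIN,
    dead_from_abs: int | None = None,
) -> FlySummary:
    sleep_state, bouts = score_sleep(series, threshold_min)
    days = analysis_days(series, n_days)
    per_day = [
        daily_metrics(series, d, sleep_state, bouts,
                      dead_from_abs=dead_from_abs)
        for d in days
    ]
    total_sleep = sum(m.sleep_min for m in per_day)
    total_bouts = sum(m.bout_count for m in per_day)
    wa = [m.waking_activity for m in per_day if not math.isnan(m.waking_activity)]
    return FlySummary(
        fly_id=series.fly_id,
        genotype=series.genotype,
        sex=series.sex,
        treatment=series.treatment,
        experiment_id=series.experiment_id,
        n_days=len(days),
        sleep_min_per_day=total_sleep / len(days),
        abl_min=total_sleep / total_bouts if total_bouts else math.nan,
        bout_count_per_day=total_bouts / len(days),
        latency_min=float(np.mean([m.latency_min for m in per_day])),
        n_latency_censored=sum(m.latency_censored for m in per_day),
        waking_activity=float(np.mean(wa)) if wa else math.nan,
        excluded=any(m.excluded for m in per_day),
    )


def cohort_table(summaries: list[FlySummary]) -> pd.DataFrame:
    """Tidy per-fly table (one row per fly) for cohort statistics."""
    df = pd.DataFrame([vars(s) for s in summaries])
    return df[~df["excluded"]].reset_index(drop=True) if len(df) else df
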