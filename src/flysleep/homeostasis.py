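"""Quantifying the homeostatic response to mechanical sleep deprivation.

Protocol: after acclimation and a complete baseline day, flies are deprived
of sleep by mechanical stimulation — 12 h designs run ZT11-ZT23, 24 h designs
ZT0-ZT0 — and rebound is measured in recovery windows anchored at deprivation
end (defaults 6 h and 9 h).  For each fly, Δsleep in a window is recovery
sleep minus sleep in the recovery-matched ZT window of the baseline day;
cohort-adjusted Δsleep then subtracts the mean Δsleep of time-matched
non-deprived controls, removing shared day-to-day drift.  %Δsleep expresses
the adjusted change relative to the fly's baseline sleep in the same window.

Deprivation efficacy — the percent of baseline-window sleep abolished by the
stimulation — is reported alongside; the protocol is considered effective
when it removes at least 90%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dam_io import ChannelSeries
from .screen_stats import GroupComparison, compare_groups

__all__ = [
    "DeprivationDesign",
    "ReboundResult",
    "window_sleep",
    "deprivation_efficacy",
    "delta_sleep",
    "percent_delta_sleep",
]


@dataclass(frozen=True)
class DeprivationDesign:
    """Timing of a deprivation experiment on the absolute-minute axis.

    ``dep_day`` is the absolute day index on which deprivation starts;
    ``baseline_day`` defaults to the preceding day, which must itself follow
    at least 36 h of acclimation in the recording.
    """

    dep_day: int
    dep_start_zt: int = 660  # ZT11
    dep_duration_min: int = 720
    recovery_windows: tuple[int, ...] = (360, 540)
    baseline_day: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_day is None:
            object.__setattr__(self, "baseline_day", self.dep_day - 1)
        if self.baseline_day >= self.dep_day:
            raise ValueError("baseline day must precede deprivation")
        for w in self.recovery_windows:
            if w <= 0:
                raise ValueError("recovery windows must be positive")

    @classmethod
    def twelve_hour(cls, dep_day: int, **kw) -> "DeprivationDesign":
        return cls(dep_day=dep_day, dep_start_zt=660, dep_duration_min=720, **kw)

    @classmethod
    def twenty_four_hour(cls, dep_day: int, **kw) -> "DeprivationDesign":
        return cls(dep_day=dep_day, dep_start_zt=0, dep_duration_min=1440, **kw)

    @property
    def dep_start_abs(self) -> int:
        return self.dep_day * 1440 + self.dep_start_zt

    @property
    def dep_end_abs(self) -> int:
        return self.dep_start_abs + self.dep_duration_min

    def baseline_window_abs(self, window_min: int) -> int:
        """Start (abs minute) of the baseline window matched to a recovery window.

        Anchored at the deprivation-end ZT on the baseline day; it may run
        into the pre-deprivation morning of the deprivation day, which is
        undisturbed by construction (checked).
        """
        start = self.baseline_day * 1440 + (
            (self.dep_start_zt + self.dep_duration_min) % 1440
        )
        if start < self.dep_start_abs < start + window_min:
            raise ValueError("baseline window overlaps deprivation")
        return start


def window_sleep(
    series: ChannelSeries, sleep_state: np.ndarray, abs_start: int, duration_min: int
) -> int:
    """Scored sleep minutes in the absolute window [abs_start, abs_start+dur)."""
    i = series.index_of(abs_start)
    j = i + duration_min
    if j > len(series):
        raise ValueError("window extends past end of recording")
    return int(sleep_state[i:j].sum())


def deprivation_efficacy(
    series: ChannelSeries, sleep_state: np.ndarray, design: DeprivationDesign
) -> float:
    """Percent of baseline-window sleep lost during the deprivation window.

    100 * (1 - dep-window sleep / baseline sleep in the same ZT window of the
    baseline day).  Flies with zero baseline-window sleep return NaN and are
    excluded from cohort efficacy.
    """
    base_start = design.baseline_day * 1440 + design.dep_start_zt
    baseline = window_sleep(series, sleep_state, base_start, design.dep_duration_min)
    if baseline == 0:
        return math.nan
    deprived = window_sleep(
        series, sleep_state, design.dep_start_abs, design.dep_duration_min
    )
    return 100.0 * (1.0 - deprived / baseline)


def percent_delta_sleep(adjusted_delta: float, baseline_window_sleep: float) -> float:
    """%Δsleep: adjusted Δsleep relative to the fly's baseline-window sleep."""
    if baseline_window_sleep <= 0:
        return math.nan
    return 100.0 * adjusted_delta / baseline_window_sleep


@dataclass
class ReboundResult:
    """Per-window rebound summary for a deprived cohort vs its control."""

    window_min: int
    per_fly: pd.DataFrame  # fly_id, cohort, baseline, recovery, delta, adjusted, pct
    mean_adjusted: float
    sem_adjusted: float
    mean_pct: float
    sem_pct: float
    comparison: GroupComparison  # deprived Δ vs control Δ
    n_deprived: int
    n_control: int
    mean_control_delta: float = field(default=math.nan)


def _window_deltas(cohort, design: DeprivationDesign, window_min: int):
    base_start = design.baseline_window_abs(window_min)
    rows = []
    for series, sleep_state in cohort:
        b = window_sleep(series, sleep_state, base_start, window_min)
        r = window_sleep(series, sleep_state, design.dep_end_abs, window_min)
        rows.append((series.fly_id, b, r, r - b))
    return rows


def delta_sleep(
    deprived: list[tuple[ChannelSeries, np.ndarray]],
    control: list[tuple[ChannelSeries, np.ndarray]],
    design: DeprivationDesign,
) -> dict[int, ReboundResult]:
    """Control-corrected Δsleep per recovery window.

    Per fly, Δ = recovery-window sleep minus the matched baseline-window
    sleep; each deprived fly's adjusted Δ subtracts the mean control Δ.
    Returns one :class:`ReboundResult` per recovery window length.
    """
    if not deprived or not control:
        raise ValueError("both cohorts must be non-empty")
    out: dict[int, ReboundResult] = {}
    for w in design.recovery_windows:
        dep_rows = _window_deltas(deprived, design, w)
        ctl_rows = _window_deltas(control, design, w)
        ctl_delta = np.array([r[3] for r in ctl_rows], dtype=float)
        dep_delta = np.array([r[3] for r in dep_rows], dtype=float)
        ctl_mean = float(ctl_delta.mean())
        adjusted = dep_delta - ctl_mean
        pct = np.array(
            [percent_delta_sleep(a, r[1]) for a, r in zip(adjusted, dep_rows)]
        )
        per_fly = pd.DataFrame(
            [
                {
                    "fly_id": r[0],
                    "cohort": "deprived",
                    "baseline_sleep": r[1],
                    "recovery_sleep": r[2],
                    "delta_sleep": r[3],
                    "adjusted_delta": a,
                    "pct_delta": p,
                }
                for r, a, p in zip(dep_rows, adjusted, pct)
            ]
            + [
                {
                    "fly_id": r[0],
                    "cohort": "control",
                    "baseline_sleep": r[1],
                    "recovery_sleep": r[2],
                    "delta_sleep": r[3],
                    "adjusted_delta": math.nan,
                    "pct_delta": math.nan,
                }
                for r in ctl_rows
            ]
        )
        finite_pct = pct[np.isfinite(pct)]
        out[w] = ReboundResult(
            window_min=w,
            per_fly=per_fly,
            mean_adjusted=float(adjusted.mean()),
            sem_adjusted=float(adjusted.std(ddof=1) / math.sqrt(len(adjusted)))
            if len(adjusted) > 1
            else math.nan,
            mean_pct=float(finite_pct.mean()) if finite_pct.size else math.nan,
            sem_pct=float(finite_pct.std(ddof=1) / math.sqrt(finite_pct.size))
            if finite_pct.size > 1
            else math.nan,
            comparison=compare_groups(dep_delta, ctl_delta, metric_kind="delta_sleep"),
            n_deprived=len(dep_rows),
            n_control=len(ctl_rows),
            mean_control_delta=ctl_mean,
        )
    return out
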