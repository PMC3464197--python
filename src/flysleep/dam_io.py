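"""Reading and writing Drosophila Activity Monitor (DAM) data.

The Trikinetics DAM system houses single flies in glass tubes crossed by an
infrared beam; each monitor reports 32 channels of per-interval beam-crossing
counts.  This module parses the DAMSystem3 plain-text dialect (tab-separated:
record index, date ``"D Mon YY"``, time ``"HH:MM:SS"``, a status code where 1
means valid, six auxiliary columns that are ignored, then 32 channel counts),
binds channels to experimental metadata, and aligns clock time to zeitgeber
time (ZT; ZT0 = lights-on, minutes, modulo the cycle length).

Records carrying a non-valid status code are retained but flagged *missing*;
downstream sleep scoring treats a missing minute as breaking an inactivity
run, so monitor outages can never fabricate sleep.  Files sampled faster than
once per minute are re-binned to 1-minute counts by summation; gaps in the
timestamp grid are filled with missing-flagged minutes.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LightSchedule",
    "ChannelSeries",
    "ExperimentLayout",
    "DAMParseError",
    "assign_zt",
    "read_dam_records",
    "read_dam_file",
    "write_dam_file",
    "detect_dead_flies",
    "censor_after_death",
    "load_config",
]

N_CHANNELS = 32
_N_META_COLS = 10  # index, date, time, status, 6 auxiliary
_VALID_STATUS = 1


class DAMParseError(ValueError):
    """Raised for malformed DAM files; carries the offending line number."""


@dataclass(frozen=True)
class LightSchedule:
    """A light:dark schedule anchoring zeitgeber time.

    Parameters
    ----------
    lights_on_clock : datetime.time
        Wall-clock time of lights-on (ZT0).
    photoperiod_min : int
        Minutes of light per cycle (default 720, i.e. 12 h:12 h light:dark).
    cycle_min : int
        Minutes per full cycle (default 1440).
    """

    lights_on_clock: dt.time = dt.time(8, 0)
    photoperiod_min: int = 720
    cycle_min: int = 1440

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_min < self.cycle_min:
            raise ValueError("need 0 < photoperiod_min < cycle_min")

    def zt_of(self, when: dt.datetime | dt.time) -> int:
        """ZT minute in [0, cycle_min) of a clock time; lights-on maps to 0."""
        t = when.time() if isinstance(when, dt.datetime) else when
        minutes = t.hour * 60 + t.minute
        on = self.lights_on_clock.hour * 60 + self.lights_on_clock.minute
        return (minutes - on) % self.cycle_min

    def is_light(self, zt_minute: int) -> bool:
        return (zt_minute % self.cycle_min) < self.photoperiod_min


def assign_zt(clock_time: dt.datetime | dt.time, schedule: LightSchedule) -> int:
    """Map a clock time to its zeitgeber minute under ``schedule``."""
    return schedule.zt_of(clock_time)


@dataclass
class ChannelSeries:
    """One fly's minute-resolution beam-crossing counts aligned to ZT.

    ``counts[i]`` is the number of beam crossings in the half-open minute
    ``[start_zt + i, start_zt + i + 1)`` of the *absolute* minute axis, where
    absolute minute ``a`` has zeitgeber time ``a % 1440`` and day index
    ``a // 1440``.  ``missing[i]`` marks minutes whose monitor record was
    flagged invalid or absent; their counts are kept but never trusted.
    """

    fly_id: str
    counts: np.ndarray
    start_zt: int = 0
    genotype: str = ""
    sex: str = ""
    treatment: str = ""
    missing: np.ndarray | None = None
    monitor_id: str = ""
    channel: int = 0
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.missing is None:
            self.missing = np.zeros(self.counts.size, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts length")
        self.start_zt = int(self.start_zt) % 1440

    def __len__(self) -> int:
        return self.counts.size

    @property
    def abs_minutes(self) -> np.ndarray:
        """Absolute minute coordinate of every sample (start_zt-anchored)."""
        return self.start_zt + np.arange(self.counts.size)

    @property
    def zt(self) -> np.ndarray:
        return self.abs_minutes % 1440

    def index_of(self, abs_minute: int) -> int:
        """Array index of an absolute minute; raises if outside recording."""
        i = int(abs_minute) - self.start_zt
        if not 0 <= i < len(self):
            raise IndexError(
                f"absolute minute {abs_minute} outside recording "
                f"[{self.start_zt}, {self.start_zt + len(self)})"
            )
        return i


@dataclass
class ExperimentLayout:
    """Maps (monitor, channel) to genotype/sex/treatment labels.

    ``channels`` is ``{monitor_id: {channel (1..32): {"genotype": ...,
    "sex": ..., "treatment": ...}}}``.  Each (monitor, channel) pair holds at
    most one fly by construction.
    """

    experiment_id: str
    channels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.experiment_id:
            raise ValueError("experiment_id must be non-empty")

    def lookup(self, monitor_id: str, channel: int) -> dict | None:
        return self.channels.get(monitor_id, {}).get(channel)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentLayout":
        channels = {
            str(mon): {int(ch): dict(meta) for ch, meta in chans.items()}
            for mon, chans in d.get("monitors", {}).items()
        }
        return cls(experiment_id=str(d.get("experiment_id", "")), channels=channels)


def load_config(path: str | Path) -> tuple[ExperimentLayout, LightSchedule]:
    """Load a YAML experiment config: layout plus light schedule.

    Keys: ``experiment_id``, ``lights_on`` ("HH:MM"), optional
    ``photoperiod_min``/``cycle_min``, and ``monitors`` mapping monitor ids to
    channel metadata.
    """
    with open(path) as fh:
        d = yaml.safe_load(fh)
    layout = ExperimentLayout.from_dict(d)
    hh, mm = str(d.get("lights_on", "08:00")).split(":")[:2]
    schedule = LightSchedule(
        lights_on_clock=dt.time(int(hh), int(mm)),
        photoperiod_min=int(d.get("photoperiod_min", 720)),
        cycle_min=int(d.get("cycle_min", 1440)),
    )
    return layout, schedule


def _parse_timestamp(date_str: str, time_str: str, lineno: int) -> dt.datetime:
    try:
        day, mon, yy = date_str.strip().split()
        t = dt.datetime.strptime(f"{int(day):02d} {mon} {yy} {time_str.strip()}",
                                 "%d %b %y %H:%M:%S")
        return t
    except Exception as exc:  # noqa: BLE001 - re-raised with context
        raise DAMParseError(f"line {lineno}: bad timestamp {date_str!r} {time_str!r}") from exc


def read_dam_records(path: str | Path):
    """Low-level parse of a DAM file.

    Returns ``(timestamps, status, counts)`` where ``counts`` has shape
    ``(n_records, 32)``.  Raises :class:`DAMParseError` naming the line for a
    malformed row and ``ValueError`` for non-monotone timestamps.
    """
    timestamps: list[dt.datetime] = []
    status: list[int] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != _N_META_COLS + N_CHANNELS:
                raise DAMParseError(
                    f"line {lineno}: expected {_N_META_COLS + N_CHANNELS} "
                    f"tab-separated columns, got {len(cols)}"
                )
            ts = _parse_timestamp(cols[1], cols[2], lineno)
            try:
                st = int(cols[3])
                counts = [int(c) for c in cols[_N_META_COLS:]]
            except ValueError as exc:
                raise DAMParseError(f"line {lineno}: non-integer field") from exc
            timestamps.append(ts)
            status.append(st)
            rows.append(counts)
    if not rows:
        raise DAMParseError("empty DAM file")
    ts_arr = np.array(timestamps)
    if len(ts_arr) > 1 and not all(b > a for a, b in zip(timestamps, timestamps[1:])):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    return timestamps, np.array(status), np.array(rows, dtype=np.int64)


def _to_minute_grid(timestamps, status, counts):
    """Re-bin records onto a 1-minute grid (summing sub-minute intervals).

    Minutes with no record, or whose records carry an invalid status code,
    are flagged missing.  Returns (first_minute_dt, minute_counts, missing).
    """
    t0 = timestamps[0].replace(second=0)
    offsets = np.array(
        [int((ts - t0).total_seconds() // 60) for ts in timestamps], dtype=np.int64
    )
    if len(timestamps) > 1:
        deltas = [
            (b - a).total_seconds() for a, b in zip(timestamps, timestamps[1:])
        ]
        base = min(deltas)
        if base > 60.0:
            raise ValueError(
                f"sampling interval {base:.0f}s is coarser than 1 min; "
                "cannot re-bin to minutes"
            )
    n_min = int(offsets[-1]) + 1
    minute_counts = np.zeros((n_min, counts.shape[1]), dtype=np.int64)
    seen = np.zeros(n_min, dtype=bool)
    invalid = np.zeros(n_min, dtype=bool)
    np.add.at(minute_counts, offsets, counts)
    seen[offsets] = True
    invalid[offsets[status != _VALID_STATUS]] = True
    missing = ~seen | invalid
    return t0, minute_counts, missing


def read_dam_file(
    path: str | Path,
    layout: ExperimentLayout,
    schedule: LightSchedule,
    monitor_id: str | None = None,
) -> list[ChannelSeries]:
    """Read a DAM file and return one :class:`ChannelSeries` per mapped channel.

    ``monitor_id`` defaults to the file's stem.  Channels present in the file
    but absent from the layout are skipped with a warning; invalid-status
    records are retained with their minutes flagged missing.
    """
    path = Path(path)
    mon = monitor_id if monitor_id is not None else path.stem
    timestamps, status, counts = read_dam_records(path)
    t0, minute_counts, missing = _to_minute_grid(timestamps, status, counts)
    start_zt = assign_zt(t0, schedule)

    series: list[ChannelSeries] = []
    mapped = layout.channels.get(mon, {})
    unmapped = [ch for ch in range(1, N_CHANNELS + 1) if ch not in mapped]
    if unmapped and minute_counts[:, [ch - 1 for ch in unmapped]].any():
        warnings.warn(
            f"{path.name}: skipping active unmapped channels {unmapped}",
            stacklevel=2,
        )
    for ch in sorted(mapped):
        meta = mapped[ch]
        series.append(
            ChannelSeries(
                fly_id=f"{mon}:{ch:02d}",
                counts=minute_counts[:, ch - 1],
                start_zt=start_zt,
                genotype=str(meta.get("genotype", "")),
                sex=str(meta.get("sex", "")),
                treatment=str(meta.get("treatment", "")),
                missing=missing.copy(),
                monitor_id=mon,
                channel=ch,
                experiment_id=layout.experiment_id,
            )
        )
    return series


def write_dam_file(
    path: str | Path,
    counts: np.ndarray,
    start: dt.datetime,
    status: np.ndarray | None = None,
) -> None:
    """Write a (n_minutes, 32) count matrix as a DAMSystem3-dialect text file."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != N_CHANNELS:
        raise ValueError(f"counts must have shape (n, {N_CHANNELS})")
    if status is None:
        status = np.full(counts.shape[0], _VALID_STATUS, dtype=np.int64)
    aux = "\t".join(["0"] * 6)
    with open(path, "w") as fh:
        for i in range(counts.shape[0]):
            ts = start + dt.timedelta(minutes=i)
            date = f"{ts.day} {ts:%b %y}"
            row = "\t".join(str(c) for c in counts[i])
            fh.write(f"{i + 1}\t{date}\t{ts:%H:%M:%S}\t{int(status[i])}\t{aux}\t{row}\n")


@dataclass(frozen=True)
class DeadFlyReport:
    dead: bool
    last_activity_abs: int | None  # absolute minute of last beam crossing


def detect_dead_flies(series: ChannelSeries, window_min: int = 1440) -> DeadFlyReport:
    """Flag a fly as dead if its trailing ``window_min`` minutes are all zero.

    Returns the absolute minute of the last beam crossing (None if the fly
    never moved).  Raises if the recording is shorter than the window.
    """
    if len(series) < window_min:
        raise ValueError(
            f"recording ({len(series)} min) shorter than dead-fly window "
            f"({window_min} min)"
        )
    dead = not series.counts[-window_min:].any()
    nz = np.flatnonzero(series.counts)
    last = int(series.start_zt + nz[-1]) if nz.size else None
    return DeadFlyReport(dead=bool(dead), last_activity_abs=last)


def censor_after_death(
    series: ChannelSeries, window_min: int = 1440
) -> tuple[ChannelSeries, DeadFlyReport]:
    """Mark every minute after a dead fly's last activity as missing.

    Applied before cohort statistics so moribund tails never count as sleep.
    Live flies are returned unchanged.
    """
    report = detect_dead_flies(series, window_min)
    if not report.dead:
        return series, report
    cut = 0 if report.last_activity_abs is None else (
        report.last_activity_abs - series.start_zt + 1
    )
    missing = series.missing.copy()
    missing[cut:] = True
    return replace(series, counts=series.counts.copy(), missing=missing), report
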