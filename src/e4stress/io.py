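"""Reading and writing Empatica-E4-style channel exports and protocol schedules.

The E4 export convention stores one channel per CSV file: the first line is
the recording start time (UTC seconds), the second line the sampling rate in
Hz, and every following line one sample. BVP is exported at 64 Hz, EDA at
4 Hz (µS).

A :class:`ProtocolSchedule` describes the alternating rest/task structure of
a recording session as half-open intervals ``[start_s, end_s)`` relative to
the recording start, each carrying a binary stress label (0 = rest,
1 = task).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "E4FormatError",
    "ConfigurationError",
    "SampledSignal",
    "ScheduleInterval",
    "ProtocolSchedule",
    "read_e4_channel",
    "write_e4_channel",
    "label_schedule_from_protocol",
]


class E4FormatError(ValueError):
    """A channel file does not follow the E4 export dialect."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete user configuration."""


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    values : ndarray
        Samples in file order (µS for EDA, arbitrary units for BVP).
    rate_hz : float
        Sampling rate, strictly positive.
    start_utc_s : float
        Recording start time in UTC seconds.
    """

    values: np.ndarray
    rate_hz: float
    start_utc_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("signal contains non-finite samples")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Exact duration; no implicit resampling happens at read time."""
        return self.n_samples / self.rate_hz

    def times_s(self) -> np.ndarray:
        """Sample times in seconds relative to the recording start."""
        return np.arange(self.n_samples) / self.rate_hz


@dataclass(frozen=True)
class ScheduleInterval:
    start_s: float
    end_s: float
    label: int
    name: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"interval {self.name!r}: start must precede end")
        if self.label not in (0, 1):
            raise ValueError(f"interval {self.name!r}: label must be 0 or 1")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered, non-overlapping rest/task intervals of one session."""

    intervals: tuple[ScheduleInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"intervals {a.name!r} and {b.name!r} overlap or are unsorted"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)

    @property
    def end_s(self) -> float:
        return self.intervals[-1].end_s if self.intervals else 0.0

    def label_at(self, t_s: float) -> int | None:
        """Label of the interval containing ``t_s`` (half-open), else None."""
        for iv in self.intervals:
            if iv.start_s <= t_s < iv.end_s:
                return iv.label
        return None


def read_e4_channel(
    path: str | Path, expected_rate_hz: float | None = None
) -> SampledSignal:
    """Read one E4-dialect channel file.

    Line 1 is the UTC start time, line 2 the sampling rate in Hz, then one
    sample per line. If ``expected_rate_hz`` is given the declared rate must
    match it exactly.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise E4FormatError(
            f"{path}: need two header lines plus at least one sample"
        )
    try:
        start_utc_s = float(lines[0])
    except ValueError as exc:
        raise E4FormatError(f"{path}: line 1 is not a UTC timestamp") from exc
    try:
        rate_hz = float(lines[1])
    except ValueError as exc:
        raise E4FormatError(f"{path}: line 2 is not a sampling rate") from exc
    if expected_rate_hz is not None and rate_hz != expected_rate_hz:
        raise ConfigurationError(
            f"{path}: declared rate {rate_hz} Hz != expected {expected_rate_hz} Hz"
        )
    try:
        values = np.array([float(v) for v in lines[2:]], dtype=float)
    except ValueError as exc:
        raise E4FormatError(f"{path}: non-numeric sample value") from exc
    return SampledSignal(values=values, rate_hz=rate_hz, start_utc_s=start_utc_s)


def write_e4_channel(signal: SampledSignal, path: str | Path, precision: int = 6) -> None:
    """Write a signal in the E4 export dialect (inverse of :func:`read_e4_channel`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{signal.start_utc_s:.6f}\n")
        fh.write(f"{signal.rate_hz:.6f}\n")
        for v in signal.values:
            fh.write(f"{v:.{precision}f}\n")


# Acquisition protocol: baseline rest, then five tasks separated by 2-minute
# rests. The fourth task (serial subtraction) has no intrinsic time limit and
# must be configured explicitly.
_DEFAULT_TASK_DURATIONS_S: dict[str, float] = {
    "task1": 600.0,  # Lego assembly without instructions (10 min)
    "task2": 300.0,  # Lego assembly with instructions (5 min)
    "task3": 180.0,  # assembly while counting down (3 min)
    "task5": 60.0,  # one-minute oral self-presentation
}
_TASK_ORDER: tuple[str, ...] = ("task1", "task2", "task3", "task4", "task5")


def label_schedule_from_protocol(
    task_durations: Mapping[str, float],
    baseline_rest_s: float = 180.0,
    inter_task_rest_s: float = 120.0,
) -> ProtocolSchedule:
    """Build the alternating rest/task schedule of the acquisition protocol.

    The protocol is: 180 s baseline rest, then five tasks each followed by a
    120 s rest (the last rest precedes the final one-minute presentation).
    ``task_durations`` overrides the default task lengths and **must** supply
    ``task4`` (the untimed arithmetic task) explicitly.
    """
    if not task_durations:
        raise ConfigurationError("task_durations must not be empty")
    durations = dict(_DEFAULT_TASK_DURATIONS_S)
    durations.update({k: float(v) for k, v in task_durations.items()})
    missing = [name for name in _TASK_ORDER if name not in durations]
    if missing:
        raise ConfigurationError(f"missing required task duration(s): {missing}")
    bad = {k: v for k, v in durations.items() if not v > 0}
    if bad or not baseline_rest_s > 0 or not inter_task_rest_s > 0:
        raise ConfigurationError(f"all durations must be positive (bad: {bad})")

    intervals: list[ScheduleInterval] = []
    t = 0.0

    def add(duration: float, label: int, name: str) -> None:
        nonlocal t
        intervals.append(ScheduleInterval(t, t + duration, label, name))
        t += duration

    add(baseline_rest_s, 0, "rest_baseline")
    for i, task in enumerate(_TASK_ORDER):
        if i > 0:
            add(inter_task_rest_s, 0, f"rest{i}")
        add(durations[task], 1, task)
    return ProtocolSchedule(tuple(intervals))


def schedule_to_dict(schedule: ProtocolSchedule) -> list[dict]:
    """JSON/YAML-serializable form of a schedule."""
    return [
        {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label, "name": iv.name}
        for iv in schedule
    ]


def schedule_from_dict(entries: Sequence[Mapping]) -> ProtocolSchedule:
    return ProtocolSchedule(
        tuple(
            ScheduleInterval(
                float(e["start_s"]), float(e["end_s"]), int(e["label"]), str(e["name"])
            )
            for e in entries
        )
    )
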