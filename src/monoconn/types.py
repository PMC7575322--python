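"""Core in-memory containers for spike-train connectivity analysis.

Times are seconds (float64) everywhere inside the package; file formats that
store integer sample indices are converted on load using a sampling rate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class CellType(enum.Enum):
    """Putative unit class from waveform/autocorrelation-based sorting."""

    PYRAMIDAL = "pyramidal"
    INTERNEURON = "interneuron"
    UNKNOWN = "unknown"


SESSION_LABELS = ("FAM1", "NOV", "FAML", "FAM2", "REST")


@dataclass(frozen=True)
class SpikeTrain:
    """One unit's spike times with identity and putative cell type.

    Parameters
    ----------
    cell_id :
        Unique unit label within the dataset.
    animal_id :
        Recording-animal label; used as the random-effect grouping factor
        in the statistical layer.
    cell_type :
        Putative class (pyramidal / interneuron / unknown).
    spikes :
        Strictly ascending spike times in seconds, all >= 0.
    """

    cell_id: str
    animal_id: str
    cell_type: CellType
    spikes: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.spikes, dtype=np.float64)
        object.__setattr__(self, "spikes", arr)
        if arr.ndim != 1:
            raise ValueError("spikes must be a 1-D sequence of times")
        if arr.size and arr[0] < 0:
            raise ValueError("spike times must be non-negative")
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError("spike times must be strictly ascending")

    @property
    def n_spikes(self) -> int:
        return int(self.spikes.size)

    def restrict(self, start_s: float, end_s: float) -> np.ndarray:
        """Spike times in the half-open interval [start_s, end_s)."""
        lo, hi = np.searchsorted(self.spikes, [start_s, end_s], side="left")
        return self.spikes[lo:hi]

    def restrict_to_intervals(self, intervals: Iterable[tuple[float, float]]) -> np.ndarray:
        """Concatenated spikes falling in any of the given intervals."""
        parts = [self.restrict(a, b) for a, b in intervals]
        if not parts:
            return np.empty(0, dtype=np.float64)
        return np.concatenate(parts)


@dataclass(frozen=True)
class Interval:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"interval {self.label}: start must precede end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, other: "Interval") -> bool:
        return self.start_s <= other.start_s and other.end_s <= self.end_s


@dataclass
class SessionSet:
    """Labeled non-overlapping session intervals plus light-event intervals.

    Sessions are ordered by start time on construction. Every light interval
    must lie inside some session interval.
    """

    sessions: list[Interval] = field(default_factory=list)
    light_intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.sessions:
            if s.label not in SESSION_LABELS:
                raise ValueError(
                    f"unknown session label {s.label!r}; expected one of {SESSION_LABELS}"
                )
        self.sessions = sorted(self.sessions, key=lambda s: s.start_s)
        for a, b in zip(self.sessions, self.sessions[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"sessions {a.label} and {b.label} overlap")
        for li in self.light_intervals:
            if not any(s.contains(li) for s in self.sessions):
                raise ValueError(
                    f"light interval [{li.start_s}, {li.end_s}] lies outside all sessions"
                )
        self.light_intervals = sorted(self.light_intervals, key=lambda s: s.start_s)

    def __getitem__(self, label: str) -> Interval:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(label)

    def __contains__(self, label: str) -> bool:
        return any(s.label == label for s in self.sessions)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sessions]

    @property
    def span(self) -> tuple[float, float]:
        """(earliest session start, latest session end)."""
        if not self.sessions:
            raise ValueError("empty SessionSet has no span")
        return self.sessions[0].start_s, self.sessions[-1].end_s

    def lights_within(self, label: str) -> list[Interval]:
        sess = self[label]
        return [li for li in self.light_intervals if sess.contains(li)]


def as_spike_array(times: Sequence[float] | np.ndarray) -> np.ndarray:
    """Coerce to a sorted float64 array (helper for loaders and simulators)."""
    arr = np.asarray(times, dtype=np.float64).ravel()
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        arr = np.sort(arr)
    return arr
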