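"""Core containers shared across the analysis modules.

All times are seconds from the session origin unless a name says otherwise;
intervals are half-open ``[onset, offset)``.  Every timestamped object carries
the name of the acquisition clock it was recorded on, because the two recording
systems (extracellular array and patch amplifier) run on independent clocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeTrainSet",
    "RateSeries",
    "BurstEvent",
]


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled voltage signal.

    Parameters
    ----------
    samples:
        Signal values in physical units (``unit``).
    fs:
        Sampling rate in Hz.
    t0:
        Time of the first sample, in seconds on ``clock_id``.
    unit:
        ``"uV"`` for extracellular traces, ``"mV"`` for membrane potential.
    clock_id:
        Name of the acquisition clock the timestamps refer to.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    unit: str = "uV"
    clock_id: str = "mea"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds on ``clock_id``."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "VoltageTrace":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class SpikeTrainSet:
    """Per-channel sorted spike times, in seconds on a named clock."""

    trains: tuple[np.ndarray, ...]
    clock_id: str = "mea"

    def __post_init__(self) -> None:
        cleaned = []
        for train in self.trains:
            t = np.asarray(train, dtype=float).ravel()
            if np.any(np.diff(t) < 0):
                t = np.sort(t)
            cleaned.append(t)
        object.__setattr__(self, "trains", tuple(cleaned))

    @property
    def n_channels(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def all_times(self) -> np.ndarray:
        """All spike times pooled across channels, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))

    @classmethod
    def from_lists(cls, trains: Sequence[Sequence[float]], clock_id: str = "mea") -> "SpikeTrainSet":
        return cls(tuple(np.asarray(t, dtype=float) for t in trains), clock_id=clock_id)


@dataclass(frozen=True)
class RateSeries:
    """Network temporal rate r(t) on a uniform grid, in Hz per electrode."""

    times: np.ndarray
    values: np.ndarray
    kernel_std_ms: float
    n_electrodes: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if times.size >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
                raise ValueError("time grid must be uniform and strictly increasing")
        if np.any(values < -1e-12):
            raise ValueError("rate values must be non-negative")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("grid too short to define a step")
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class BurstEvent:
    """A detected or ground-truth burst interval ``[onset, offset)``."""

    onset: float
    offset: float
    level: str = "sub"  # "sub" or "entire"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("burst offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset
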