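"""Shared containers: spike trains and uniformly sampled traces.

A :class:`SpikeTrain` holds the discharge times of one motor unit (MU) in
seconds.  :class:`DriveTrace` and :class:`ForceTrace` hold a uniformly
sampled signal (common synaptic drive and dorsiflexion force respectively),
both expressed in %MVC (percent of maximum voluntary contraction).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeTrain", "SampledTrace", "DriveTrace", "ForceTrace",
           "MIN_SPIKE_SEPARATION_S"]

#: discharges closer than 0.1 ms are treated as duplicates (physiologically
#: impossible for a single motor neuron; refractory period is a few ms)
MIN_SPIKE_SEPARATION_S = 1e-4


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered discharge times of a single motor unit.

    Parameters
    ----------
    unit_id:
        Identifier of the unit (e.g. ``"mu03"``).
    times:
        Discharge times in seconds; strictly increasing, non-negative,
        no duplicates within 0.1 ms.
    """

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size:
            if not np.all(np.isfinite(t)):
                raise ValueError("spike times must be finite")
            if t[0] < 0:
                raise ValueError("spike times must be non-negative")
            if t.size > 1 and np.any(np.diff(t) < MIN_SPIKE_SEPARATION_S):
                raise ValueError(
                    "spike times must be strictly increasing with no "
                    "duplicates within 0.1 ms")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    def count_between(self, t0: float, t1: float) -> int:
        """Number of discharges in the closed interval ``[t0, t1]``."""
        i0 = np.searchsorted(self.times, t0, side="left")
        i1 = np.searchsorted(self.times, t1, side="right")
        return int(i1 - i0)

    def shifted(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.unit_id, self.times + dt)


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled signal starting at time ``t0``."""

    fs: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def duration(self) -> float:
        """Length of the covered interval ``[t0, t0 + n/fs)`` in seconds."""
        return len(self) / self.fs

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration

    def value_at(self, t) -> np.ndarray:
        """Nearest-sample lookup (vectorised)."""
        idx = np.clip(np.round((np.asarray(t) - self.t0) * self.fs).astype(int),
                      0, len(self) - 1)
        return self.values[idx]


@dataclass(frozen=True)
class DriveTrace(SampledTrace):
    """Common synaptic drive to the pool, in %MVC-equivalent units."""


@dataclass(frozen=True)
class ForceTrace(SampledTrace):
    """Dorsiflexion force in %MVC."""
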