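"""Spike-train containers shared by the periphery models and the EI neuron."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "SpikeEnsemble"]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of a single fiber.

    Attributes
    ----------
    times : ndarray
        Spike times in s, strictly increasing, within [0, duration].
    duration : float
        Observation interval length, s.
    fiber_id : int
        Identifier within an ensemble.
    """

    times: np.ndarray
    duration: float
    fiber_id: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, float)
        object.__setattr__(self, "times", t)
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times outside [0, duration]")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SpikeEnsemble:
    """Spike trains of a population of fibers on one side."""

    trains: tuple[SpikeTrain, ...]
    duration: float

    def __post_init__(self):
        object.__setattr__(self, "trains", tuple(self.trains))
        for tr in self.trains:
            if abs(tr.duration - self.duration) > 1e-12:
                raise ValueError("all trains must share the ensemble duration")

    @property
    def n_fibers(self) -> int:
        return len(self.trains)

    def pooled(self) -> np.ndarray:
        """All spike times of the population, sorted ascending."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate([tr.times for tr in self.trains]))

    def n_spikes(self) -> int:
        return sum(len(tr) for tr in self.trains)
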