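"""Spike-train statistics and rate-ITD/IPD tuning curves.

Implements the standard single-neuron metrics: peristimulus time histogram,
period histogram, vector strength (modulus of the mean unit phasor of spike
phases), firing rate over an analysis window, tuning-curve construction over
an ITD or IPD grid, the best-worst contrast ``sqrt(r_max) - sqrt(r_min)``
(a Poisson-inspired best-case discrimination metric), and the squared
Pearson correlation between two tuning curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .spikes import SpikeEnsemble, SpikeTrain

__all__ = [
    "TuningCurve",
    "firing_rate",
    "psth",
    "period_histogram",
    "vector_strength",
    "tuning_curve",
    "sqrt_contrast",
    "r_squared",
]


@dataclass(frozen=True)
class TuningCurve:
    """Mean and per-repetition spike rates over an ITD or IPD grid.

    ``axis_kind`` is ``"itd_ms"`` or ``"ipd_rad"``; ``rep_rates`` has shape
    (n_grid, n_reps) in sp/s.
    """

    axis_kind: str
    grid: np.ndarray
    rep_rates: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        r = np.atleast_2d(np.asarray(self.rep_rates, float))
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "rep_rates", r)
        if r.shape[0] != g.size:
            raise ValueError("rep_rates must have one row per grid point")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be sorted ascending")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")

    @property
    def mean_rate(self) -> np.ndarray:
        return self.rep_rates.mean(axis=1)

    @property
    def n_reps(self) -> int:
        return self.rep_rates.shape[1]


def _times(spikes) -> np.ndarray:
    if isinstance(spikes, SpikeEnsemble):
        return spikes.pooled()
    if isinstance(spikes, SpikeTrain):
        return spikes.times
    return np.asarray(spikes, float)


def firing_rate(spikes, window: tuple[float, float]) -> float:
    """Spike count in ``[t0, t1]`` divided by the window length, sp/s."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    t = _times(spikes)
    n = np.searchsorted(t, t1, side="right") - np.searchsorted(t, t0, side="left")
    return float(n) / (t1 - t0)


def psth(spikes, bin_s: float = 0.001, duration: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram; returns (bin_edges, counts)."""
    if bin_s <= 0:
        raise ValueError("bin size must be positive")
    t = _times(spikes)
    if duration is None:
        duration = getattr(spikes, "duration", t[-1] if t.size else bin_s)
    edges = np.arange(0.0, duration + bin_s, bin_s)
    counts, _ = np.histogram(t, bins=edges)
    return edges, counts


def spike_phases(spikes, frequency: float) -> np.ndarray:
    """Spike phases in cycles, in [0, 1)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    t = _times(spikes)
    return np.mod(t * frequency, 1.0)


def period_histogram(spikes, frequency: float, n_bins: int = 50) -> np.ndarray:
    """Histogram of spike phases at the given frequency over ``n_bins`` bins."""
    ph = spike_phases(spikes, frequency)
    counts, _ = np.histogram(ph, bins=n_bins, range=(0.0, 1.0))
    return counts


def vector_strength(spikes, frequency: float) -> float:
    """``|mean(exp(i phi_k))|`` of spike phases at ``frequency``; 1 = perfect locking."""
    ph = spike_phases(spikes, frequency)
    if ph.size == 0:
        raise ValueError("vector strength undefined for an empty spike train")
    return float(np.abs(np.mean(np.exp(2j * np.pi * ph))))


def tuning_curve(
    runner: Callable[[float, int], SpikeTrain],
    grid: Sequence[float],
    n_reps: int,
    window: tuple[float, float],
    axis_kind: str = "itd_ms",
) -> TuningCurve:
    """Build a tuning curve by running ``runner(axis_value, rep)`` on a grid."""
    grid = np.asarray(grid, float)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rates = np.zeros((grid.size, n_reps))
    for j in range(n_reps):
        for i, v in enumerate(grid):
            rates[i, j] = firing_rate(runner(float(v), j), window)
    return TuningCurve(axis_kind, grid, rates)


def sqrt_contrast(curve: TuningCurve) -> float:
    """Best-worst contrast ``sqrt(r_max) - sqrt(r_min)`` of the mean curve."""
    m = curve.mean_rate
    if m.size == 0:
        raise ValueError("empty tuning curve")
    return float(np.sqrt(m.max()) - np.sqrt(m.min()))


def r_squared(a: TuningCurve, b: TuningCurve) -> float:
    """Squared Pearson correlation between two mean tuning curves."""
    if a.grid.size != b.grid.size or not np.allclose(a.grid, b.grid):
        raise ValueError("tuning curves must share a grid")
    x, y = a.mean_rate, b.mean_rate
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: constant tuning curve")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)
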