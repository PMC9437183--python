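"""Stochastic auditory-nerve fiber model for electric pulse-train stimulation.

The single-fiber model has four stages:

1. **Cell membrane** -- a deterministic leaky integrate-and-fire membrane.
   The voltage reached at the end of the first pulse phase is
   ``u = I * gain * (1 - exp(-phase_duration / tau_m))``.
2. **Membrane noise** -- a zero-mean Gaussian draw (sd =
   ``relative_spread * v_threshold``) added independently per pulse, giving
   the fiber its stochastic threshold behaviour.
3. **Refractoriness** -- the effective threshold is scaled by
   ``R(dt) = 1 / (1 - exp(-(dt - t_abs) / tau_rel))`` where ``dt`` is the
   time since the last action potential; spiking is impossible within the
   absolute refractory period ``t_abs``.
4. **Latency and jitter** -- the action potential is emitted at
   ``pulse time + discharge_time + latency draw + jitter draw``.

The model carries no adaptation and the same threshold for every fiber.  The
per-fiber loop evaluates each pulse once, so a pulse either evokes one spike
or none; at high carrier rates refractoriness blocks entrainment.

``gain`` is a calibration constant: it is fixed once such that the
behavioural reference procedure (:func:`find_reference_threshold` on a
40-pps train driving the EI neuron through 20 ipsilateral fibers) lands at
a 240-uA reference current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ei import EIParams, simulate_ei
from .spikes import SpikeEnsemble, SpikeTrain
from .stimuli import ElectricPulseTrain, gen_electric_train

__all__ = [
    "ElectricFiberParams",
    "membrane_first_phase",
    "spike_decision",
    "simulate_electric_fiber",
    "simulate_electric_population",
    "find_reference_threshold",
]


@dataclass(frozen=True)
class ElectricFiberParams:
    """Parameters of the electrically stimulated AN fiber.

    Units: ``tau_m`` in us, ``gain`` in voltage units per uA, times in s.
    ``relative_spread`` is the noise sd over the threshold voltage and sets
    the width of the single-pulse firing-probability curve.
    """

    tau_m_us: float = 100.0
    v_threshold: float = 1.0
    relative_spread: float = 0.30
    gain: float = 2.99e-3
    t_abs: float = 0.7e-3
    tau_rel: float = 1.32e-3
    latency_mean: float = 0.685e-3
    latency_sd: float = 0.10e-3
    jitter_sd: float = 0.12e-3
    discharge_time: float = 0.01e-3

    def __post_init__(self):
        if min(self.tau_m_us, self.v_threshold, self.gain, self.t_abs,
               self.tau_rel, self.latency_mean, self.discharge_time) <= 0:
            raise ValueError("fiber parameters must be positive")
        if not (0 <= self.relative_spread < 0.5):
            raise ValueError("relative_spread must be in [0, 0.5)")

    @property
    def noise_sd(self) -> float:
        return self.relative_spread * self.v_threshold


def membrane_first_phase(
    current: float, phase_duration_us: float, params: ElectricFiberParams
) -> float:
    """Membrane voltage at the end of the first pulse phase (deterministic)."""
    if np.any(np.asarray(current) < 0):
        raise ValueError("current must be non-negative")
    return current * params.gain * (1.0 - math.exp(-phase_duration_us / params.tau_m_us))


def _refractory_factor(dt_last: float | None, params: ElectricFiberParams) -> float:
    if dt_last is None:
        return 1.0
    if dt_last <= 0:
        raise ValueError("dt_last must be positive")
    if dt_last < params.t_abs:
        return math.inf
    arg = (dt_last - params.t_abs) / params.tau_rel
    if arg <= 0:
        return math.inf
    return 1.0 / (1.0 - math.exp(-arg))


def spike_decision(
    u: float,
    dt_last: float | None,
    params: ElectricFiberParams,
    noise_draw: float,
) -> bool:
    """Fire iff the noisy membrane voltage reaches the refractory-scaled threshold."""
    r = _refractory_factor(dt_last, params)
    if math.isinf(r):
        return False
    return u + noise_draw >= params.v_threshold * r


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_electric_fiber(
    train: ElectricPulseTrain,
    params: ElectricFiberParams = ElectricFiberParams(),
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Simulate one fiber's response to a biphasic pulse train.

    Each pulse is evaluated once with a fresh membrane-noise draw; a firing
    pulse emits a spike at ``pulse time + discharge_time + latency + jitter``
    (clipped to keep spike times increasing and inside the train duration).
    Reproducible given the seed.
    """
    rng = _as_rng(seed)
    n = len(train.pulse_times)
    u = train.amplitudes * params.gain * (
        1.0 - math.exp(-train.phase_duration_us / params.tau_m_us)
    )
    noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    latency = (
        rng.normal(params.latency_mean, params.latency_sd, n)
        if params.latency_sd > 0
        else np.full(n, params.latency_mean)
    )
    jitter = rng.normal(0.0, params.jitter_sd, n) if params.jitter_sd > 0 else np.zeros(n)
    v_thr = params.v_threshold
    t_abs = params.t_abs
    tau_rel = params.tau_rel
    times: list[float] = []
    t_last = -math.inf
    pulse_times = train.pulse_times
    for i in range(n):
        dt = pulse_times[i] - t_last
        if dt < t_abs:
            continue
        thr = v_thr / (1.0 - math.exp(-(dt - t_abs) / tau_rel)) if math.isfinite(t_last) else v_thr
        if u[i] + noise[i] >= thr:
            t_spike = pulse_times[i] + params.discharge_time + latency[i] + jitter[i]
            if times and t_spike <= times[-1]:
                t_spike = times[-1] + 1e-9
            if 0.0 <= t_spike <= train.duration:
                times.append(t_spike)
            t_last = t_spike
    return SpikeTrain(np.asarray(times), train.duration)


def simulate_electric_population(
    train: ElectricPulseTrain,
    n_fibers: int,
    params: ElectricFiberParams = ElectricFiberParams(),
    seed: int | np.random.SeedSequence = 0,
) -> SpikeEnsemble:
    """Independent identical fibers with per-fiber seeds split off the master seed."""
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_fibers)
    trains = []
    for fid, child in enumerate(children):
        tr = simulate_electric_fiber(train, params, np.random.default_rng(child))
        trains.append(SpikeTrain(tr.times, tr.duration, fiber_id=fid))
    return SpikeEnsemble(tuple(trains), train.duration)


def _ipsi_only_rate(
    current: float,
    standard: str,
    ei: EIParams,
    params: ElectricFiberParams,
    rep_seeds: list[np.random.SeedSequence],
) -> float:
    """Mean EI output rate (sp/s) with ipsilateral-only drive at a current."""
    if standard == "unmodulated":
        train = gen_electric_train(40.0, level=0.0, f_m=None, reference_current=current)
    elif standard == "sam":
        train = gen_electric_train(1000.0, level=0.0, f_m=40.0, reference_current=current)
    else:
        raise ValueError(f"unknown standard stimulus {standard!r}")
    empty = SpikeEnsemble((), train.duration)
    rates = []
    for ss in rep_seeds:
        exc = simulate_electric_population(train, ei.n_exc, params, ss)
        out = simulate_ei(exc, empty, ei)
        rates.append(len(out) / train.duration)
    return float(np.mean(rates))


def find_reference_threshold(
    standard: str = "unmodulated",
    ei: EIParams = EIParams(),
    params: ElectricFiberParams = ElectricFiberParams(),
    seed: int = 0,
    n_reps: int = 10,
    bracket: tuple[float, float] = (20.0, 2000.0),
    criterion_rate: float = 1.0,
) -> float:
    """Behavioural reference current (uA) for the dB-thr scale.

    Smallest current (bisection to 1-uA resolution, ``n_reps`` repetitions
    averaged) at which the EI neuron, driven only by its ``n_exc``
    ipsilateral fibers by the standard stimulus (40-pps unmodulated train,
    or the 40-Hz SAM 1000-pps train for the SAM reference), fires at least
    ``criterion_rate`` sp/s.  The same repetition seeds are reused at every
    probed current (common random numbers), which keeps the rate-current
    function monotone during the search.
    """
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    lo, hi = bracket
    if _ipsi_only_rate(lo, standard, ei, params, rep_seeds) >= criterion_rate:
        raise ValueError("lower bracket already above criterion")
    if _ipsi_only_rate(hi, standard, ei, params, rep_seeds) < criterion_rate:
        raise ValueError("upper bracket below criterion; search range does not bracket")
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if _ipsi_only_rate(mid, standard, ei, params, rep_seeds) >= criterion_rate:
            hi = mid
        else:
            lo = mid
    return float(round(hi))
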