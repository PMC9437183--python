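"""Simplified acoustically stimulated auditory-nerve model.

A stand-in for a full biophysical periphery, kept behind a narrow interface
(``AcousticStimulus`` in, ``SpikeEnsemble`` out) so a published periphery
model can be substituted.  The chain, per fiber population at one
characteristic frequency (CF = stimulus carrier unless overridden):

1. gammatone band-pass at CF (FIR, 4th order, ERB-scaled bandwidth);
2. inner-hair-cell / synapse stage: half-wave rectification followed by a
   first-order low-pass, which removes carrier fine structure while passing
   the envelope; its cutoff (400 Hz) also sets the decay of the drive after
   a transient and thereby the multi-millisecond duration of high-level
   click-evoked response bursts;
3. saturating rate nonlinearity: a logistic function of the drive in dB
   mapping to instantaneous rate in [spont_rate, rate_max]; rate_max is the
   *onset* (instantaneous) ceiling, of the order of the inverse dead time,
   not the sustained rate;
4. short-term adaptation: divisive feed-forward gain from a single
   exponential low-pass of the rate, which compresses sustained responses
   well below the onset ceiling;
5. inhomogeneous-Poisson spike generation with an absolute dead time.

The deterministic stages (1-4) are shared by all fibers of a population;
only the Poisson draws differ, which
:func:`simulate_acoustic_population` exploits by computing the rate profile
once.  Medium-spontaneous-rate fibers (0.5-18 sp/s) are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .spikes import SpikeEnsemble, SpikeTrain
from .stimuli import AcousticStimulus, P_REF

__all__ = [
    "AcousticFiberParams",
    "erb_bandwidth",
    "rate_profile",
    "simulate_acoustic_fiber",
    "simulate_acoustic_population",
]

#: sampling rate of the rate profile handed to the spike generator, Hz
RATE_FS = 20_000.0


def erb_bandwidth(cf: float) -> float:
    """Standard ERB scale: ``24.7 (4.37 cf / 1000 + 1)`` Hz."""
    return 24.7 * (4.37 * cf / 1000.0 + 1.0)


@dataclass(frozen=True)
class AcousticFiberParams:
    """Parameters of the simplified acoustic AN fiber.

    ``rate_level_mid`` is the drive level (dB re 20 uPa, measured after the
    IHC stage) of half-maximal rate, and ``rate_slope`` the logistic slope
    in dB^-1; together they place the dynamic range so that SAM tones drive
    the EI neuron hardest near 30 dB SPL.
    """

    cf: float = 8000.0
    spont_rate: float = 5.0
    filter_order: int = 4
    filter_bandwidth: float | None = None  # Hz; None -> ERB scale at cf
    ihc_cutoff: float = 400.0
    rate_max: float = 1000.0
    rate_level_mid: float = 19.5  # dB re 20 uPa drive at half-max rate
    rate_slope: float = 0.7      # dB^-1 logistic slope
    adaptation_tau: float = 0.060
    adaptation_strength: float = 3.0
    t_abs: float = 0.75e-3

    def __post_init__(self):
        if not (0.5 <= self.spont_rate <= 18.0):
            raise ValueError("spont_rate must lie in the MSR range 0.5-18 sp/s")

    @property
    def bandwidth(self) -> float:
        return self.filter_bandwidth if self.filter_bandwidth is not None else erb_bandwidth(self.cf)


def _gammatone_fir(params: AcousticFiberParams, fs: float) -> np.ndarray:
    """FIR gammatone impulse response, unit gain at cf."""
    b = 1.019 * params.bandwidth
    # envelope t^(n-1) exp(-2 pi b t): keep 12 envelope time constants
    dur = max(12.0 / (2 * math.pi * b), 2e-3)
    t = np.arange(1, int(dur * fs)) / fs
    h = t ** (params.filter_order - 1) * np.exp(-2 * math.pi * b * t) * np.cos(
        2 * math.pi * params.cf * t
    )
    gain = np.abs(np.sum(h * np.exp(-2j * math.pi * params.cf * t)))
    return h / gain


def rate_profile(
    stimulus: AcousticStimulus, params: AcousticFiberParams | None = None
) -> tuple[np.ndarray, float]:
    """Deterministic instantaneous firing rate (sp/s) driving the spike generator.

    Returns ``(rate, dt)`` with the rate sampled at :data:`RATE_FS`.
    """
    if params is None:
        params = AcousticFiberParams(cf=stimulus.f_c)
    fs = stimulus.sample_rate
    if fs <= 4 * params.cf:
        raise ValueError("stimulus sample rate too low for this CF")
    x = signal.fftconvolve(stimulus.samples, _gammatone_fir(params, fs), mode="same")
    # IHC: rectify + 1st-order low-pass
    x = np.maximum(x, 0.0)
    sos = signal.butter(1, params.ihc_cutoff, fs=fs, output="sos")
    x = signal.sosfilt(sos, x)
    # downsample: the drive is band-limited to ihc_cutoff
    step = max(1, int(round(fs / RATE_FS)))
    d = np.maximum(x[::step], 0.0)
    dt = step / fs
    # saturating rate nonlinearity on the dB drive
    with np.errstate(divide="ignore"):
        d_db = 20.0 * np.log10(np.maximum(d, 1e-12) / P_REF)
    act = 1.0 / (1.0 + np.exp(-params.rate_slope * (d_db - params.rate_level_mid)))
    r = params.spont_rate + (params.rate_max - params.spont_rate) * act
    # divisive feed-forward adaptation from an exponential low-pass of the rate
    if params.adaptation_strength > 0:
        alpha = dt / params.adaptation_tau
        lp = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], r)
        r = r / (1.0 + params.adaptation_strength * lp / params.rate_max)
    return np.maximum(r, 0.0), dt


def _draw_spikes(
    rate: np.ndarray, dt: float, t_abs: float, rng: np.random.Generator, duration: float
) -> np.ndarray:
    """Inhomogeneous-Poisson draw with absolute dead time."""
    p = np.clip(rate * dt, 0.0, 1.0)
    hits = np.nonzero(rng.random(len(p)) < p)[0]
    if hits.size == 0:
        return np.empty(0)
    # uniform placement within each bin, then dead-time pruning
    t_cand = (hits + rng.random(hits.size)) * dt
    out: list[float] = []
    t_last = -math.inf
    for t in t_cand:
        if t - t_last >= t_abs and t <= duration:
            out.append(t)
            t_last = t
    return np.asarray(out)


def simulate_acoustic_fiber(
    stimulus: AcousticStimulus,
    params: AcousticFiberParams | None = None,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """One fiber's spike train in response to an acoustic stimulus."""
    if params is None:
        params = AcousticFiberParams(cf=stimulus.f_c)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate, dt = rate_profile(stimulus, params)
    times = _draw_spikes(rate, dt, params.t_abs, rng, stimulus.duration)
    return SpikeTrain(times, stimulus.duration)


def simulate_acoustic_population(
    stimulus: AcousticStimulus,
    n_fibers: int,
    params: AcousticFiberParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    profile: tuple[np.ndarray, float] | None = None,
) -> SpikeEnsemble:
    """Independent identical fibers; the deterministic drive is computed once.

    ``profile`` may carry a precomputed :func:`rate_profile` result to avoid
    refiltering the same stimulus across repetitions.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if params is None:
        params = AcousticFiberParams(cf=stimulus.f_c)
    rate, dt = profile if profile is not None else rate_profile(stimulus, params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    trains = []
    for fid, child in enumerate(ss.spawn(n_fibers)):
        rng = np.random.default_rng(child)
        times = _draw_spikes(rate, dt, params.t_abs, rng, stimulus.duration)
        trains.append(SpikeTrain(times, stimulus.duration, fiber_id=fid))
    return SpikeEnsemble(tuple(trains), stimulus.duration)
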