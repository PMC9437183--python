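"""Synthesis of CI-simulating acoustic stimuli and electric pulse trains.

Four acoustic stimulus classes are provided, all high-frequency carriers with
pulsatile or sinusoidal envelopes designed to mimic cochlear-implant (CI)
stimulation in normal-hearing listeners:

* SAM tones     -- sinusoidally amplitude-modulated tones,
                   ``s(t) = a sin(2 pi f_c t) (1 - cos 2 pi f_m t)``
* transposed tones -- carrier modulated by a half-wave rectified, low-pass
                   filtered low-frequency tone
* GE tones      -- trains of Gaussian-envelope tone bursts whose equivalent
                   rectangular bandwidth matches a fixed cochlear extent on
                   the Greenwood frequency-position map
* filtered clicks -- band-pass filtered trains of 10-us rectangular clicks

Electric stimuli are constant-amplitude or SAM biphasic pulse trains
(100-us phase duration) specified in dB relative to a behavioural reference
current.  All acoustic stimuli are gated with sin^2 ramps and scaled to a
target steady-state RMS level in dB SPL (re 20 uPa).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "AcousticStimulus",
    "ElectricPulseTrain",
    "GreenwoodMap",
    "HUMAN_MAP",
    "P_REF",
    "ac_dc_ratio",
    "apply_gating_and_level",
    "gen_electric_train",
    "gen_filtered_clicks",
    "gen_ge_train",
    "gen_sam_tone",
    "gen_transposed_tone",
    "greenwood_erb",
]

logger = logging.getLogger(__name__)

#: reference sound pressure for dB SPL, Pa
P_REF = 20e-6

#: default acoustic sampling rate, Hz (doubled for clicks, see gen_filtered_clicks)
DEFAULT_FS = 100_000.0

#: cutoff of the low-pass applied to the rectified modulator of transposed
#: tones, Hz (4th-order Butterworth)
TRANSPOSED_LP_CUTOFF = 2000.0


@dataclass(frozen=True)
class AcousticStimulus:
    """A sampled pressure waveform with its synthesis metadata.

    Attributes
    ----------
    samples : ndarray
        Pressure waveform in Pa.
    sample_rate : float
        Sampling rate, Hz.
    kind : str
        One of ``{"sam", "transposed", "ge", "clicks"}``.
    f_c : float
        Carrier frequency, Hz.
    f_m : float
        Modulation frequency or pulse rate, s^-1.
    level : float
        Steady-state RMS level, dB SPL re 20 uPa.
    duration : float
        Nominal duration, s.
    ramp : float
        sin^2 gating ramp length, s (0 if not yet gated).
    """

    samples: np.ndarray
    sample_rate: float
    kind: str
    f_c: float
    f_m: float
    level: float
    duration: float
    ramp: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")
        n_expect = self.duration * self.sample_rate
        if abs(len(self.samples) - n_expect) > 1.0:
            raise ValueError(
                f"length {len(self.samples)} inconsistent with duration "
                f"{self.duration} s at {self.sample_rate} Hz"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


@dataclass(frozen=True)
class ElectricPulseTrain:
    """Timed biphasic pulses with per-pulse current amplitudes.

    ``pulse_times`` are the onsets of the first (cathodic) phase, in s;
    ``amplitudes`` are the corresponding phase currents in uA.  The fiber
    model is indifferent to polarity, so only ``cathodic_first`` exists.
    """

    pulse_times: np.ndarray
    amplitudes: np.ndarray
    phase_duration_us: float
    carrier_rate: float
    f_m: float | None
    level: float  # dB re reference threshold
    duration: float
    polarity: str = "cathodic_first"

    def __post_init__(self):
        t = np.asarray(self.pulse_times, float)
        a = np.asarray(self.amplitudes, float)
        if t.shape != a.shape:
            raise ValueError("pulse_times and amplitudes must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("pulse_times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class GreenwoodMap:
    """Exponential cochlear frequency-position function.

    ``frequency(x) = A (10**(a x) - k)`` with ``x`` the distance from the
    apex in mm.  Defaults are the standard human constants.
    """

    A: float = 165.4      # Hz
    a: float = 0.06       # 1/mm
    k: float = 1.0
    length: float = 35.0  # mm

    def frequency(self, x_mm) -> float:
        return self.A * (10.0 ** (self.a * np.asarray(x_mm, float)) - self.k)

    def position(self, f_hz) -> float:
        f = np.asarray(f_hz, float)
        return np.log10(f / self.A + self.k) / self.a


#: the standard human Greenwood map
HUMAN_MAP = GreenwoodMap()


# ---------------------------------------------------------------------------
# level / gating helpers
# ---------------------------------------------------------------------------

def _sin2_gate(n: int, n_ramp: int) -> np.ndarray:
    """Amplitude gate with sin^2 on/off ramps of n_ramp samples."""
    g = np.ones(n)
    if n_ramp > 0:
        ramp = np.sin(0.5 * np.pi * np.arange(n_ramp) / n_ramp) ** 2
        g[:n_ramp] = ramp
        g[-n_ramp:] = ramp[::-1]
    return g


def apply_gating_and_level(
    stimulus: AcousticStimulus, level: float, ramp: float = 0.010
) -> AcousticStimulus:
    """Gate a stimulus with sin^2 ramps and scale to a dB SPL target.

    The level is defined on the steady-state segment (between the ramps):
    after scaling, its RMS equals ``P_REF * 10**(level/20)``.

    Parameters
    ----------
    stimulus : AcousticStimulus
        Input waveform (typically raw, un-gated).
    level : float
        Target steady-state level, dB SPL.
    ramp : float
        Ramp duration, s.  Must satisfy ``2 * ramp < duration``.
    """
    if 2 * ramp >= stimulus.duration:
        raise ValueError(f"ramp {ramp} s too long for duration {stimulus.duration} s")
    fs = stimulus.sample_rate
    n_ramp = int(round(ramp * fs))
    x = stimulus.samples * _sin2_gate(len(stimulus.samples), n_ramp)
    steady = x[n_ramp:len(x) - n_ramp]
    rms = np.sqrt(np.mean(steady**2))
    if rms == 0:
        raise ValueError("cannot scale a silent stimulus")
    target = P_REF * 10.0 ** (level / 20.0)
    x = x * (target / rms)
    return replace(stimulus, samples=x, level=level, ramp=ramp)


# ---------------------------------------------------------------------------
# acoustic generators
# ---------------------------------------------------------------------------

def _check_carrier(f_c: float, f_m: float, sample_rate: float) -> None:
    if sample_rate <= 4 * f_c:
        raise ValueError(
            f"sample_rate {sample_rate} Hz too low for carrier {f_c} Hz "
            "(need > 4 f_c)"
        )
    if f_m >= f_c / 2:
        raise ValueError(f"f_m {f_m} Hz must be below f_c/2 = {f_c / 2} Hz")


def gen_sam_tone(
    f_c: float,
    f_m: float,
    duration: float = 1.0,
    sample_rate: float = DEFAULT_FS,
    level: float = 30.0,
    ramp: float = 0.010,
) -> AcousticStimulus:
    """Sinusoidally amplitude-modulated tone.

    The raw waveform is ``sin(2 pi f_c t) (1 - cos 2 pi f_m t)``; its
    spectrum holds exactly three components, the carrier and two sidebands at
    ``f_c +- f_m`` of half the carrier amplitude.
    """
    _check_carrier(f_c, f_m, sample_rate)
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    x = np.sin(2 * np.pi * f_c * t) * (1.0 - np.cos(2 * np.pi * f_m * t))
    stim = AcousticStimulus(x, sample_rate, "sam", f_c, f_m, level, duration)
    return apply_gating_and_level(stim, level, ramp)


def transposed_modulator(
    f_m: float, n: int, sample_rate: float, cutoff: float = TRANSPOSED_LP_CUTOFF
) -> np.ndarray:
    """Half-wave rectified ``sin(2 pi f_m t)`` low-passed and peak-normalised.

    The low-pass is a zero-phase 4th-order Butterworth so the modulator stays
    aligned with the underlying sine cycle.
    """
    if f_m >= cutoff:
        raise ValueError(f"f_m {f_m} Hz at or above low-pass cutoff {cutoff} Hz")
    t = np.arange(n) / sample_rate
    m = np.maximum(np.sin(2 * np.pi * f_m * t), 0.0)
    sos = signal.butter(4, cutoff, fs=sample_rate, output="sos")
    m = signal.sosfiltfilt(sos, m)
    return m / np.max(np.abs(m))


def gen_transposed_tone(
    f_c: float,
    f_m: float,
    duration: float = 1.0,
    sample_rate: float = DEFAULT_FS,
    level: float = 30.0,
    ramp: float = 0.010,
) -> AcousticStimulus:
    """Transposed tone: carrier modulated by a rectified, low-passed sine.

    Mimics the hair-cell-transduced waveform of a low-frequency tone in a
    high-frequency channel; its envelope is sharper than a SAM tone's.
    """
    _check_carrier(f_c, f_m, sample_rate)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    m = transposed_modulator(f_m, n, sample_rate)
    x = m * np.sin(2 * np.pi * f_c * t)
    stim = AcousticStimulus(x, sample_rate, "transposed", f_c, f_m, level, duration)
    return apply_gating_and_level(stim, level, ramp)


def greenwood_erb(f_c: float, span_mm: float = 1.5, cmap: GreenwoodMap = HUMAN_MAP) -> float:
    """Bandwidth (Hz) of a fixed cochlear extent centred on the place of f_c.

    Returns ``frequency(x + span/2) - frequency(x - span/2)`` where ``x`` is
    the Greenwood place of ``f_c``.  Strictly increasing in both arguments.
    """
    if not (0 < f_c < cmap.frequency(cmap.length)):
        raise ValueError(f"f_c {f_c} Hz outside the Greenwood map range")
    x = cmap.position(f_c)
    if x - span_mm / 2 < 0 or x + span_mm / 2 > cmap.length:
        raise ValueError("span extends beyond the cochlea for this f_c")
    return float(cmap.frequency(x + span_mm / 2) - cmap.frequency(x - span_mm / 2))


def gen_ge_train(
    f_c: float,
    rate: float,
    duration: float = 1.0,
    sample_rate: float = DEFAULT_FS,
    level: float = 30.0,
    band_mm: float = 1.5,
    ramp: float = 0.010,
    cmap: GreenwoodMap = HUMAN_MAP,
) -> AcousticStimulus:
    """Constant-amplitude train of Gaussian-envelope tone bursts.

    The Gaussian width is set so the equivalent rectangular bandwidth (ERB,
    amplitude-spectrum convention) of each burst equals the ``band_mm``
    cochlear span at ``f_c`` on the Greenwood map.  Under that convention a
    Gaussian satisfies ERB * ERD = 1, so the equivalent rectangular duration
    of the envelope is 1/ERB.  The carrier phase is locked to each pulse
    centre.
    """
    _check_carrier(f_c, rate, sample_rate)
    erb = greenwood_erb(f_c, band_mm, cmap)
    # amplitude-convention ERB of exp(-t^2 / (2 s^2)) is 1/(s sqrt(2 pi))
    sigma_t = 1.0 / (erb * math.sqrt(2 * math.pi))
    period = 1.0 / rate
    # 20 log10(envelope at the midpoint between pulses), computed from the
    # exponent to survive underflow at low rates
    midpoint_db = -20.0 * ((period / 2) ** 2) / (2 * sigma_t**2) / math.log(10)
    if midpoint_db > -40:
        logger.warning(
            "adjacent GE pulses overlap at %.1f dB (above -40 dB) at rate %g pps",
            midpoint_db, rate,
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.zeros(n)
    n_pulses = int(round(rate * duration))
    half_width = 5 * sigma_t
    for k in range(n_pulses):
        tc = (k + 0.5) * period
        i0 = max(0, int((tc - half_width) * sample_rate))
        i1 = min(n, int((tc + half_width) * sample_rate) + 1)
        tt = t[i0:i1] - tc
        x[i0:i1] += np.exp(-(tt**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * f_c * tt)
    stim = AcousticStimulus(x, sample_rate, "ge", f_c, rate, level, duration)
    return apply_gating_and_level(stim, level, ramp)


#: width of the unfiltered condensation click, s
CLICK_WIDTH = 10e-6


def constant_q_corners(f_c: float, q: float = 0.5) -> tuple[float, float]:
    """Band edges of a constant-Q band centred (geometrically) on f_c.

    Solves ``f_lo * f_hi = f_c**2`` and ``f_hi - f_lo = f_c / q``.
    """
    half = f_c / (2 * q)
    root = f_c * math.sqrt(1 + 1 / (4 * q**2))
    return root - half, root + half


def gen_filtered_clicks(
    f_c: float,
    rate: float,
    duration: float = 1.0,
    sample_rate: float = 2 * DEFAULT_FS,
    level: float = 30.0,
    q: float = 0.5,
    ramp: float = 0.010,
) -> AcousticStimulus:
    """Band-pass filtered train of 10-us rectangular condensation clicks.

    Clicks at ``rate`` pps are filtered with a 2nd-order constant-Q
    Butterworth band-pass (Q = 0.5) centred on ``f_c``.
    """
    if sample_rate < 200_000:
        raise ValueError("sample_rate must be >= 200 kHz so the 10-us click spans >= 2 samples")
    n = int(round(duration * sample_rate))
    x = np.zeros(n)
    n_click = max(2, int(round(CLICK_WIDTH * sample_rate)))
    n_pulses = int(round(rate * duration))
    for k in range(n_pulses):
        i0 = int(round(k / rate * sample_rate))
        x[i0:min(n, i0 + n_click)] = 1.0
    f_lo, f_hi = constant_q_corners(f_c, q)
    sos = signal.butter(2, [f_lo, f_hi], btype="bandpass", fs=sample_rate, output="sos")
    x = signal.sosfilt(sos, x)
    stim = AcousticStimulus(x, sample_rate, "clicks", f_c, rate, level, duration)
    return apply_gating_and_level(stim, level, ramp)


# ---------------------------------------------------------------------------
# electric generator
# ---------------------------------------------------------------------------

def sam_envelope(t: np.ndarray, f_m: float) -> np.ndarray:
    """Raised-cosine SAM envelope ``(1 - cos(2 pi f_m t)) / 2`` in [0, 1]."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * f_m * np.asarray(t, float)))


def gen_electric_train(
    carrier_rate: float,
    duration: float = 0.600,
    level: float = 0.0,
    f_m: float | None = None,
    reference_current: float = 240.0,
    phase_duration_us: float = 100.0,
    ramp: float = 0.010,
) -> ElectricPulseTrain:
    """Biphasic pulse train, unmodulated or sinusoidally amplitude-modulated.

    Parameters
    ----------
    carrier_rate : float
        Pulse rate, pps.
    duration : float
        Train duration, s (600 ms default).
    level : float
        Current level in dB re ``reference_current``.
    f_m : float or None
        SAM modulation frequency; ``None`` for a constant-amplitude train.
        Must not exceed 40 % of the carrier rate.
    reference_current : float
        The behavioural reference threshold current, uA.
    ramp : float
        sin^2 gating ramp, s, applied to the pulse amplitudes.
    """
    if f_m is not None and f_m > 0.4 * carrier_rate:
        raise ValueError(
            f"f_m {f_m} Hz exceeds 40% of the carrier rate {carrier_rate} pps"
        )
    times = np.arange(0.0, duration - 1e-12, 1.0 / carrier_rate)
    amp0 = reference_current * 10.0 ** (level / 20.0)
    amps = np.full(len(times), amp0)
    if f_m is not None:
        amps = amps * sam_envelope(times, f_m)
    # sin^2 gating sampled at the pulse times (pulse shape itself unchanged)
    gate = np.ones(len(times))
    rising = times < ramp
    gate[rising] = np.sin(0.5 * np.pi * times[rising] / ramp) ** 2
    falling = times > duration - ramp
    gate[falling] = np.sin(0.5 * np.pi * (duration - times[falling]) / ramp) ** 2
    amps = amps * gate
    return ElectricPulseTrain(
        pulse_times=times,
        amplitudes=amps,
        phase_duration_us=phase_duration_us,
        carrier_rate=carrier_rate,
        f_m=f_m,
        level=level,
        duration=duration,
    )


# ---------------------------------------------------------------------------
# envelope sharpness metric
# ---------------------------------------------------------------------------

def ac_dc_ratio(stimulus: AcousticStimulus) -> float:
    """AC/DC ratio of the half-wave rectified waveform.

    ``sqrt(sum_{f != 0} A(f)**2) / A(0)`` over the full (two-sided) FFT
    amplitude spectrum of the rectified signal; a predictor of how strongly
    the auditory nerve will phase lock to the stimulus envelope.
    """
    x = np.maximum(stimulus.samples, 0.0)
    if np.all(x == 0):
        raise ValueError("degenerate input: rectified waveform is identically zero")
    amp = np.abs(np.fft.fft(x)) / len(x)
    dc = amp[0]
    if dc == 0:
        raise ValueError("degenerate input: zero DC component")
    ac = math.sqrt(float(np.sum(amp[1:] ** 2)))
    return ac / dc
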