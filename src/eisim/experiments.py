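"""Experiment protocols: binaural tuning-curve runs, sweeps, and fixtures.

The central entry point is :func:`rate_curve`, which synthesises (or takes) a
stimulus, drives the ipsilateral (excitatory, 20 fibers) and contralateral
(inhibitory, 8 fibers) periphery populations, imposes the interaural time
difference on the contralateral spike trains, runs the EI neuron, and
collects firing rates over an ITD or IPD grid.  :func:`run_experiment`
wraps this in a configuration-driven sweep over levels, rates and inhibitory
window lengths, writing CSV tables plus a provenance JSON.

Conventions: positive ITD/IPD is contralateral-leading.  Acoustic runs use a
1-s stimulus and discard the first 200 ms; electric runs use a 600-ms train
analysed from the end of the 10-ms onset ramp.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .acoustic_periphery import (
    AcousticFiberParams,
    rate_profile,
    simulate_acoustic_population,
)
from .analysis import TuningCurve, firing_rate, sqrt_contrast
from .ei import EIParams, apply_itd, simulate_ei
from .electric_periphery import (
    ElectricFiberParams,
    find_reference_threshold,
    simulate_electric_population,
)
from .spikes import SpikeEnsemble, SpikeTrain
from .stimuli import (
    gen_electric_train,
    gen_filtered_clicks,
    gen_ge_train,
    gen_sam_tone,
    gen_transposed_tone,
)

__all__ = [
    "ACOUSTIC_WINDOW",
    "ELECTRIC_WINDOW",
    "ExperimentSpec",
    "ipd_to_itd",
    "make_acoustic_stimulus",
    "make_fixture_spikes",
    "operational_cutoff",
    "rate_curve",
    "run_experiment",
    "second_plateau_offset",
    "trough_span",
]

#: analysis window for 1-s acoustic runs (first 200 ms discarded), s
ACOUSTIC_WINDOW = (0.200, 1.0)
#: analysis window for 600-ms electric runs (onset ramp excluded), s
ELECTRIC_WINDOW = (0.010, 0.600)

_ACOUSTIC_GENERATORS = {
    "sam": gen_sam_tone,
    "transposed": gen_transposed_tone,
    "ge": gen_ge_train,
    "clicks": gen_filtered_clicks,
}


def make_acoustic_stimulus(kind: str, f_c: float, f_m: float, level: float, **kw):
    """Dispatch to the acoustic generator for ``kind``."""
    try:
        gen = _ACOUSTIC_GENERATORS[kind]
    except KeyError:
        raise ValueError(f"unknown acoustic stimulus kind {kind!r}") from None
    return gen(f_c, f_m, level=level, **kw)


def ipd_to_itd(ipd_rad: float, f_m: float) -> float:
    """Interaural phase (rad, at the modulation/pulse rate) to time (s)."""
    return ipd_rad / (2.0 * np.pi * f_m)


def rate_curve(
    pathway: str,
    axis: str,
    grid: np.ndarray,
    *,
    f_m: float,
    kind: str | None = None,
    f_c: float = 8000.0,
    carrier_rate: float | None = None,
    level: float = 30.0,
    reference_current: float = 240.0,
    ei: EIParams = EIParams(),
    fiber_params=None,
    n_reps: int = 10,
    seed: int = 0,
) -> TuningCurve:
    """Simulate a rate-ITD or rate-IPD tuning curve of the EI neuron.

    Parameters
    ----------
    pathway : {"acoustic", "electric"}
    axis : {"itd", "ipd"}
        ``grid`` is in ms for "itd" and rad for "ipd".
    f_m : float
        Modulation frequency or pulse rate, s^-1 (also the IPD reference).
    kind : str
        Acoustic stimulus class (ignored for electric).
    carrier_rate : float
        Electric carrier rate, pps; if it equals ``f_m`` the train is
        unmodulated.
    level : float
        dB SPL (acoustic) or dB thr (electric).
    reference_current : float
        Electric dB-thr reference current, uA.

    Periphery noise is redrawn per repetition; each repetition's spike
    ensembles are reused across the whole grid (the ITD is imposed on the
    contralateral spike trains).
    """
    grid = np.asarray(grid, float)
    if axis == "itd":
        itds = grid * 1e-3
    elif axis == "ipd":
        itds = np.array([ipd_to_itd(v, f_m) for v in grid])
    else:
        raise ValueError("axis must be 'itd' or 'ipd'")

    if pathway == "acoustic":
        stim = make_acoustic_stimulus(kind, f_c, f_m, level)
        fp = fiber_params or AcousticFiberParams(cf=f_c)
        profile = rate_profile(stim, fp)
        window = ACOUSTIC_WINDOW
        duration = stim.duration

        def populations(ss_ipsi, ss_contra):
            return (
                simulate_acoustic_population(stim, ei.n_exc, fp, ss_ipsi, profile),
                simulate_acoustic_population(stim, ei.n_inh, fp, ss_contra, profile),
            )

    elif pathway == "electric":
        if carrier_rate is None:
            carrier_rate = f_m
        mod = None if carrier_rate == f_m else f_m
        train = gen_electric_train(
            carrier_rate, level=level, f_m=mod, reference_current=reference_current
        )
        fp = fiber_params or ElectricFiberParams()
        window = ELECTRIC_WINDOW
        duration = train.duration

        def populations(ss_ipsi, ss_contra):
            return (
                simulate_electric_population(train, ei.n_exc, fp, ss_ipsi),
                simulate_electric_population(train, ei.n_inh, fp, ss_contra),
            )

    else:
        raise ValueError("pathway must be 'acoustic' or 'electric'")

    seeds = np.random.SeedSequence(seed).spawn(2 * n_reps)
    rates = np.zeros((grid.size, n_reps))
    for j in range(n_reps):
        exc, inh = populations(seeds[2 * j], seeds[2 * j + 1])
        for i, itd in enumerate(itds):
            out = simulate_ei(exc, apply_itd(inh, itd), ei)
            rates[i, j] = firing_rate(out, window)
    kind_axis = "itd_ms" if axis == "itd" else "ipd_rad"
    return TuningCurve(kind_axis, grid, rates)


# ---------------------------------------------------------------------------
# curve metrics used by the sweep protocols
# ---------------------------------------------------------------------------

def trough_span(curve: TuningCurve, frac: float = 0.2) -> float:
    """Contiguous axis span around the worst point where rate < frac * max.

    Returns the span in the curve's axis units (ms for ITD curves).
    """
    m = curve.mean_rate
    lo = frac * m.max()
    i_min = int(np.argmin(m))
    if m[i_min] >= lo:
        return 0.0
    i0 = i_min
    while i0 > 0 and m[i0 - 1] < lo:
        i0 -= 1
    i1 = i_min
    while i1 < m.size - 1 and m[i1 + 1] < lo:
        i1 += 1
    return float(curve.grid[i1] - curve.grid[i0])


def second_plateau_offset(curve: TuningCurve, f_m: float, tol_frac: float = 0.05) -> float:
    """Worst ITD minus the nearest ITD whose rate reaches twice ``f_m``.

    At high levels a second response per modulation cycle appears once the
    excitation precedes the inhibition by more than the refractory period,
    producing a plateau at twice the modulation frequency; this returns the
    distance (in axis units) between the trough and the onset of that
    plateau.  Because the per-cycle double-spike probability saturates just
    below 1 and repetitions are stochastic, the plateau is considered
    attained at ``(1 - tol_frac)`` of its nominal ``2 f_m`` level.
    """
    m = curve.mean_rate
    i_min = int(np.argmin(m))
    at_double = np.nonzero(m >= 2.0 * f_m * (1.0 - tol_frac))[0]
    if at_double.size == 0:
        raise ValueError("no point of the curve reaches twice the modulation frequency")
    i_on = at_double[np.argmin(np.abs(curve.grid[at_double] - curve.grid[i_min]))]
    return float(curve.grid[i_min] - curve.grid[i_on])


def operational_cutoff(rates: np.ndarray, contrasts: np.ndarray, frac: float = 0.5) -> float:
    """Rate at which ITD sensitivity collapses: the first tested rate above
    the contrast peak whose contrast falls below ``frac`` of the maximum
    contrast over the rate list.  (Contrast also declines toward very low
    rates at low stimulation levels; that branch is not the limit.)

    The collapse rate tracks the inverse inhibitory window length.  (The
    highest surviving rate is deliberately not used: with rectangular
    coincidence windows the contrast can partially revive above the limit,
    when the window edge re-samples the pulse grid, without restoring
    ordinary ITD tuning.)  Returns the highest tested rate if the contrast
    never collapses.
    """
    rates = np.asarray(rates, float)
    contrasts = np.asarray(contrasts, float)
    i_peak = int(np.argmax(contrasts))
    below = np.nonzero(contrasts[i_peak:] < frac * contrasts.max())[0]
    if below.size == 0:
        return float(rates.max())
    return float(rates[i_peak + below[0]])


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------

def make_fixture_spikes(name: str, **params) -> tuple[SpikeEnsemble, SpikeEnsemble]:
    """Deterministic (or seeded) excitatory/inhibitory ensemble pairs.

    * ``full_volley`` -- 20 excitatory spikes spread inside one excitatory
      window and 8 inhibitory spikes inside the inhibitory window, the
      textbook 20 - 2*8 = +4 coincidence case; exactly one output spike.
    * ``double_volley`` -- two coincident 20-spike excitatory volleys
      ``dt`` apart (no inhibition); probes the refractory period.
    * ``poisson_pair`` -- seeded homogeneous-Poisson ensembles on a 1-us
      grid, for cross-checking the event-driven EI against the grid oracle.
    """
    duration = params.pop("duration", 0.05)
    if name == "full_volley":
        t0 = params.pop("t0", 5e-3)
        exc_t = t0 + 0.04e-3 * np.arange(20)          # span 0.76 ms < w_exc
        inh_t = t0 - 1e-3 + 0.2e-3 * np.arange(8)     # span 1.4 ms < w_inh
        exc = _ensemble_from_times(exc_t, duration)
        inh = _ensemble_from_times(inh_t, duration)
    elif name == "double_volley":
        dt = params.pop("dt", 1.0e-3)
        t0 = params.pop("t0", 5e-3)
        exc = _ensemble_from_times(np.concatenate([
            np.full(20, t0), np.full(20, t0 + dt)
        ]), duration, n_fibers=20, per_fiber=True)
        inh = SpikeEnsemble((), duration)
    elif name == "poisson_pair":
        seed = params.pop("seed", 0)
        rate = params.pop("rate", 100.0)
        rng = np.random.default_rng(seed)
        exc = _poisson_ensemble(rng, 20, rate, duration)
        inh = _poisson_ensemble(rng, 8, rate, duration)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return exc, inh


def _ensemble_from_times(times, duration, n_fibers=None, per_fiber=False):
    times = np.asarray(times, float)
    if per_fiber and n_fibers:
        trains = []
        for f in range(n_fibers):
            t = np.unique(times[f::n_fibers])
            trains.append(SpikeTrain(t, duration, fiber_id=f))
        return SpikeEnsemble(tuple(trains), duration)
    trains = tuple(
        SpikeTrain(np.array([t]), duration, fiber_id=i) for i, t in enumerate(times)
    )
    return SpikeEnsemble(trains, duration)


def _poisson_ensemble(rng, n_fibers, rate, duration):
    trains = []
    for f in range(n_fibers):
        n = rng.poisson(rate * duration)
        t = np.sort(rng.uniform(0, duration, n))
        t = np.unique(np.round(t, 6))  # snap to the 1-us oracle grid
        trains.append(SpikeTrain(t, duration, fiber_id=f))
    return SpikeEnsemble(tuple(trains), duration)


# ---------------------------------------------------------------------------
# configuration-driven sweep
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSpec:
    """A sweep over rates/levels/inhibitory windows for one stimulus class.

    ``rates`` are pulse rates or modulation frequencies, s^-1; acoustic
    levels are dB SPL in [0, 70], electric levels dB thr in [0, 14].
    """

    pathway: str = "electric"
    kind: str | None = None          # acoustic stimulus class
    f_c: float = 8000.0
    carrier_rate: float | None = None  # electric; None -> unmodulated at `rate`
    rates: tuple = (25, 50, 100, 200, 250, 320, 400, 500, 800)
    levels: tuple = (5.0,)
    axis: str = "ipd"
    grid_step: float = 0.05          # in pi units for ipd, ms for itd
    n_reps: int = 20
    w_inh_list: tuple = (3.1e-3,)
    ei: EIParams = field(default_factory=EIParams)
    reference_current: float = 240.0
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.pathway not in ("acoustic", "electric"):
            raise ValueError(f"pathway: unknown value {self.pathway!r}")
        if self.pathway == "acoustic" and self.kind not in _ACOUSTIC_GENERATORS:
            raise ValueError(f"kind: unknown acoustic stimulus {self.kind!r}")
        if self.axis not in ("itd", "ipd"):
            raise ValueError(f"axis: must be 'itd' or 'ipd', got {self.axis!r}")
        if not self.rates:
            raise ValueError("rates: list must be non-empty")
        if not self.levels:
            raise ValueError("levels: list must be non-empty")
        lo, hi = (0.0, 70.0) if self.pathway == "acoustic" else (0.0, 14.0)
        for lv in self.levels:
            if not (lo <= lv <= hi):
                raise ValueError(f"levels: {lv} outside [{lo}, {hi}]")

    def grid(self) -> np.ndarray:
        if self.axis == "ipd":
            n = int(round(2 / self.grid_step))
            return np.linspace(-np.pi, np.pi, n + 1)
        n = int(round(8.0 / self.grid_step))
        return np.linspace(-4.0, 4.0, n + 1)


def run_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Run the full sweep; returns and writes the metrics summary table.

    Writes, under ``spec.out_dir``: one tuning-curve CSV per condition
    (columns axis_value, rep, rate_sps), ``metrics.csv`` with one row per
    condition, and ``provenance.json`` recording the spec and seeds.
    """
    spec.validate()
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = spec.grid()
    records = []
    for w_inh in spec.w_inh_list:
        ei = replace(spec.ei, w_inh=w_inh)
        for level in spec.levels:
            for rate in spec.rates:
                cond_seed = _condition_seed(spec.seed, w_inh, level, rate)
                curve = rate_curve(
                    spec.pathway,
                    spec.axis,
                    grid if spec.axis == "itd" else grid,
                    f_m=float(rate),
                    kind=spec.kind,
                    f_c=spec.f_c,
                    carrier_rate=spec.carrier_rate,
                    level=float(level),
                    reference_current=spec.reference_current,
                    ei=ei,
                    n_reps=spec.n_reps,
                    seed=cond_seed,
                )
                tag = f"{spec.pathway}_{spec.kind or 'pulses'}_w{w_inh * 1e3:.1f}_L{level:g}_r{rate:g}"
                _write_curve(curve, out / f"curve_{tag}.csv")
                records.append(
                    {
                        "pathway": spec.pathway,
                        "kind": spec.kind or "pulses",
                        "w_inh_ms": w_inh * 1e3,
                        "level": level,
                        "rate": rate,
                        "r_max": curve.mean_rate.max(),
                        "r_min": curve.mean_rate.min(),
                        "sqrt_contrast": sqrt_contrast(curve),
                        "seed": cond_seed,
                    }
                )
    metrics = pd.DataFrame.from_records(records)
    metrics.to_csv(out / "metrics.csv", index=False)
    prov = asdict(spec)
    prov["ei"] = asdict(spec.ei)
    prov["version"] = _pkg_version
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return metrics


def _condition_seed(master: int, w_inh: float, level: float, rate: float) -> int:
    """Deterministic per-condition seed derived from the master seed."""
    key = f"{w_inh:.6g}|{level:.6g}|{rate:.6g}".encode()
    return int((master * 2654435761 + zlib.crc32(key)) % 2**31)


def _write_curve(curve: TuningCurve, path: Path) -> None:
    rows = [
        {"axis_value": v, "rep": j, "rate_sps": curve.rep_rates[i, j]}
        for i, v in enumerate(curve.grid)
        for j in range(curve.n_reps)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
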