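"""Plain-text export: stimuli, spike trains and tuning curves as CSV + JSON."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import TuningCurve
from .spikes import SpikeEnsemble
from .stimuli import AcousticStimulus, ElectricPulseTrain

__all__ = [
    "export_stimulus",
    "export_spikes",
    "export_tuning_curve",
    "load_spikes",
]


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def export_stimulus(stim: AcousticStimulus | ElectricPulseTrain, path: str | Path) -> None:
    """Write a stimulus as two-column CSV with a JSON metadata sidecar.

    Acoustic: (time_s, value_pa); electric: (pulse_time_s, amplitude_uA).
    """
    path = Path(path)
    if isinstance(stim, AcousticStimulus):
        df = pd.DataFrame({"time_s": stim.times, "value_pa": stim.samples})
        meta = {k: v for k, v in asdict(stim).items() if k != "samples"}
    else:
        df = pd.DataFrame(
            {"pulse_time_s": stim.pulse_times, "amplitude_uA": stim.amplitudes}
        )
        meta = {
            k: v
            for k, v in asdict(stim).items()
            if k not in ("pulse_times", "amplitudes")
        }
    df.to_csv(path, index=False)
    _sidecar(path, meta)


def export_spikes(ensemble: SpikeEnsemble, path: str | Path, meta: dict | None = None) -> None:
    """Write an ensemble as (fiber_id, spike_time_s) CSV plus a JSON sidecar."""
    path = Path(path)
    rows = [
        {"fiber_id": tr.fiber_id, "spike_time_s": t}
        for tr in ensemble.trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["fiber_id", "spike_time_s"]).to_csv(path, index=False)
    _sidecar(path, {"duration": ensemble.duration, "n_fibers": ensemble.n_fibers, **(meta or {})})


def load_spikes(path: str | Path) -> SpikeEnsemble:
    """Read an ensemble written by :func:`export_spikes`."""
    from .spikes import SpikeTrain

    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    duration = float(meta["duration"])
    trains = []
    for fid in range(int(meta["n_fibers"])):
        t = np.sort(df.loc[df.fiber_id == fid, "spike_time_s"].to_numpy())
        trains.append(SpikeTrain(t, duration, fiber_id=fid))
    return SpikeEnsemble(tuple(trains), duration)


def export_tuning_curve(curve: TuningCurve, path: str | Path) -> None:
    """Per-repetition CSV (axis_value, rep, rate_sps) plus a mean-curve summary."""
    path = Path(path)
    rows = [
        {"axis_value": v, "rep": j, "rate_sps": curve.rep_rates[i, j]}
        for i, v in enumerate(curve.grid)
        for j in range(curve.n_reps)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    summary = pd.DataFrame({"axis_value": curve.grid, "mean_rate": curve.mean_rate})
    summary.to_csv(path.with_name(path.stem + "_mean.csv"), index=False)
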