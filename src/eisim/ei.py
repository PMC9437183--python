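"""Deterministic coincidence-counting excitatory-inhibitory (EI) neuron.

An LSO-type binaural neuron: it pools excitatory spikes from the ipsilateral
auditory nerve and inhibitory spikes from the contralateral side.  At every
pooled excitatory spike time ``t`` it forms the signed count

    (# excitatory spikes in (t - w_exc, t])
        - inh_gain * (# inhibitory spikes in (t - w_inh, t])

and emits an output spike when the count reaches ``threshold``, subject to an
absolute refractory period.  The windows are causal (trailing) and the
boundary is half-open, so a spike counts toward its own evaluation.  Because
the inhibitory window is longer than the excitatory one, the worst
(minimum-rate) interaural time difference is not at 0 but where the
excitation sits centred inside the inhibition.

The neuron itself is fully deterministic; all stochasticity lives in the
periphery models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spikes import SpikeEnsemble, SpikeTrain

__all__ = ["EIParams", "apply_itd", "ei_count", "simulate_ei", "ei_oracle"]

# guard for float roundoff at window edges / refractory equality: a spike
# exactly at t - W is excluded, an interval of exactly t_ref fires
_EPS = 1e-12


@dataclass(frozen=True)
class EIParams:
    """Parameters of the coincidence-counting EI neuron.

    Defaults: 1.1-ms excitatory and 3.1-ms inhibitory rectangular windows,
    response threshold 3, inhibitory gain 2, 1.6-ms refractory period,
    20 excitatory and 8 inhibitory input fibers.
    """

    w_exc: float = 1.1e-3
    w_inh: float = 3.1e-3
    threshold: int = 3
    inh_gain: float = 2.0
    t_ref: float = 1.6e-3
    n_exc: int = 20
    n_inh: int = 8

    def __post_init__(self):
        if not (self.w_inh >= self.w_exc > 0):
            raise ValueError("need w_inh >= w_exc > 0")
        if self.threshold < 1 or self.inh_gain < 0 or self.t_ref <= 0:
            raise ValueError("invalid EI parameters")


def apply_itd(ensemble: SpikeEnsemble, itd: float) -> SpikeEnsemble:
    """Impose an interaural time difference on the contralateral ensemble.

    Positive ITD means contralateral-leading: all spike times are shifted
    *earlier* by ``itd`` (spikes shifted before 0 are dropped).  Negative ITD
    shifts later; spikes pushed beyond the duration are dropped.  Applying
    the ITD on the spike trains rather than the stimulus is equivalent for a
    time-invariant periphery and far cheaper.

    The shift must stay small against the stimulus duration; +-20 ms covers
    both the +-4 ms ITD grids and a full IPD cycle down to a 25 s^-1 rate.
    """
    if abs(itd) > 20.001e-3:
        raise ValueError("|ITD| must be <= 20 ms")
    if itd == 0:
        return ensemble
    new = []
    for tr in ensemble.trains:
        t = tr.times - itd
        t = t[(t >= 0) & (t <= ensemble.duration)]
        new.append(replace(tr, times=t))
    return SpikeEnsemble(tuple(new), ensemble.duration)


def ei_count(
    t: float,
    exc_spikes: np.ndarray,
    inh_spikes: np.ndarray,
    params: EIParams,
) -> float:
    """Signed coincidence count at time ``t`` (windows are (t - W, t])."""
    exc = np.asarray(exc_spikes, float)
    inh = np.asarray(inh_spikes, float)
    n_e = np.searchsorted(exc, t + _EPS, side="right") - np.searchsorted(
        exc, t - params.w_exc + _EPS, side="right"
    )
    n_i = np.searchsorted(inh, t + _EPS, side="right") - np.searchsorted(
        inh, t - params.w_inh + _EPS, side="right"
    )
    return float(n_e - params.inh_gain * n_i)


def simulate_ei(
    exc: SpikeEnsemble, inh: SpikeEnsemble, params: EIParams = EIParams()
) -> SpikeTrain:
    """Run the EI neuron on excitatory and inhibitory input ensembles.

    The count is evaluated at each pooled excitatory spike time in ascending
    order (simultaneous spikes are one evaluation); an output spike is
    emitted when the count reaches threshold and the neuron is out of its
    refractory period.  Deterministic given its inputs.
    """
    if abs(exc.duration - inh.duration) > 1e-12:
        raise ValueError("excitatory and inhibitory ensembles must share a duration")
    exc_t = exc.pooled()
    inh_t = inh.pooled()
    if exc_t.size == 0:
        return SpikeTrain(np.empty(0), exc.duration)
    eval_t = np.unique(exc_t)
    n_e = (
        np.searchsorted(exc_t, eval_t + _EPS, side="right")
        - np.searchsorted(exc_t, eval_t - params.w_exc + _EPS, side="right")
    )
    n_i = (
        np.searchsorted(inh_t, eval_t + _EPS, side="right")
        - np.searchsorted(inh_t, eval_t - params.w_inh + _EPS, side="right")
    )
    counts = n_e - params.inh_gain * n_i
    supra = counts >= params.threshold
    out: list[float] = []
    t_last = -np.inf
    t_ref = params.t_ref - _EPS
    for t, ok in zip(eval_t, supra):
        if ok and t - t_last >= t_ref:
            out.append(t)
            t_last = t
    return SpikeTrain(np.asarray(out), exc.duration)


def ei_oracle(
    exc: SpikeEnsemble,
    inh: SpikeEnsemble,
    params: EIParams = EIParams(),
    grid_dt: float = 1e-6,
) -> SpikeTrain:
    """Brute-force reference: the same EI rule on a dense 1-us time grid.

    Test-only; rejects instances above 1000 total spikes.  Output spikes are
    reported at excitatory spike times (grid times between input spikes
    cannot create new threshold crossings because counts only change at
    spike times, and only excitatory arrivals can raise the count).
    """
    if exc.n_spikes() + inh.n_spikes() > 1000:
        raise ValueError("oracle instance too large (> 1000 spikes)")
    if abs(exc.duration - inh.duration) > 1e-12:
        raise ValueError("duration mismatch")
    exc_t = exc.pooled()
    inh_t = inh.pooled()
    out: list[float] = []
    t_last_i = -(10**12)
    # snap spike times onto the grid for exact window comparisons; the count
    # is piecewise constant between grid points holding spikes and only an
    # excitatory arrival can raise it, so scanning the grid reduces to
    # scanning the grid points that contain excitatory spikes
    exc_idx = np.round(exc_t / grid_dt).astype(np.int64)
    inh_idx = np.round(inh_t / grid_dt).astype(np.int64)
    w_exc = int(round(params.w_exc / grid_dt))
    w_inh = int(round(params.w_inh / grid_dt))
    t_ref = int(round(params.t_ref / grid_dt))
    for i in np.unique(exc_idx):
        n_e = int(np.sum((exc_idx > i - w_exc) & (exc_idx <= i)))
        n_i = int(np.sum((inh_idx > i - w_inh) & (inh_idx <= i)))
        count = n_e - params.inh_gain * n_i
        if count >= params.threshold and i - t_last_i >= t_ref:
            out.append(i * grid_dt)
            t_last_i = i
    return SpikeTrain(np.asarray(out), exc.duration)
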