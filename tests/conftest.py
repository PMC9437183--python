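import numpy as np
import pytest

from eisim import EIParams, SpikeEnsemble, SpikeTrain


@pytest.fixture
def ei_defaults() -> EIParams:
    return EIParams()


def ensemble_of(times_per_fiber, duration):
    """Build a SpikeEnsemble from a list of per-fiber time arrays."""
    trains = tuple(
        SpikeTrain(np.asarray(t, float), duration, fiber_id=i)
        for i, t in enumerate(times_per_fiber)
    )
    return SpikeEnsemble(trains, duration)


def volley(n_fibers, t, duration, spread=0.0):
    """n_fibers single-spike trains at time t (optionally evenly spread)."""
    offs = np.linspace(0, spread, n_fibers) if spread else np.zeros(n_fibers)
    return ensemble_of([[t + o] for o in offs], duration)


@pytest.fixture
def empty_ensemble():
    def make(duration=0.05):
        return SpikeEnsemble((), duration)

    return make
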