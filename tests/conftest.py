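import numpy as np
import pytest

from caedbs.params import PlantParams, initial_state
from caedbs.model_core import PlantState


@pytest.fixture(scope="session")
def normal_params():
    return PlantParams.preset("normal")


@pytest.fixture(scope="session")
def cae_params():
    return PlantParams.preset("cae")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_plant_states(params, rng, n):
    """Physiologically-shaped random states: V in [-90, 60], gates in [0,1]."""
    states = []
    for _ in range(n):
        y = initial_state(rng.uniform(-90, 60, 3), params)
        y[3:19] = rng.uniform(0, 1, 16)
        y[19:26] = rng.uniform(0, 1, 7)
        states.append(PlantState(y=y, t=0.0))
    return states
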