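import numpy as np
import pytest

from energytoggle import (
    RegulatoryParams,
    find_steady_states,
    sweep_energy,
)


@pytest.fixture(scope="session")
def defaults():
    return RegulatoryParams.defaults()


@pytest.fixture(scope="session")
def tristable(defaults):
    """The canonical tristable attractor set (defaults, A*=1)."""
    return find_steady_states(defaults, 1.0)


@pytest.fixture(scope="session")
def defaults_sweep(defaults):
    """Full-resolution energy sweep of the default circuit (step 5e-3)."""
    return sweep_energy(defaults, step=5e-3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)
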