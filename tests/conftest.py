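import numpy as np
import pytest

from gendpde.eos import TaitParams, tait_params_from_model
from gendpde.local_density import KernelConfig
from gendpde.units import ARGON, WATER, reduce_reference_state


@pytest.fixture(scope="session")
def argon_model():
    return reduce_reference_state(ARGON)


@pytest.fixture(scope="session")
def water_model():
    return reduce_reference_state(WATER)


@pytest.fixture(scope="session")
def argon_tait(argon_model):
    return tait_params_from_model(argon_model)


@pytest.fixture(scope="session")
def water_tait(water_model):
    return tait_params_from_model(water_model)


@pytest.fixture
def kernel3d():
    return KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture
def random_liquid_config(rng):
    """Small random configuration at roughly unit density in a periodic box."""
    N, box = 60, 6.0  # density ~0.28; enough neighbors within R_cut ~ 2
    positions = rng.uniform(0.0, box, size=(N, 3))
    return positions, box
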