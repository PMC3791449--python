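import numpy as np
import pytest

from dimerpull.core_model import BellParams, PhysicalConstants
from dimerpull.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def constants_298():
    """Constants pinned to kBT = 4.114 pN nm, for hand-derived expectations."""
    return PhysicalConstants(temperature=298.0, thermal_energy=4.114)


@pytest.fixture(scope="session")
def default_constants():
    return PhysicalConstants()


@pytest.fixture(scope="session")
def reference_bell():
    """Bell parameters in the mid-range of the dimer-dissociation regime."""
    return BellParams(k_off=5.56, x_beta=0.30)


@pytest.fixture()
def quiet_sim_config():
    """Noiseless single-anchor simulation for deterministic round trips."""
    return SimulationConfig(
        force_noise_sd=0.0, length_noise_sd=0.0,
        anchor_mixture=((20, 1.0),), seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
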