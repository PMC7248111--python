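import numpy as np
import pytest

import bloodpool as bp


@pytest.fixture(scope="session")
def fluid():
    return bp.FluidProperties()


@pytest.fixture(scope="session")
def env():
    return bp.REFERENCE_ENVIRONMENT


@pytest.fixture(scope="session")
def constants():
    return bp.DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def model():
    return bp.CalibratedModel()


@pytest.fixture(scope="session")
def tile():
    return bp.TILE_PRIOR


@pytest.fixture(scope="session")
def default_sim():
    """One mid-sized simulated pool shared across read-only tests."""
    scenario = bp.PoolScenario(initial_mass=5.24e-3, shape_irregularity=0.2, seed=11)
    return bp.simulate_drying(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
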