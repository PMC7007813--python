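import numpy as np
import pytest

from befthermal import SimulationConfig, generate_species_pool
from befthermal.simulate import default_design, simulate_community_experiment


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def pool(config):
    return generate_species_pool(config)


@pytest.fixture(scope="session")
def design(config):
    return default_design(config)


@pytest.fixture(scope="session")
def experiment(pool, design, config):
    return simulate_community_experiment(pool, design, config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
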