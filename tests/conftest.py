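import numpy as np
import pytest

from genlen.simulate import SimulationConfig, simulate_world, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A 20-species world, shared across tests that only read it."""
    return simulate_world(
        SimulationConfig(n_species=20, n_genera=8, n_families=3, seed=42,
                         missing_wild_fraction=0.25)
    )


@pytest.fixture(scope="session")
def paper_scale_world():
    """One world at the default (antelope-scale) study conditions."""
    return simulate_world(SimulationConfig(seed=20180125))


def random_yule_graph(n, seed, depth=10.0):
    return simulate_tree(n, 1.0, np.random.default_rng(seed), depth=depth)
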