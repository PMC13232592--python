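import numpy as np
import pytest
from hypothesis import settings

from infantde.simulate import SimConfig, generate_truth, simulate_bundle

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast bundle: enough structure for every stage, seconds to build."""
    return SimConfig(
        n_genes=400,
        n_individuals_per_species_per_age=5,
        n_core_genes=20,
        n_pass_edges_per_lineage=15,
        n_background_edges_per_lineage=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The study conditions the pipeline is validated under."""
    return simulate_bundle(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
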