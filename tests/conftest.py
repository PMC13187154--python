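import numpy as np
import pytest

from aeroferm import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return simulate.SimConfig(seed=7)


@pytest.fixture(scope="session")
def plate_sim(default_config):
    return simulate.simulate_plate(default_config)


@pytest.fixture(scope="session")
def tree_sim(default_config):
    return simulate.simulate_tree_trait_counts(default_config)


@pytest.fixture(scope="session")
def expr_sim(default_config):
    return simulate.simulate_expression(default_config)


@pytest.fixture(scope="session")
def genome_sim():
    return simulate.simulate_genome_with_motifs(
        simulate.SimConfig(seed=7, g_free_background=True)
    )
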