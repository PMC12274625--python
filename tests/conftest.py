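import pytest

from radnet.simulate import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully planted study: ~360 molecules, 5 donors."""
    return SimulationConfig(n_genes=300, n_mirnas=40, n_tfs=20, rng_seed=5)


@pytest.fixture(scope="session")
def small_world(small_config):
    """(expr, edge tables, gene sets, assoc, cat_map, profiles, truth)."""
    return generate_all(small_config)
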