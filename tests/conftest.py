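import numpy as np
import pytest

from precipdiv.synthetic_data import ScenarioConfig, generate_synthesis_dataset


@pytest.fixture(scope="session")
def small_config():
    """Compact but fully hierarchical scenario: 3 studies, 6 experiments."""
    return ScenarioConfig(
        n_studies=3,
        n_experiments_total=6,
        blocks_per_experiment=(3, 4),
        species_pool_size=20,
        individuals_per_plot_control=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_synthesis_dataset(small_config)


@pytest.fixture(scope="session")
def small_effects(small_dataset):
    from precipdiv.effect_sizes import assemble_effect_table

    community, meta, _ = small_dataset
    return assemble_effect_table(community, meta, n_boot=100, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
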