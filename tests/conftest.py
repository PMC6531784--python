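import pytest

from morphoscreen import feature_qc, synthetic_data


@pytest.fixture(scope="session")
def small_screen_config():
    """A scaled-down screen retaining all planted structure: 15 genes x 3
    guides + 8 non-targeting, 4 replicates, 60 features (6 noise, 12
    redundant, 42 base)."""
    return synthetic_data.ScreenConfig(
        n_genes=15,
        guides_per_gene=3,
        n_nontargeting=8,
        replicates=4,
        densities=1,
        n_features=60,
        n_noise_features=6,
        n_redundant_features=12,
        n_lethal=4,
        n_lipo=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_screen_config):
    return synthetic_data.generate_screen(small_screen_config)


@pytest.fixture(scope="session")
def small_qc(small_screen):
    table, _ = small_screen
    return feature_qc.run_feature_qc(table)
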