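import numpy as np
import pandas as pd
import pytest

from depcompress import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_cells=80, n_genes=160, n_factors=8,
                           n_synthetic_lethal=3, n_dosage=3, n_paralog_pairs=3,
                           n_lineages=4, n_lineage_effects=3, rare_category_size=5,
                           seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A desk-scale planted dataset shared across tests (read-only)."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """No noise, no private effects: selective genes are exact factor readouts."""
    cfg = GeneratorConfig(n_cells=40, n_genes=60, n_factors=4, noise_sd=0.0,
                          n_synthetic_lethal=0, n_dosage=0, n_paralog_pairs=0,
                          n_lineages=3, n_lineage_effects=0, rare_category_size=0,
                          nonexpressed_fraction=0.1, seed=5)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def low_noise_dataset():
    """Low noise with every private mechanism planted, for recovery oracles."""
    cfg = GeneratorConfig(n_cells=120, n_genes=200, n_factors=8, noise_sd=0.05,
                          n_synthetic_lethal=4, n_dosage=4, n_paralog_pairs=4,
                          n_lineages=4, n_lineage_effects=4, rare_category_size=6,
                          seed=23)
    return generate_dataset(cfg)
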