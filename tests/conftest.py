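import logging

import pytest

from lactokin.config import AnalysisThresholds
from lactokin.synthetic import SyntheticConfig

logging.getLogger("lactokin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def thresholds():
    return AnalysisThresholds()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic dataset for fast end-to-end tests."""
    return SyntheticConfig(n_genes=400, n_regulated=180, genome_length=2_500_000,
                           n_mutations=60, seed=7)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, artefact-free generator settings for exactness tests."""
    return SyntheticConfig(n_genes=120, n_regulated=90, noise_sd=0.0,
                           dye_bias_amplitude=0.0, nondetectable_fraction=0.0,
                           off_cds_fraction=0.0, genome_length=1_000_000,
                           n_mutations=30, seed=5)
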