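import numpy as np
import pytest

from nirsens import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale generator: 12 samples, 2 replicates, coarse 151-channel grid."""
    return GeneratorConfig(n_samples=12, n_replicates=2, wavenumber_step=40.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
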