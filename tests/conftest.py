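import numpy as np
import pytest

from wristmets.synthetic import ProtocolSpec, SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort for unit tests: 6 subjects, full 8-speed protocol."""
    return SimConfig(n_subjects=6, n_modeling=4, n_validation=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(modeling, validation) feature tables of the scaled-down cohort."""
    return generate_dataset(small_config, ProtocolSpec())
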