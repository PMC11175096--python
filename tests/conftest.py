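import numpy as np
import pytest

from movequal.synthetic import SyntheticCohortConfig, SubjectParams, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_config():
    """Protocol-faithful noise-free generator configuration."""
    return SyntheticCohortConfig(seed=1, noise_sd_frac=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    """Default generator configuration (1% measurement noise)."""
    return SyntheticCohortConfig(seed=1)


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    return generate_trial(clean_config, seed=1)


@pytest.fixture(scope="session")
def noisy_trial(noisy_config):
    return generate_trial(noisy_config, seed=1)


@pytest.fixture
def degraded_params():
    return SubjectParams(
        amplitude_jitter=0.15,
        ripple_amp=0.2,
        alternation_factor=0.3,
        perturbation_sd=0.1,
    )
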