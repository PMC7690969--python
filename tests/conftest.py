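import numpy as np
import pytest
from hypothesis import settings

import infodemic as inf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> inf.SyntheticConfig:
    """A cheap configuration for plumbing tests (reduced comment volume)."""
    return inf.SyntheticConfig(seed=7, comment_volume_mean=2000.0)


@pytest.fixture(scope="session")
def noise_free_config() -> inf.SyntheticConfig:
    """Latent expectations kept as reals; exact-recovery identities hold."""
    return inf.SyntheticConfig(seed=11, noise_scale=0.0, comment_volume_mean=2000.0)


@pytest.fixture(scope="session")
def small_cases(small_config):
    return inf.simulate_epidemic(small_config)


@pytest.fixture(scope="session")
def small_comments(small_config, small_cases):
    return inf.simulate_comments(small_config, small_cases)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200120)
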