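"""Shared fixtures: small synthetic datasets generated at test time."""

import pytest
from hypothesis import HealthCheck, settings

from nutrinet import SyntheticConfig, generate_dataset, generate_with_ground_truth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Three provinces, two years: large enough to exercise every code path."""
    return SyntheticConfig(seed=11, n_years=2, n_provinces=3, members_per_group=2)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config):
    _, truth = generate_with_ground_truth(small_config)
    return truth


@pytest.fixture(scope="session")
def national_config():
    """Single-region dataset with deterministic (zero-CV) member contents."""
    return SyntheticConfig(seed=23, n_years=1, n_provinces=1, within_group_cv=0.0)


@pytest.fixture(scope="session")
def national_data(national_config):
    return generate_dataset(national_config)
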