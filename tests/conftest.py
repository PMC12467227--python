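import pytest
from hypothesis import settings

from torcscan import SimConfig, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """One 12-tip synthetic dataset shared across tests (read-only)."""
    return generate(SimConfig(n_tips=12, n_clades=3, seed=7))


@pytest.fixture(scope="session")
def profiles(small_dataset):
    return small_dataset.profiles
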