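import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ritualsync import RitualConfig, generate_session

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> RitualConfig:
    """A compact session (imam + 11 worshippers, 4 min) for fast end-to-end tests."""
    return RitualConfig(
        duration_s=240,
        n_rakah=2,
        grid_rows=2,
        grid_cols=3,
        n_colocated=5,
        n_separated=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
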