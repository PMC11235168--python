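import pytest
from hypothesis import HealthCheck, settings

from hydrofrac.synthetic import SyntheticConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def zero_noise_config() -> SyntheticConfig:
    """Study-condition generator config with measurement noise switched off."""
    return SyntheticConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)
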