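import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from simindex import SimilarityInterval, SimulationConfig


@pytest.fixture
def si() -> SimilarityInterval:
    return SimilarityInterval()


@pytest.fixture
def fast_config() -> SimulationConfig:
    """Small-rep config for unit tests; calibration-scale runs live elsewhere."""
    return SimulationConfig(reps=4000, seed=7)
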