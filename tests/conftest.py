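import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

from gudscale import PipelineConfig, SimulationConfig, generate_study
from gudscale.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two-series study configuration: every stage exercised, fast to run."""
    return SimulationConfig(n_series=2)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config, seed=7)


@pytest.fixture(scope="session")
def full_result():
    """Full default study (7 treatments x 4 series) through the whole pipeline."""
    return run_pipeline(PipelineConfig(seed=1))
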