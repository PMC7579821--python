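import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study shared by read-only tests."""
    from holosplit.synthetic import SimulationConfig, simulate

    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_report(default_sim):
    """One full pipeline run on the shared study."""
    from holosplit.pipeline import PipelineConfig, run

    return run(PipelineConfig(seed=7), sim=default_sim)
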