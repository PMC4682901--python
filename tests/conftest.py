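import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture(scope="session")
def default_config():
    from tumorshape.simulate import SimulationConfig

    return SimulationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort shared by read-only tests."""
    from tumorshape.simulate import SimulationConfig, generate_clinical

    cfg = SimulationConfig(n_patients=400)
    return generate_clinical(cfg, np.random.default_rng(7))
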