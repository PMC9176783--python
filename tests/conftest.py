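import pytest
from hypothesis import HealthCheck, settings

# deterministic property testing: derandomised, no wall-clock deadline
settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hcrsim import (
    CatchHistoryScenario,
    ProjectionConfig,
    ThresholdCatchRule,
    make_life_history,
)


@pytest.fixture
def lh_medium():
    return make_life_history("medium")


@pytest.fixture
def fig1_rule():
    """Worked-example hockey-stick rule: Cmax=140, Cmin=10, Blim=0.2, Belbow=0.5."""
    return ThresholdCatchRule(cmax=140, cmin=10, blim=0.2, belbow=0.5, name="fig1")


@pytest.fixture
def fully():
    return CatchHistoryScenario(label="fully", noise_sd=0.1)


@pytest.fixture
def fully_noiseless():
    return CatchHistoryScenario(label="fully", noise_sd=0.0)


@pytest.fixture
def cfg_small():
    """Small stochastic configuration for fast closed-loop tests."""
    return ProjectionConfig(n_replicates=5, seed=123)


@pytest.fixture
def cfg_deterministic():
    """All uncertainty switched off."""
    return ProjectionConfig(n_replicates=3, seed=7, bio_sd=0.0, est_sd=0.0, est_bias=0.0)
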