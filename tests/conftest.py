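import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def subcritical_trials():
    """A moderately long, fully sampled branching ensemble (m=0.9)."""
    from mrtau import BranchingConfig, simulate_branching

    cfg = BranchingConfig(
        m=0.9, target_activity=500, length=2000, numtrials=200, seed=1234
    )
    return simulate_branching(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
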