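import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def static_trial():
    """Zero-noise trial at a fixed tilted orientation."""
    from wristdtw.synthetic import ZERO_NOISE, simulate_trial, static_template

    return simulate_trial(
        static_template(0.4, -0.25, 0.9), ZERO_NOISE, 7, trial_id="static"
    )


@pytest.fixture(scope="session")
def small_participant():
    """One-task participant, small but classifiable: shared by several
    integration tests to amortize the pipeline cost."""
    from wristdtw.synthetic import (
        SyntheticConfig,
        simulate_participant,
        truth_mapping,
    )

    cfg = SyntheticConfig(
        tasks=(1,),
        lab_trials_correct=4,
        lab_trials_per_incorrect=3,
        home_trials_per_task=12,
    )
    lab, home, truth = simulate_participant(cfg, 3)
    return lab, home, truth_mapping(truth)
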