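import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_trajectory():
    """Sinusoidal head trajectory at the normal peak velocity (285.6 mm/s)."""
    from slantflow.synthetic_observer import make_trajectory

    return make_trajectory(285.6, 25.0, 11, 1000.0)


@pytest.fixture(scope="session")
def slow_trajectory():
    from slantflow.synthetic_observer import make_trajectory

    return make_trajectory(57.7, 25.0, 11, 1000.0)


@pytest.fixture(scope="session")
def avv_trials_with_responses():
    """One synthetic AVV block: 17 subjects x 25 trials, default k and noise."""
    from slantflow.synthetic_observer import ConditionSpec, generate_trials, simulate_responses

    trials = generate_trials(ConditionSpec("AVV"), n_subjects=17, seed=11)
    return simulate_responses(trials, seed=12)


def assert_close(actual, expected, rtol=1e-9, atol=0.0):
    np.testing.assert_allclose(actual, expected, rtol=rtol, atol=atol)
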