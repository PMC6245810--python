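import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ghostrisk import Cohort, default_wihs_scenario, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_cohort(rng: np.random.Generator, n: int, event_frac: float = 0.7) -> Cohort:
    """Small random right-censored cohort for property tests."""
    time = rng.exponential(3.0, n) + 1e-3
    event = (rng.random(n) < event_frac).astype(int)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return Cohort.from_arrays(time, event)


@pytest.fixture(scope="session")
def wihs_like_cohort() -> Cohort:
    """One default-scenario synthetic cohort, shared across tests."""
    return generate_cohort(default_wihs_scenario(7))
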