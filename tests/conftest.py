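import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pubage as pa

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def female_model() -> pa.TransitionModel:
    return pa.INDONESIA_FEMALE


@pytest.fixture(scope="session")
def male_model() -> pa.TransitionModel:
    return pa.INDONESIA_MALE


@pytest.fixture(scope="session")
def uniform_female_cohort():
    """n=2000 cohort at the female reference truth, uniform ages."""
    spec = pa.CohortSpec(
        n=2000, sex="F", true_model=pa.INDONESIA_FEMALE,
        age_distribution=pa.AgeDistribution("uniform", 17, 86), seed=42,
    )
    return pa.simulate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_female(uniform_female_cohort) -> pa.TransitionModel:
    return pa.fit_transition_model(
        uniform_female_cohort["age"], uniform_female_cohort["phase_left"], sex="F"
    )


def random_model(rng: np.random.Generator, n_stages: int = 6) -> pa.TransitionModel:
    """A random valid transition model with thresholds inside the log support."""
    lo, hi = np.log(17.0), np.log(86.0)
    t = np.sort(rng.uniform(lo - 0.3, hi + 0.3, size=n_stages - 1))
    while np.any(np.diff(t) < 0.05):
        t = np.sort(rng.uniform(lo - 0.3, hi + 0.3, size=n_stages - 1))
    sigma = rng.uniform(0.1, 0.6)
    return pa.TransitionModel(thresholds=t, sigma=float(sigma))
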