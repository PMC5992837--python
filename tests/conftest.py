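import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import priceits as p

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return p.InterventionSchedule()


@pytest.fixture(scope="session")
def X(schedule):
    return p.build_design_matrix(schedule)


@pytest.fixture(scope="session")
def Xc(X):
    """Design with intercept, as the estimators see it."""
    return np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])


@pytest.fixture(scope="session")
def study_beta():
    """Published overall-cost coefficients (billion KRW)."""
    return np.array([29.982, 0.295, -0.984, -0.136, -4.384, 0.192, -2.643])


def simulate_ar1_series(Xc, beta, rho, sd, rng):
    """Independent data-generating oracle: the AR(1) recursion, written out."""
    n = Xc.shape[0]
    u = rng.normal(0.0, sd, n)
    e = np.empty(n)
    e[0] = u[0] / np.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + u[t]
    return Xc @ beta + e


@pytest.fixture(scope="session")
def ar1_oracle():
    return simulate_ar1_series
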