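import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metadiff.preprocess import MetaRegressionProblem

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_problem(rng, n=12, p=2, tau2=0.05, beta=None, s2_range=(0.001, 0.1)):
    """Random meta-regression problem generated exactly under the model."""
    X = np.column_stack(
        [np.ones(n), np.repeat([0.0, 1.0], [n - n // 2, n // 2])]
        + [rng.normal(size=n) for _ in range(p - 2)]
    )
    if beta is None:
        beta = np.concatenate([[3.0, 0.0], np.zeros(p - 2)])
    s2 = rng.uniform(*s2_range, size=n)
    y = X @ beta + rng.normal(0.0, np.sqrt(s2 + tau2))
    return MetaRegressionProblem(log_y=y, within_var=s2, design=X, coef_of_interest=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
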