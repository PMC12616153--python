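import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from roimed import SyntheticConfig, generate_cohort, generate_scored_cohort, generate_trials

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_participants=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort, truth


@pytest.fixture(scope="session")
def small_trials(small_config, small_cohort):
    cohort, _ = small_cohort
    return generate_trials(cohort, small_config)


@pytest.fixture(scope="session")
def scored_cohort(small_config):
    merged, truth = generate_scored_cohort(small_config)
    return merged, truth


def make_mediation_data(
    n: int, a: float, b: float, c_prime: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Gaussian data with known standardized mediation paths."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1.0 - a**2) * rng.standard_normal(n)
    var_y = c_prime**2 + b**2 + 2.0 * a * b * c_prime
    if var_y >= 1.0:
        raise ValueError("paths too large for unit-variance outcome")
    y = c_prime * x + b * m + np.sqrt(1.0 - var_y) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})
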