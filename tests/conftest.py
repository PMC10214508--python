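import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from crankms import (
    BootstrapPlan,
    SyntheticSpec,
    bundled_pd_marker_compounds,
    default_spec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Strongly separated little cohort: fast to fit, easy to classify."""
    return generate_dataset(
        SyntheticSpec(n_subjects=40, n_features=20, n_informative=5,
                      effect_fold=4.0, correlation_rho=0.2, seed=101)
    )


@pytest.fixture(scope="session")
def missing_dataset():
    return generate_dataset(
        SyntheticSpec(n_subjects=30, n_features=12, n_informative=3,
                      effect_fold=3.0, missing_rate=0.1, seed=77)
    )


@pytest.fixture(scope="session")
def compound_db():
    return bundled_pd_marker_compounds()


@pytest.fixture
def fast_plan():
    return BootstrapPlan(n_iterations=5, seed=11)


@pytest.fixture(scope="session")
def separable_toy():
    """Two well-separated 2-D point clouds (linearly separable)."""
    rng = np.random.default_rng(3)
    n = 30
    X = np.vstack([
        rng.normal([-3, -3], 0.3, size=(n, 2)),
        rng.normal([3, 3], 0.3, size=(n, 2)),
    ])
    y = np.array([0] * n + [1] * n)
    return X, y


@pytest.fixture(scope="session")
def xor_toy():
    """Four tight clusters in XOR arrangement: linearly inseparable."""
    rng = np.random.default_rng(4)
    n = 25
    centers = [(-2, -2, 1), (2, 2, 1), (-2, 2, 0), (2, -2, 0)]
    X = np.vstack([rng.normal([cx, cy], 0.2, size=(n, 2)) for cx, cy, _ in centers])
    y = np.concatenate([[lab] * n for _, _, lab in centers])
    return X, y
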