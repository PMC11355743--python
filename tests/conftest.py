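import numpy as np
import pytest

from tpscore import CohortConfig, EventTensor, MarkerSpec, OutcomeVector, generate_cohort
from tpscore.datatypes import day_labels_for


def make_tensor(data, categories=None) -> EventTensor:
    """Wrap a raw binary array in an EventTensor with generated labels."""
    data = np.asarray(data, dtype=np.uint8)
    n, t, f = data.shape
    return EventTensor(
        data,
        [f"case{i}" for i in range(n)],
        day_labels_for(t),
        [f"lab:F{j}" for j in range(f)],
        categories or ["lab"] * f,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """A quick cohort with one strong planted monotonic marker."""
    cfg = CohortConfig(
        n_cases=300,
        n_features=12,
        markers=[
            MarkerSpec(
                feature_index=0,
                pattern="monotonic_mortality",
                rate_mortality_far=0.8,
                rate_mortality_near=0.8,
                rate_recovery_far=0.1,
                rate_recovery_near=0.1,
            )
        ],
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def random_tensor(rng):
    X = make_tensor(rng.integers(0, 2, size=(6, 10, 4)))
    Y = OutcomeVector(np.array([1, 0, 1, 0, 1, 0]), list(X.case_ids))
    return X, Y
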