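import numpy as np
import pandas as pd
import pytest

from keysense.instances import FeatureMatrix
from keysense.simulate import SimulationConfig, default_planted, make_cohort_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default simulation (65 healthy + 14 dementia x 8 activities)."""
    return make_cohort_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study for fast module tests: 13 participants, 4 activities."""
    activities = (1, 2, 3, 4)
    return SimulationConfig(
        n_healthy=10,
        n_dementia=3,
        activities=activities,
        planted=default_planted(activities=activities),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_cohort_dataset(small_config)


@pytest.fixture()
def toy_matrix():
    """3 classes x 9 instances x 4 features, hand-checkable counts."""
    data = pd.DataFrame(
        {
            "f1": [5, 5, 0, 1, 0, 0, 2, 2, 2],
            "f2": [2, 2, 0, 8, 8, 8, 0, 0, 1],
            "f3": [0, 0, 0, 0, 0, 0, 9, 9, 9],
            "f4": [1, 0, 0, 0, 1, 0, 0, 0, 0],
        }
    )
    return FeatureMatrix(
        data=data,
        class_labels=np.array([1, 1, 1, 2, 2, 2, 3, 3, 3]),
        cohorts=np.array(["healthy"] * 9),
        participant_ids=np.array([f"p{i}" for i in range(9)]),
    )


def random_feature_matrix(rng, n_rows, n_features, n_classes):
    """Random small count matrix for oracle comparisons."""
    data = pd.DataFrame(
        rng.poisson(1.5, size=(n_rows, n_features)),
        columns=[f"f{j}" for j in range(n_features)],
    ).astype(float)
    return FeatureMatrix(
        data=data,
        class_labels=rng.integers(0, n_classes, n_rows),
        cohorts=np.array(["healthy"] * n_rows),
        participant_ids=np.array([f"p{i}" for i in range(n_rows)]),
    )
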