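import numpy as np
import pandas as pd
import pytest

from phradiomics.cohort import CohortConfig, FeatureMatrix, SideStudyBundle
from phradiomics.runner import build_cohort_data


@pytest.fixture(scope="session")
def default_data():
    """One default-condition cohort (42 cases / 40 controls, 348 features
    per mask) shared across tests that only read it."""
    return build_cohort_data(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A miniature cohort for fast pipeline tests."""
    return CohortConfig(
        n_cases=12,
        n_controls=12,
        n_features_per_mask=30,
        n_informative_stable=2,
        n_informative_unstable=6,
        frac_side_study=0.5,
        effect_size=2.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return build_cohort_data(small_config)


def make_bundle(arrays, subject_ids=None, feature_names=None, mask="LV"):
    """Build a SideStudyBundle from three (subjects x features) arrays."""
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    n, p = arrays[0].shape
    subject_ids = subject_ids or [f"S{i:02d}" for i in range(n)]
    feature_names = feature_names or [f"f{j}" for j in range(p)]
    return SideStudyBundle(
        tuple(
            FeatureMatrix(
                pd.DataFrame(a, index=subject_ids, columns=feature_names), mask, str(e)
            )
            for e, a in zip((1, 2, 3), arrays)
        )
    )


@pytest.fixture
def toy_bundle():
    """Two subjects, one feature, hand-enumerable differences."""
    return make_bundle(
        [np.array([[1.0], [4.0]]), np.array([[2.0], [3.0]]), np.array([[0.0], [5.0]])]
    )
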