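import numpy as np
import pytest

import muscnet as mn
from muscnet.features import feature_matrix


@pytest.fixture(scope="session")
def small_linear_cohort():
    """A desk-speed cohort with a strong planted linear effect (8+8 subjects)."""
    spec = mn.CohortSpec(
        n_per_group=8, num_roi=10, num_volume=60, effect_delta=0.6, seed=123
    )
    return mn.generate_cohort(spec), spec


@pytest.fixture(scope="session")
def small_pcc_features(small_linear_cohort):
    cohort, _ = small_linear_cohort
    X = feature_matrix(cohort.subjects, "PCC")
    return X, cohort.labels, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
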