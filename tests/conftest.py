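import warnings

import numpy as np
import pytest

import mddsubtypes as m


@pytest.fixture(autouse=True)
def _silence_zero_variance_warning():
    # noiseless cohorts legitimately drop the constant hypersomnia column
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping zero-variance")
        yield


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise planted 3-subtype cohort plus its true labels."""
    matrix, labels = m.generate_symptom_cohort(m.noiseless_cohort_spec(90, seed=1))
    return matrix, labels


@pytest.fixture(scope="session")
def noisy_cohort():
    """Moderate-noise planted cohort (study-like profiles, no targets)."""
    spec = m.CohortSpec(150, m.study_profiles(), noise_sd=0.6, seed=2)
    return m.generate_symptom_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
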