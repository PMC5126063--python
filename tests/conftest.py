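import numpy as np
import pytest

import pdqeeg as pq


@pytest.fixture(scope="session")
def clean_spec():
    """Artifact-free generator spec used by several round-trip tests."""
    return pq.EEGGenSpec(duration=60.0, seed=7)


@pytest.fixture(scope="session")
def clean_rec(clean_spec):
    return pq.generate_eeg(clean_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """80-subject cohort with sampled spectral features and planted outcome."""
    feats = pq.sample_spectral_features(80, seed=11)
    cohort = pq.generate_cohort(pq.CohortGenSpec(n_subjects=80, seed=11), feats)
    return feats, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
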