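import numpy as np
import pytest

from ppg2ecg import preprocess as pp
from ppg2ecg import synthdata as sd


@pytest.fixture(scope="session")
def clean_cohort():
    """Ten artifact-free subjects, 60 s each (shared across peak tests)."""
    return sd.make_cohort(10, 60.0, seed=1234)


@pytest.fixture(scope="session")
def small_cohort():
    return sd.make_cohort(2, 60.0, seed=77)


@pytest.fixture(scope="session")
def segment_pairs(small_cohort):
    cfg = pp.PreprocessConfig(window_s=4)
    return pp.preprocess_cohort(small_cohort, cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
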