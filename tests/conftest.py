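import numpy as np
import pytest

from lvifusion.cohort import CohortSpec, sample_clinical_features


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A fast-rendering cohort spec for I/O and rendering tests."""
    return CohortSpec(n_cases=6, volume_shape=(36, 36, 36), lesion_radius_range=(3.0, 5.0), seed=11)


@pytest.fixture(scope="session")
def feature_table():
    spec = CohortSpec(n_cases=400, seed=3)
    return sample_clinical_features(400, spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
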