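import numpy as np
import pytest

from cbfmed.config import AcquisitionConfig, CohortConfig
from cbfmed.synthetic import build_masks, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_acq():
    """A reduced acquisition (16x16x2 grid, 24 frames) for fast fits."""
    return AcquisitionConfig(matrix_shape=(16, 16), n_slices=2,
                             n_tag=12, n_control=12, noise_sd=5.0)


@pytest.fixture
def small_masks(small_acq):
    return build_masks(small_acq.shape)


@pytest.fixture
def cohort41():
    """Default-conditions cohort: n = 41, ages 55-85, full gray mediation."""
    return generate_cohort(CohortConfig(), seed=11)
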