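import numpy as np
import pandas as pd
import pytest

from dalff.preprocess import BoldImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bold(data, tr=2.0, voxel_size=3.0, mask=None):
    data = np.asarray(data, dtype=np.float64)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldImage(data=data, affine=affine, tr=tr, mask=mask)


@pytest.fixture
def bold_factory():
    return make_bold


@pytest.fixture
def small_covariates():
    """6 + 6 subject covariate table."""
    rng = np.random.default_rng(0)
    n = 12
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": ["patient"] * 6 + ["control"] * 6,
            "age": rng.uniform(20, 80, n).round(1),
            "sex": rng.integers(0, 2, n),
            "score": rng.poisson(4, n),
        }
    )
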