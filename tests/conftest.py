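import numpy as np
import pandas as pd
import pytest

from kfis import KernelSpec, KSCParams
from kfis.synthetic import SyntheticSpec, generate, generate_blobs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_blobs():
    """Two tight, well-separated clusters in [0, 1]² (20 points each)."""
    return generate_blobs(2, 20, separation=0.8, dim=2, seed=1, cluster_sd=0.03)


@pytest.fixture(scope="session")
def random_points_2d():
    """50 random 2-D points in [0, 1]² for linear-kernel reduction checks."""
    return np.random.default_rng(7).random((50, 2))


@pytest.fixture(scope="session")
def separable_dataset():
    """Two Gaussian clouds in 2-D separated by 5 within-class SDs."""
    g = np.random.default_rng(3)
    a = g.normal(0.2, 0.04, size=(20, 2))
    b = g.normal(0.8, 0.04, size=(20, 2))
    X = np.vstack([a, b])
    y = np.array([0] * 20 + [1] * 20)
    return X, y


@pytest.fixture(scope="session")
def synthetic_expression():
    """A small microarray-like dataset with a known informative subset."""
    spec = SyntheticSpec(n_genes=120, n_informative=8, effect_size=3.0, seed=11)
    return generate(spec)


@pytest.fixture
def toy_frame():
    return pd.DataFrame(
        {
            "gA": [1.0, np.nan, 3.0],
            "gB": [0.0, 5.0, 10.0],
            "gC": [3.0, 3.0, 3.0],
        },
        index=["s1", "s2", "s3"],
    )


@pytest.fixture(params=["linear", "polynomial", "rbf", "tansig"])
def any_kernel(request):
    return KernelSpec(request.param, gamma=0.5, coef=0.1, degree=2)


@pytest.fixture
def default_params():
    return KSCParams()
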