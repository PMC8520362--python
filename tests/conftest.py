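import numpy as np
import pytest

from sonokr import PhantomSpec, PointCloud, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def affine_cloud(rng):
    """Noiseless samples of the affine field 2 + 3x - y + 0.5z."""
    X = rng.uniform(-1.0, 1.0, size=(400, 3))
    y = 2.0 + 3.0 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2]
    return PointCloud(positions=X, values=y)


def affine_field(p):
    p = np.atleast_2d(p)
    return 2.0 + 3.0 * p[:, 0] - p[:, 1] + 0.5 * p[:, 2]


@pytest.fixture(scope="session")
def default_truth():
    return make_phantom(PhantomSpec())
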