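import numpy as np
import pytest

import kfcmiss as kf


@pytest.fixture(scope="session")
def iris_like():
    """Complete three-cluster mixture (150 x 4) with generating labels."""
    X, y = kf.generate_mixture(kf.iris_like_spec(seed=1))
    return X, y


@pytest.fixture(scope="session")
def iris_like_masked(iris_like):
    """The same mixture with a 10% row-guarded MCAR mask applied."""
    X, y = iris_like
    mask = kf.generate_mcar_mask(
        *X.shape, kf.MissingConfig(theta=0.10, seed=1, row_guard=True)
    )
    return kf.apply_mask(X, mask, labels=y), X


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_blobs():
    """Two tight, widely separated 2-D blobs of 10 points each."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 0.0], 0.3, size=(10, 2))
    b = rng.normal([10.0, 10.0], 0.3, size=(10, 2))
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 10)
    return X, y
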