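import numpy as np
import pytest

from dlbcnet.datasets import make_gaussian_features, make_synthetic_cell_images
from dlbcnet.rnn import one_hot


@pytest.fixture(scope="session")
def separable_features():
    """Well-separated 4-class Gaussian clouds: (X, y, Y_onehot)."""
    x, y = make_gaussian_features(200, 4, 8, separation=10.0, seed=42)
    return x, y, one_hot(y, 4)


@pytest.fixture(scope="session")
def cell_images():
    """Small 4-class fixture image set (32x32, 20 per class)."""
    return make_synthetic_cell_images(20, 4, (32, 32), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
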