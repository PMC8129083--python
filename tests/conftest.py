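import numpy as np
import pytest

from xoxdr import LabeledDataset


@pytest.fixture
def four_point():
    """Two axis-aligned two-point classes: the canonical hand-worked case."""
    X = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])
    return LabeledDataset.from_arrays(X, ["a", "a", "b", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n=30, p=12, C=2, shift=3.0):
    """Gaussian blobs with distinct class means; labels cyclic for balance."""
    y = np.arange(n) % C
    X = rng.standard_normal((n, p))
    for c in range(C):
        X[y == c] += shift * rng.standard_normal(p) / np.sqrt(p)
    return LabeledDataset(X, y, classes=np.arange(C))


def sign_align(A, B):
    """Flip columns of B to match the signs of A (for eigenvector comparison)."""
    B = B.copy()
    for j in range(A.shape[1]):
        if np.dot(A[:, j], B[:, j]) < 0:
            B[:, j] = -B[:, j]
    return B
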