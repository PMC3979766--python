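import numpy as np
import pytest

from smartclust.core import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_blobs(rng, centers, n_per=60, sd=0.3):
    """Well-separated spherical Gaussian blobs with truth labels."""
    pts, lab = [], []
    for i, c in enumerate(centers):
        c = np.asarray(c, dtype=float)
        pts.append(c + sd * rng.standard_normal((n_per, c.size)))
        lab.append(np.full(n_per, i + 1))
    return DataMatrix.from_array(np.vstack(pts)), np.concatenate(lab)


@pytest.fixture
def two_blobs(rng):
    return make_blobs(rng, [(0.0, 0.0), (10.0, 10.0)])
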