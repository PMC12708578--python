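import numpy as np
import pytest

from fedlsh import blinding


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dense_rotation_product(rotations, dim):
    """Oracle: the dense matrix P1·P2·…·Pl built by explicit multiplication."""
    out = np.eye(dim)
    for rot in rotations:
        out = out @ blinding.rotation_as_dense(rot, dim)
    return out


@pytest.fixture
def random_instance(rng):
    """A small random blinding instance: (X, W, key) with matching shapes."""

    def make(m=10, d=6, t=8, l=4):
        X = blinding.FeatureMatrix(
            values=rng.normal(size=(m, d)), row_ids=[f"item-{k}" for k in range(m)]
        )
        W = rng.normal(size=(t, d))
        key = blinding.keygen(m, d, l, rng)
        return X, W, key

    return make
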