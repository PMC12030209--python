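import numpy as np
import pytest

from gnnpot import Configuration, create_model, small_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def argon_model():
    """A small FP64 model with fixed random (untrained) parameters."""
    return create_model(small_spec([18], seed=7))


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_cluster(rng, n=6, scale=2.5, element=18, min_sep=1.0) -> Configuration:
    """Random aperiodic cluster with a minimum pair separation (Å)."""
    while True:
        pos = rng.normal(size=(n, 3)) * scale
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        if np.all(d[np.triu_indices(n, 1)] > min_sep):
            return Configuration(pos, np.full(n, element))
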