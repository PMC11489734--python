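import numpy as np
import pytest

from symgate.synthetic_data import ToyModelSpec, build_toy_transition_matrix


@pytest.fixture(scope="session")
def small_spec():
    """Low-dimensional pentamer toy spec for fast estimator tests."""
    return ToyModelSpec(b=3)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_toy_transition_matrix(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pentamer_ring_coords(rng=None, n_fold=5, atoms=3, radius=0.8, jitter=0.0):
    """Cα ring in nm: subunit clusters at radius with small local offsets."""
    offsets = np.array([[0.0, 0.0, 0.0], [0.12, 0.05, 0.08], [0.02, -0.1, 0.15]])[
        :atoms
    ]
    coords = np.zeros((n_fold * atoms, 3))
    subunit_ids = np.repeat(np.arange(n_fold), atoms)
    for s in range(n_fold):
        th = 2 * np.pi * s / n_fold
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        anchor = rot @ np.array([radius, 0.0, 0.0])
        coords[s * atoms : (s + 1) * atoms] = offsets @ rot.T + anchor
    if rng is not None and jitter > 0:
        coords = coords + rng.normal(0, jitter, size=coords.shape)
    return coords, subunit_ids
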