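import numpy as np
import pytest

from loopdyn.model_io import Trajectory, select_atoms
from loopdyn.synthetic_data import (
    GG_LOOP,
    GG_SEQUENCE,
    build_duplex,
    gg_loop_spec,
    sample_ensemble,
)

LOOP_RESIDUES = list(GG_LOOP[0]) + list(GG_LOOP[1])


def random_rotation(rng) -> np.ndarray:
    """A uniform-ish random proper rotation via QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


@pytest.fixture(scope="session")
def duplex():
    """All-anti self-complementary 12-mer duplex with strand-swap symmetry."""
    topo, frame = build_duplex(GG_SEQUENCE)
    return topo, frame


@pytest.fixture(scope="session")
def loop_heavy(duplex):
    topo, _ = duplex
    return select_atoms(topo, residues=LOOP_RESIDUES, heavy=True)


@pytest.fixture(scope="session")
def gg_small_ensemble():
    """Four-state ensemble at 1/10 of the reference proportions + noise."""
    spec = gg_loop_spec(
        {"sa/as": 85, "as/as": 72, "aa/aa": 8, "as/sa": 7},
        n_noise=28,
        noise_sigma=0.15,
        seed=11,
    )
    return sample_ensemble(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_traj(coords, topo, times=None) -> Trajectory:
    return Trajectory(np.asarray(coords, dtype=float), topo, times)
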