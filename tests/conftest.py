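import numpy as np
import pytest

import batgen as bg


@pytest.fixture(scope="session")
def toy():
    """Small branched toy molecule: (topology, frame, indexing)."""
    top, frame = bg.make_toy_molecule(10, branches=(3, 6))
    return top, frame, bg.build_bat_indexing(top)


@pytest.fixture(scope="session")
def two_state():
    """Canonical two-state concerted-torsion dataset:
    (topology, frame, indexing, trajectory, torsion model)."""
    return bg.two_state_fixture(n_frames=400, seed=3)


@pytest.fixture(scope="session")
def fixture_features(two_state):
    """Stride-split vBAT features: (train, valid, all-in-temporal-order)."""
    _, _, idx, traj, _ = two_state
    tr, va = bg.stride_split(traj, 2, 0, 1)
    ftr = bg.cartesian_to_vbat(tr.coords, idx)
    fva = bg.cartesian_to_vbat(va.coords, idx)
    order = np.argsort(np.concatenate([np.arange(0, traj.n_frames, 2),
                                       np.arange(1, traj.n_frames, 2)]))
    return ftr, fva, np.concatenate([ftr, fva])[order]


FIXTURE_TRAIN_CONFIG = bg.TrainConfig(
    iterations=500, batch_size=200, seed=0,
    lr_schedule=[(0, 0.01), (300, 0.005)],
)


@pytest.fixture(scope="session")
def trained_model(two_state, fixture_features):
    """Autoencoder trained on the two-state fixture (shared across tests)."""
    top, _, _, _, _ = two_state
    ftr, fva, _ = fixture_features
    model = bg.build_model(bg.ModelConfig(n_f=ftr.shape[1]), seed=0)
    model.topology_hash = top.hash()
    bg.train(model, ftr, fva, FIXTURE_TRAIN_CONFIG)
    return model


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=10.0, size=3)


def dihedral_oracle(p0, p1, p2, p3):
    """Four-point dihedral by atan2 of cross/dot products (test oracle)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2)


def wrap_angle(a):
    """Wrap to (-π, π]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi
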