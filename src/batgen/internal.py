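"""Exact, batched conversion among Cartesian, BAT, and vBAT representations.

Classical bond-angle-torsion (BAT, Z-matrix) coordinates describe each atom
beyond the three root atoms by a bond length b_i (Å), a bond angle α_i and a
torsion θ_i relative to three previously placed atoms.  The transform is an
exact bijection given the external block (the root atoms' Cartesian
positions), so Cartesian → BAT → Cartesian reproduces coordinates to
floating-point precision.

Torsions are periodic, which poisons arithmetic near ±180°: the step from
179° to −179° is a 2° rotation, not 358°.  The vBAT feature vector removes
the discontinuity by replacing each (b, α, θ) triple with four 3-vectors per
placement quadruple (i, j, k, l):

    n̂_ijk = -(v_ij × v_jk)/|v_ij × v_jk|,   n̂_jkl = -(v_jk × v_kl)/|v_jk × v_kl|,
    v_ij = r_j - r_i,                        v_jk = r_k - r_j,

i.e. the unit normals of the two torsion planes plus the two inner bond
vectors, giving 4×3×(N-3) features per conformation.  Angles and torsions are
recovered exactly from dot/cross products; bond lengths and the external
block are supplied by a reference conformation during decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import BATIndexing, MoleculeTopology

__all__ = [
    "BATState",
    "feature_length",
    "cartesian_to_bat",
    "bat_to_cartesian",
    "cartesian_to_vbat",
    "vbat_to_cartesian",
    "reference_from_frame",
    "save_features",
    "load_features",
]

_DEGENERACY_TOL = 1e-10


@dataclass
class BATState:
    """Batched internal-coordinate state.

    root_coords : (n, 3, 3) Cartesian positions of the root atoms — the
        external block (global position/orientation) plus the two root bonds
        and the root angle.
    bonds, angles, torsions : (n, N-3) arrays in construction order; bonds in
        Å, angles in (0, π), torsions in (-π, π].
    """

    root_coords: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    torsions: np.ndarray

    def __post_init__(self):
        self.root_coords = np.atleast_3d(np.asarray(self.root_coords, dtype=float))
        self.bonds = np.atleast_2d(np.asarray(self.bonds, dtype=float))
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        self.torsions = np.atleast_2d(np.asarray(self.torsions, dtype=float))
        if np.any(self.bonds <= 0):
            raise ValueError("bond lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.bonds.shape[0]

    def single(self, idx: int = 0) -> "BATState":
        return BATState(self.root_coords[idx:idx + 1], self.bonds[idx:idx + 1],
                        self.angles[idx:idx + 1], self.torsions[idx:idx + 1])


def feature_length(n_atoms: int) -> int:
    """Length of the flat vBAT vector: 4 vectors × 3 components × (N-3)."""
    return 12 * (n_atoms - 3)


def _promote(frames: np.ndarray) -> tuple:
    frames = np.asarray(frames, dtype=float)
    squeeze = frames.ndim == 2
    if squeeze:
        frames = frames[None]
    return frames, squeeze


def _norm(v: np.ndarray) -> np.ndarray:
    return np.linalg.norm(v, axis=-1)


def _quad_vectors(frames: np.ndarray, indexing: BATIndexing):
    q = indexing.placement_array
    pi, pj, pk, pl = (frames[:, q[:, c]] for c in range(4))
    v_ij = pj - pi
    v_jk = pk - pj
    v_kl = pl - pk
    return v_ij, v_jk, v_kl


def _dihedral(v_ij, v_jk, v_kl):
    """Signed torsion between plane (i,j,k) and plane (j,k,l), in (-π, π]."""
    n1 = np.cross(v_ij, v_jk)
    n2 = np.cross(v_jk, v_kl)
    m = np.cross(n1, n2)
    jk_hat = v_jk / _norm(v_jk)[..., None]
    return np.arctan2(np.einsum("...i,...i", m, jk_hat),
                      np.einsum("...i,...i", n1, n2))


def cartesian_to_bat(frames, indexing: BATIndexing) -> BATState:
    """Convert Cartesian frames (n, N, 3) or (N, 3) to internal coordinates."""
    frames, _ = _promote(frames)
    v_ij, v_jk, v_kl = _quad_vectors(frames, indexing)
    b = _norm(v_ij)
    if np.any(b < _DEGENERACY_TOL):
        bad = int(indexing.placement_array[np.argwhere(b < _DEGENERACY_TOL)[0][1], 0])
        raise ValueError(f"coincident bonded atoms at placement of atom {bad}")
    cos_a = -np.einsum("...i,...i", v_ij, v_jk) / (b * _norm(v_jk))
    for n, scale in ((np.cross(v_ij, v_jk), b * _norm(v_jk)),
                     (np.cross(v_jk, v_kl), _norm(v_jk) * _norm(v_kl))):
        degenerate = _norm(n) < 1e-8 * scale
        if np.any(degenerate):
            col = np.argwhere(degenerate)[0]
            bad = int(indexing.placement_array[col[1], 0])
            raise ValueError(
                f"collinear reference triple at placement of atom {bad}")
    angles = np.arccos(np.clip(cos_a, -1.0, 1.0))
    torsions = _dihedral(v_ij, v_jk, v_kl)
    root_coords = frames[:, list(indexing.root)]
    return BATState(root_coords, b, angles, torsions)


def bat_to_cartesian(state: BATState, indexing: BATIndexing) -> np.ndarray:
    """Rebuild Cartesian frames from internal coordinates, atoms in
    construction order (NeRF-style placement)."""
    n_frames = state.n_frames
    n_atoms = indexing.n_placed + 3
    coords = np.empty((n_frames, n_atoms, 3), dtype=float)
    r0, r1, r2 = indexing.root
    coords[:, [r0, r1, r2]] = state.root_coords
    for p, (i, j, k, l) in enumerate(indexing.placements):
        b = state.bonds[:, p, None]
        alpha = state.angles[:, p, None]
        theta = state.torsions[:, p, None]
        cj, ck, cl = coords[:, j], coords[:, k], coords[:, l]
        bc = cj - ck
        bc /= _norm(bc)[..., None]
        n = np.cross(ck - cl, bc)
        nn = _norm(n)
        if np.any(nn < _DEGENERACY_TOL):
            raise ValueError(f"collinear reference triple while placing atom {i}")
        n /= nn[..., None]
        m = np.cross(n, bc)
        d = (-np.cos(alpha) * bc
             + np.sin(alpha) * np.cos(theta) * m
             + np.sin(alpha) * np.sin(theta) * n)
        coords[:, i] = cj + b * d
    return coords


def _root_frame(frames: np.ndarray, indexing: BATIndexing) -> np.ndarray:
    """Right-handed orthonormal basis attached to the root triple, (n, 3, 3).

    Rows are the basis vectors: e1 along the first root bond, e2 the
    orthogonalized second root bond, e3 = e1 × e2.  Expressing all feature
    vectors in this molecule-fixed basis removes the global orientation, so
    features are *invariant* (not merely equivariant) under rigid motion.
    """
    r0, r1, r2 = indexing.root
    e1 = frames[:, r1] - frames[:, r0]
    n1 = _norm(e1)
    if np.any(n1 < _DEGENERACY_TOL):
        raise ValueError("coincident root atoms")
    e1 = e1 / n1[..., None]
    v = frames[:, r2] - frames[:, r1]
    v = v - np.einsum("...i,...i", v, e1)[..., None] * e1
    n2 = _norm(v)
    if np.any(n2 < _DEGENERACY_TOL):
        raise ValueError("collinear root atoms: molecule frame undefined")
    e2 = v / n2[..., None]
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def cartesian_to_vbat(frames, indexing: BATIndexing) -> np.ndarray:
    """Featurize frames as flat vBAT vectors of length 12·(N-3).

    All blocks are relative vectors or plane normals expressed in the
    molecule-fixed root frame, so the output is invariant under any rigid
    rotation + translation of the input conformation.
    """
    frames, squeeze = _promote(frames)
    v_ij, v_jk, v_kl = _quad_vectors(frames, indexing)
    basis = _root_frame(frames, indexing)  # (n, 3, 3), rows = e1,e2,e3
    v_ij, v_jk, v_kl = (np.einsum("nqi,nbi->nqb", v, basis)
                        for v in (v_ij, v_jk, v_kl))
    for name, v in (("v_ij", v_ij), ("v_jk", v_jk), ("v_kl", v_kl)):
        if np.any(_norm(v) < _DEGENERACY_TOL):
            raise ValueError(f"zero-length bond vector in block {name}")
    n1 = -np.cross(v_ij, v_jk)
    n2 = -np.cross(v_jk, v_kl)
    for n in (n1, n2):
        nn = _norm(n)
        if np.any(nn < _DEGENERACY_TOL):
            raise ValueError("collinear atoms: torsion plane normal undefined")
        n /= nn[..., None]
    feats = np.concatenate([n1, n2, v_ij, v_jk], axis=-1)  # (n, N-3, 12)
    flat = feats.reshape(frames.shape[0], -1)
    return flat[0] if squeeze else flat


def vbat_to_cartesian(features, reference: BATState,
                      indexing: BATIndexing) -> np.ndarray:
    """Decode vBAT features back to Cartesian frames.

    Angles come from the bond-vector blocks, torsions from the plane normals
    (sign resolved against v_jk); bond lengths and the external block are
    taken from ``reference`` (a single state broadcast over the batch, or one
    state per frame).  Plane-normal blocks are re-normalized before use, so
    decoding is robust to small feature noise.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n_frames = features.shape[0]
    n_place = indexing.n_placed
    if features.shape[1] != 12 * n_place:
        raise ValueError(
            f"feature length {features.shape[1]} != 12*(N-3) = {12 * n_place}")
    blocks = features.reshape(n_frames, n_place, 4, 3)
    n1, n2, v_ij, v_jk = (blocks[:, :, c] for c in range(4))
    for n in (n1, n2):
        nn = _norm(n)
        if np.any(nn < 1e-6):
            raise ValueError("non-normalizable plane-normal block in features")
    n1 = n1 / _norm(n1)[..., None]
    n2 = n2 / _norm(n2)[..., None]
    bij, bjk = _norm(v_ij), _norm(v_jk)
    if np.any(bij < _DEGENERACY_TOL) or np.any(bjk < _DEGENERACY_TOL):
        raise ValueError("zero-length bond-vector block in features")
    cos_a = -np.einsum("...i,...i", v_ij, v_jk) / (bij * bjk)
    angles = np.arccos(np.clip(cos_a, -1.0, 1.0))
    jk_hat = v_jk / bjk[..., None]
    torsions = np.arctan2(
        np.einsum("...i,...i", np.cross(n1, n2), jk_hat),
        np.einsum("...i,...i", n1, n2),
    )
    if reference.n_frames == 1:
        bonds = np.broadcast_to(reference.bonds, (n_frames, n_place))
        root = np.broadcast_to(reference.root_coords, (n_frames, 3, 3))
    elif reference.n_frames == n_frames:
        bonds, root = reference.bonds, reference.root_coords
    else:
        raise ValueError("reference batch size must be 1 or n_frames")
    state = BATState(np.array(root), np.array(bonds), angles, torsions)
    return bat_to_cartesian(state, indexing)


def reference_from_frame(frame, indexing: BATIndexing) -> BATState:
    """Reference geometry (fixed bonds + external block) from one frame."""
    return cartesian_to_bat(np.asarray(frame, dtype=float)[None], indexing)


def save_features(path, features: np.ndarray, topology: MoleculeTopology) -> None:
    """Persist a feature matrix with a topology digest guarding decode misuse."""
    import h5py

    with h5py.File(path, "w") as f:
        ds = f.create_dataset("vbat", data=np.asarray(features))
        ds.attrs["topology_hash"] = topology.hash()


def load_features(path, topology: MoleculeTopology) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        stored = f["vbat"].attrs["topology_hash"]
        if stored != topology.hash():
            raise ValueError("feature file belongs to a different topology")
        return np.asarray(f["vbat"])
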