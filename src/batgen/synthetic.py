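"""Deterministic fixture generators emulating MD-like input.

Real training data for conformational generators comes from long
molecular-dynamics runs; these generators emulate its statistical structure
at desk scale so every stage of the pipeline is testable without downloads:

* a small bonded chain with ideal geometry (:func:`make_toy_molecule`),
* an all-atom peptide with correct PDB atom naming assembled from chemical
  component templates (:func:`make_peptide_fixture`),
* a trajectory whose torsions fluctuate around metastable wells with
  Markov-switching — optionally *concerted* — transitions
  (:func:`simulate_torsion_trajectory`), standing in for the dihedral-driven
  conformational dynamics of a flexible peptide.

Every generator is seeded and bitwise reproducible.  Geometry is ideal
(uniform bonds/angles), which is sufficient because the properties under
test concern transforms, counts and statistics rather than force-field
realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .internal import BATState, bat_to_cartesian, cartesian_to_bat
from .topology import BATIndexing, MoleculeTopology, Trajectory, build_bat_indexing

__all__ = [
    "TorsionStateModel",
    "make_toy_molecule",
    "make_peptide_fixture",
    "pose_contact",
    "simulate_torsion_trajectory",
    "two_state_fixture",
]

_BOND = 1.5          # Å, ideal chain bond
_ANGLE = np.deg2rad(109.5)

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def make_toy_molecule(n_backbone: int, branches=()):
    """A carbon chain with optional single-atom branches, ideal geometry.

    Bonds are 1.5 Å, angles 109.5°, backbone torsions 180° (extended zigzag);
    branch atoms sit at ±60° torsions.  ``branches`` lists the 0-based
    backbone atoms that carry one extra atom each.  Returns (topology, frame).
    """
    if n_backbone < 4:
        raise ValueError("need at least 4 backbone atoms")
    branches = list(branches)
    n = n_backbone + len(branches)
    names = [f"C{i + 1}" for i in range(n_backbone)]
    names += [f"B{i + 1}" for i in range(len(branches))]
    bonds = [(i, i + 1) for i in range(n_backbone - 1)]
    for bi, host in enumerate(branches):
        if not 0 <= host < n_backbone:
            raise ValueError(f"branch host {host} outside backbone")
        bonds.append((host, n_backbone + bi))
    topology = MoleculeTopology(
        names=tuple(names), elements=("C",) * n,
        residue_indices=(0,) * n, residue_names=("LIG",) * n,
        bonds=tuple(bonds),
    )
    indexing = build_bat_indexing(topology)
    n_place = indexing.n_placed
    torsions = np.empty(n_place)
    for p, (i, _, _, _) in enumerate(indexing.placements):
        if i >= n_backbone:  # branch atom: stand off the backbone plane
            torsions[p] = np.deg2rad(60.0 if (i % 2 == 0) else -60.0)
        else:
            torsions[p] = np.pi
    root_coords = _ideal_root()
    state = BATState(root_coords[None], np.full((1, n_place), _BOND),
                     np.full((1, n_place), _ANGLE), torsions[None])
    frame = bat_to_cartesian(state, indexing)[0]
    return topology, frame


def _ideal_root() -> np.ndarray:
    a0 = np.zeros(3)
    a1 = np.array([_BOND, 0.0, 0.0])
    phi = np.pi - _ANGLE
    a2 = a1 + _BOND * np.array([np.cos(phi), np.sin(phi), 0.0])
    return np.stack([a0, a1, a2])


def make_peptide_fixture(sequence: str):
    """All-atom peptide with template geometry and standard atom names.

    Residues come from ideal chemical-component templates, oriented so each
    N→C axis extends the chain, twisted residue-by-residue to avoid clashes,
    and joined by C(n)–N(n+1) peptide bonds of 1.33 Å.  Terminal decorations:
    the first residue keeps its extra amine hydrogen, the last its OXT.
    Returns (topology, frame).
    """
    import biotite.structure.info as info

    if not sequence:
        raise ValueError("empty sequence")
    names, elements, res_idx, res_names = [], [], [], []
    coords, bonds = [], []
    offset = np.zeros(3)
    prev_c_global = None
    n_prev = 0
    for i, letter in enumerate(sequence.upper()):
        if letter not in _AA3:
            raise ValueError(f"unknown amino-acid letter {letter!r}")
        code = _AA3[letter]
        tmpl = info.residue(code)
        keep = np.ones(tmpl.array_length(), dtype=bool)
        drop = {"HXT"}
        if i < len(sequence) - 1:
            drop |= {"OXT"}
        if i > 0:
            drop |= {"H2", "H3"}
        for a, nm in enumerate(tmpl.atom_name):
            if nm in drop:
                keep[a] = False
        sub_idx = np.nonzero(keep)[0]
        local = {int(old): new for new, old in enumerate(sub_idx)}
        xyz = np.asarray(tmpl.coord[sub_idx], dtype=float)
        tnames = list(tmpl.atom_name[sub_idx])
        n_pos = xyz[tnames.index("N")]
        c_pos = xyz[tnames.index("C")]
        xyz = xyz - n_pos
        xyz = _orient(xyz, c_pos - n_pos, twist=np.deg2rad(77.0 * i))
        xyz = xyz + offset
        for a, nm in enumerate(tnames):
            names.append(nm)
            elements.append(str(tmpl.element[sub_idx[a]]).capitalize())
            res_idx.append(i)
            res_names.append(code)
        coords.append(xyz)
        for a, b, _ in tmpl.bonds.as_array():
            if keep[a] and keep[b]:
                bonds.append((n_prev + local[int(a)], n_prev + local[int(b)]))
        if prev_c_global is not None:
            bonds.append((prev_c_global, n_prev + tnames.index("N")))
        prev_c_global = n_prev + tnames.index("C")
        offset = xyz[tnames.index("C")] + np.array([1.33, 0.0, 0.0])
        n_prev += len(tnames)
    topology = MoleculeTopology(
        names=tuple(names), elements=tuple(elements),
        residue_indices=tuple(res_idx), residue_names=tuple(res_names),
        bonds=tuple(bonds),
    )
    return topology, np.concatenate(coords, axis=0)


def _orient(xyz: np.ndarray, axis: np.ndarray, twist: float) -> np.ndarray:
    """Rotate coordinates so ``axis`` maps to +x, then twist about x."""
    a = axis / np.linalg.norm(axis)
    target = np.array([1.0, 0.0, 0.0])
    v = np.cross(a, target)
    c = float(a @ target)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    ct, st = np.cos(twist), np.sin(twist)
    rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    return xyz @ (rx @ rot).T


def pose_contact(frame: np.ndarray, topology: MoleculeTopology,
                 atom_a: tuple, atom_b: tuple, distance: float) -> np.ndarray:
    """Move one atom along the line to another so they sit ``distance`` apart.

    ``atom_a``/``atom_b`` are (residue index, atom name); atom_b moves.  Used
    to pose synthetic contacts (e.g. a carboxylate–amine salt bridge) without
    re-deriving sidechain torsions; neighbouring bond lengths are distorted,
    which posed fixtures tolerate.
    """
    def find(res, name):
        for idx, (ri, nm) in enumerate(zip(topology.residue_indices,
                                           topology.names)):
            if ri == res and nm == name:
                return idx
        raise ValueError(f"atom {name} of residue {res} not found")

    ia, ib = find(*atom_a), find(*atom_b)
    out = np.array(frame, dtype=float)
    direction = out[ib] - out[ia]
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        direction, norm = np.array([1.0, 0.0, 0.0]), 1.0
    out[ib] = out[ia] + direction / norm * distance
    return out


@dataclass
class TorsionStateModel:
    """Metastable-well model of torsion dynamics.

    ``wells`` maps a placement-order torsion index to its list of
    (mean, std) wells in radians.  Torsions without wells jitter around
    their base value with ``default_std``.  Each frame, a well-occupying
    torsion switches to a different well with probability ``switch_prob``;
    torsion groups listed in ``concerted`` share one Markov state and switch
    jointly.
    """

    wells: dict = field(default_factory=dict)
    switch_prob: float = 0.01
    concerted: tuple = ()
    default_std: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch probability must be in [0, 1]")
        for t, ws in self.wells.items():
            if any(std <= 0 for _, std in ws):
                raise ValueError(f"non-positive well std for torsion {t}")
        grouped = [t for grp in self.concerted for t in grp]
        if len(grouped) != len(set(grouped)):
            raise ValueError("torsion listed in two concerted groups")


def simulate_torsion_trajectory(topology: MoleculeTopology, frame: np.ndarray,
                                model: TorsionStateModel, n_frames: int,
                                indexing: BATIndexing | None = None) -> Trajectory:
    """Markov-switching torsion dynamics around a base conformation.

    Bond lengths, angles and the external block are held at the base frame's
    values; each torsion follows its well model.  Fixed seed ⇒ bitwise
    reproducible coordinates.
    """
    indexing = indexing or build_bat_indexing(topology)
    base = cartesian_to_bat(frame, indexing)
    n_place = indexing.n_placed
    rng = np.random.default_rng(model.seed)
    torsions = np.tile(base.torsions[0], (n_frames, 1))
    torsions += rng.normal(0.0, model.default_std, size=torsions.shape)
    groups = list(model.concerted)
    singles = [t for t in model.wells
               if not any(t in grp for grp in groups)]
    groups += [(t,) for t in singles]
    for grp in groups:
        n_wells = len(model.wells[grp[0]])
        if any(len(model.wells[t]) != n_wells for t in grp):
            raise ValueError("concerted torsions must share a well count")
        state = int(rng.integers(n_wells))
        states = np.empty(n_frames, dtype=int)
        for f in range(n_frames):
            if rng.random() < model.switch_prob and n_wells > 1:
                others = [w for w in range(n_wells) if w != state]
                state = others[int(rng.integers(len(others)))]
            states[f] = state
        for t in grp:
            means = np.array([m for m, _ in model.wells[t]])
            stds = np.array([s for _, s in model.wells[t]])
            torsions[:, t] = (means[states]
                              + rng.normal(0.0, 1.0, n_frames) * stds[states])
    torsions = (torsions + np.pi) % (2 * np.pi) - np.pi
    state_batch = BATState(
        np.broadcast_to(base.root_coords, (n_frames, 3, 3)).copy(),
        np.broadcast_to(base.bonds, (n_frames, n_place)).copy(),
        np.broadcast_to(base.angles, (n_frames, n_place)).copy(),
        torsions,
    )
    return Trajectory(bat_to_cartesian(state_batch, indexing), topology)


def two_state_fixture(n_backbone: int = 22, branches=(3, 9, 15),
                      n_frames: int = 1000, switch_prob: float = 0.01,
                      seed: int = 0):
    """The canonical end-to-end dataset: a toy chain whose middle torsion
    pair hops concertedly between wells at ±60°.

    Returns (topology, frame, indexing, trajectory, model).  The concerted
    pair dominates the ensemble variance (wells 120° apart, 5° in-well
    noise, 3° jitter elsewhere), emulating a molecule with two metastable
    conformers bridged by a concerted dihedral rotation.
    """
    branches = tuple(b for b in branches if b < n_backbone)
    topology, frame = make_toy_molecule(n_backbone, branches)
    indexing = build_bat_indexing(topology)
    mid = indexing.n_placed // 2
    pair = (mid, mid + 1)
    wells = {t: [(np.deg2rad(60.0), np.deg2rad(5.0)),
                 (np.deg2rad(-60.0), np.deg2rad(5.0))] for t in pair}
    model = TorsionStateModel(wells=wells, switch_prob=switch_prob,
                              concerted=(pair,), default_std=np.deg2rad(3.0),
                              seed=seed)
    traj = simulate_torsion_trajectory(topology, frame, model, n_frames,
                                       indexing)
    return topology, frame, indexing, traj, model
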