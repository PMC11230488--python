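"""Molecular topology, trajectories, and the bond-angle-torsion construction order.

A molecule is represented by a :class:`MoleculeTopology` (atoms + bond graph)
and an ordered stack of Cartesian frames (:class:`Trajectory`, Å).  The
internal-coordinate machinery needs a *construction order*: three sequentially
bonded root atoms carrying the six external degrees of freedom, followed by
one (bond, angle, torsion) placement per remaining atom.  That order is the
:class:`BATIndexing`.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MoleculeTopology",
    "BATIndexing",
    "Trajectory",
    "build_bat_indexing",
    "validate_indexing",
    "read_structure",
    "write_structure",
    "read_dcd",
    "write_dcd",
    "stride_split",
]

# Atomic masses (amu) for the elements fixtures and peptides use.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

# Sidechain / terminal atoms that carry a formal charge at neutral pH.
_POSITIVE_ATOMS = {
    ("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
}
_NEGATIVE_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


def _charge_class(res_name: str, atom_name: str) -> str:
    if (res_name, atom_name) in _POSITIVE_ATOMS:
        return "positive"
    if (res_name, atom_name) in _NEGATIVE_ATOMS or atom_name == "OXT":
        return "negative"
    return "neutral"


@dataclass(frozen=True)
class MoleculeTopology:
    """Atoms, bonds and residue bookkeeping for a single bonded molecule.

    Parameters
    ----------
    names, elements : per-atom identifiers (PDB atom name, element symbol)
    residue_indices : 0-based residue index per atom
    residue_names : 3-letter residue code per atom
    bonds : (n_bonds, 2) array of 0-based atom index pairs
    """

    names: tuple
    elements: tuple
    residue_indices: tuple
    residue_names: tuple
    bonds: tuple

    def __post_init__(self):
        n = self.n_atoms
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"bond ({a},{b}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def adjacency(self) -> dict:
        adj: dict = {i: [] for i in range(self.n_atoms)}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return {k: sorted(v) for k, v in adj.items()}

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e.upper(), 12.011) for e in self.elements])

    @property
    def charge_classes(self) -> tuple:
        return tuple(
            _charge_class(r, a) for r, a in zip(self.residue_names, self.names)
        )

    def heavy_atoms(self) -> np.ndarray:
        """Indices of non-hydrogen atoms."""
        return np.array([i for i, e in enumerate(self.elements) if e.upper() != "H"],
                        dtype=int)

    def backbone_atoms(self) -> np.ndarray:
        """Indices of protein backbone atoms N, CA, C, O."""
        return np.array([i for i, nm in enumerate(self.names)
                         if nm in ("N", "CA", "C", "O")], dtype=int)

    def alpha_carbons(self) -> np.ndarray:
        """One CA index per residue, in residue order; error if any is missing."""
        per_res: dict = {}
        for i, (nm, ri) in enumerate(zip(self.names, self.residue_indices)):
            if nm == "CA":
                per_res[ri] = i
        res_ids = sorted(set(self.residue_indices))
        missing = [r for r in res_ids if r not in per_res]
        if missing:
            raise ValueError(f"residues without a CA atom: {missing}")
        return np.array([per_res[r] for r in res_ids], dtype=int)

    def connected_components(self) -> list:
        seen = set()
        comps = []
        adj = self.adjacency
        for start in range(self.n_atoms):
            if start in seen:
                continue
            comp, stack = [], [start]
            seen.add(start)
            while stack:
                a = stack.pop()
                comp.append(a)
                for b in adj[a]:
                    if b not in seen:
                        seen.add(b)
                        stack.append(b)
            comps.append(sorted(comp))
        return comps

    def hash(self) -> str:
        """Stable digest of atoms + bonds, used to guard cross-topology decoding."""
        h = hashlib.md5()
        h.update(",".join(self.names).encode())
        h.update(",".join(self.elements).encode())
        h.update(",".join(map(str, self.residue_indices)).encode())
        h.update(",".join(f"{a}-{b}" for a, b in sorted(map(tuple, map(sorted, self.bonds)))).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class BATIndexing:
    """Construction order for the internal-coordinate transform.

    ``root`` holds three sequentially bonded atoms placed first; ``placements``
    is an (N-3, 4) integer array of quadruples (i, j, k, l): atom i is placed
    from its bond to j, the angle i-j-k and the torsion about j-k measured
    against l.  For atoms whose anchor j is the middle root atom, (k, l) span
    the two outer root atoms and the torsion is an improper (k and l are not
    bonded); ``improper`` flags those rows.
    """

    root: tuple
    placements: tuple
    improper: tuple

    @property
    def placement_array(self) -> np.ndarray:
        return np.array(self.placements, dtype=int)

    @property
    def n_placed(self) -> int:
        return len(self.placements)


def build_bat_indexing(topology: MoleculeTopology, root=None) -> BATIndexing:
    """Choose root atoms and a deterministic placement order over the bond graph.

    The default root is the lowest-index terminal heavy atom, its bonded
    neighbour, and that neighbour's lowest-index remaining heavy neighbour.
    Remaining atoms are placed lowest-index-first among atoms adjacent to the
    already-placed set; each atom i anchors to its lowest-index placed
    neighbour j, and inherits (k, l) from j's own reference chain so the four
    atoms are bonded in sequence wherever the graph allows it.
    """
    n = topology.n_atoms
    if n < 4:
        raise ValueError(f"BAT construction needs at least 4 atoms, got {n}")
    comps = topology.connected_components()
    if len(comps) > 1:
        raise ValueError(
            f"bond graph is disconnected; orphan component atoms: {comps[1]}"
        )
    adj = topology.adjacency

    if root is None:
        root = _default_root(topology, adj)
    r0, r1, r2 = root
    if r1 not in adj[r0] or r2 not in adj[r1]:
        raise ValueError(f"root atoms {root} are not bonded in a chain")

    # Reference chain per placed atom: for a later atom anchored at j, the
    # quadruple is (i, j, *chain[j]).  The middle root's chain is improper.
    chain = {r0: (r1, r2), r1: (r0, r2), r2: (r1, r0)}
    placed = {r0, r1, r2}
    frontier = []  # min-heap of candidate atoms adjacent to the placed set
    for r in (r0, r1, r2):
        for b in adj[r]:
            if b not in placed:
                heapq.heappush(frontier, b)
    placements, improper = [], []
    in_frontier = set(frontier)
    while frontier:
        i = heapq.heappop(frontier)
        in_frontier.discard(i)
        if i in placed:
            continue
        j = min(b for b in adj[i] if b in placed)
        k, l = chain[j]
        placements.append((i, j, k, l))
        improper.append(l not in adj[k])
        chain[i] = (j, k)
        placed.add(i)
        for b in adj[i]:
            if b not in placed and b not in in_frontier:
                heapq.heappush(frontier, b)
                in_frontier.add(b)
    assert len(placements) == n - 3
    return BATIndexing(root=tuple(root), placements=tuple(placements),
                       improper=tuple(improper))


def _default_root(topology: MoleculeTopology, adj: dict):
    heavy = set(topology.heavy_atoms().tolist())
    # terminal heavy atoms first, then any terminal atom, then any atom
    candidates = sorted(
        range(topology.n_atoms),
        key=lambda a: (a not in heavy, len(adj[a]) != 1, a),
    )
    for r0 in candidates:
        for r1 in adj[r0]:
            nxt = [c for c in adj[r1] if c != r0]
            nxt.sort(key=lambda c: (c not in heavy, c))
            for r2 in nxt:
                return (r0, r1, r2)
    raise ValueError("no bonded chain of three atoms found")


def validate_indexing(topology: MoleculeTopology, indexing: BATIndexing) -> None:
    """Re-check all construction-order invariants; raise on any violation."""
    n = topology.n_atoms
    adj = topology.adjacency
    r0, r1, r2 = indexing.root
    if r1 not in adj[r0] or r2 not in adj[r1]:
        raise AssertionError("root atoms not bonded in a chain")
    if len(indexing.placements) != n - 3:
        raise AssertionError("placement list length != N-3")
    placed = {r0, r1, r2}
    seen = set()
    for (i, j, k, l), imp in zip(indexing.placements, indexing.improper):
        if i in seen or i in placed:
            raise AssertionError(f"atom {i} placed twice")
        for ref in (j, k, l):
            if ref not in placed:
                raise AssertionError(f"reference atom {ref} not yet placed for {i}")
        if j not in adj[i]:
            raise AssertionError(f"anchor {j} not bonded to placed atom {i}")
        if k not in adj[j]:
            raise AssertionError(f"reference chain {j}-{k} not bonded")
        if not imp and l not in adj[k]:
            raise AssertionError(f"reference chain {k}-{l} not bonded")
        seen.add(i)
        placed.add(i)
    if placed != set(range(n)):
        raise AssertionError("not every atom placed")


@dataclass
class Trajectory:
    """Ordered Cartesian frames (n_frames, N, 3) in Å over one topology."""

    coords: np.ndarray
    topology: MoleculeTopology
    time_per_frame: float = 1.0  # ps between stored frames

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def subset(self, frame_indices) -> "Trajectory":
        return Trajectory(self.coords[np.asarray(frame_indices, dtype=int)],
                          self.topology, self.time_per_frame)


# ---------------------------------------------------------------------------
# File I/O: multi-model PDB via biotite; DCD as the binary trajectory format.
# ---------------------------------------------------------------------------

def _to_atom_array_stack(topology: MoleculeTopology, trajectory: Trajectory):
    import biotite.structure as struc

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.atom_name = np.array(topology.names)
    arr.element = np.array([e.upper() for e in topology.elements])
    arr.res_id = np.array(topology.residue_indices) + 1
    arr.res_name = np.array(topology.residue_names)
    arr.chain_id = np.array(["A"] * n)
    standard = set("ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE"
                   " PRO SER THR TRP TYR VAL".split())
    arr.hetero = np.array([rn not in standard for rn in topology.residue_names])
    stack = struc.stack([arr] * trajectory.n_frames)
    stack.coord = np.asarray(trajectory.coords, dtype=np.float32)
    bond_arr = np.array([[a, b, 1] for a, b in topology.bonds], dtype=np.uint32)
    stack.bonds = struc.BondList(n, bond_arr)
    return stack


def write_structure(path, topology: MoleculeTopology, trajectory: Trajectory) -> None:
    """Write a multi-model PDB with MODEL/ENDMDL blocks and CONECT records."""
    from biotite.structure.io.pdb import PDBFile

    if trajectory.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(topology, trajectory))
    pdb.write(str(path))


def read_structure(path):
    """Read a multi-model PDB into a topology and trajectory.

    Atom order follows the file; each MODEL becomes a frame.  Bonds come from
    CONECT records when present, otherwise from amino-acid residue templates
    plus inter-residue peptide bonds.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged models
        raise ValueError(f"models differ in atom count or are malformed: {exc}")
    # honor CONECT records verbatim when present; otherwise fall back to
    # residue templates + peptide bonds via biotite
    conect = set()
    for line in pdb.lines:
        if line.startswith("CONECT"):
            fields = [line[s:s + 5] for s in range(6, 27, 5)]
            serials = [int(f) for f in fields if f.strip()]
            for partner in serials[1:]:
                conect.add((min(serials[0], partner) - 1,
                            max(serials[0], partner) - 1))
    if conect:
        bond_pairs = sorted(conect)
    else:
        bond_pairs = [tuple(sorted((int(a), int(b))))
                      for a, b, _ in
                      struc.connect_via_residue_names(stack[0]).as_array()]
    res_ids = stack.res_id
    # compact residue ids to 0-based indices preserving order of appearance
    _, res_index = np.unique(res_ids, return_inverse=True)
    topology = MoleculeTopology(
        names=tuple(stack.atom_name),
        elements=tuple(str(e).capitalize() for e in stack.element),
        residue_indices=tuple(int(r) for r in res_index),
        residue_names=tuple(stack.res_name),
        bonds=tuple((int(a), int(b)) for a, b in bond_pairs),
    )
    traj = Trajectory(np.asarray(stack.coord, dtype=float), topology)
    return topology, traj


def write_dcd(path, trajectory: Trajectory) -> None:
    """Write frames to a DCD file (CHARMM/NAMD layout, float32 Å)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path), "w") as f:
        f.write(np.asarray(trajectory.coords, dtype=np.float32))


def read_dcd(path, topology: MoleculeTopology) -> Trajectory:
    """Read a DCD file; the topology supplies atom metadata."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(str(path)) as f:
        xyz, _, _ = f.read()
    return Trajectory(np.asarray(xyz, dtype=float), topology)


def stride_split(traj: Trajectory, train_stride: int, offset_train: int = 0,
                 offset_valid: int | None = None):
    """Split a trajectory into training/validation sets by regular resaving.

    Training frames are ``offset_train, offset_train+stride, ...``; validation
    frames likewise from ``offset_valid`` (default: half a stride later, the
    usual interleaved split).  The two sets are disjoint whenever the offsets
    differ modulo the stride.
    """
    if train_stride < 1:
        raise ValueError("stride must be >= 1")
    if offset_valid is None:
        offset_valid = offset_train + train_stride // 2
    n = traj.n_frames
    if offset_train >= n or offset_valid >= n:
        raise ValueError("offset beyond trajectory length")
    train_idx = np.arange(offset_train, n, train_stride)
    valid_idx = np.arange(offset_valid, n, train_stride)
    if len(train_idx) == 0 or len(valid_idx) == 0:
        raise ValueError("stride split produced an empty set")
    train = traj.subset(train_idx)
    valid = traj.subset(valid_idx)
    train.time_per_frame = traj.time_per_frame * train_stride
    valid.time_per_frame = traj.time_per_frame * train_stride
    return train, valid
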