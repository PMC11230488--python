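"""Ensemble characterization: dihedral PCA, free-energy surfaces, contacts,
turns and salt bridges.

dPCA maps each torsion θ to the unit-circle pair (cos θ, sin θ) before
computing the covariance, so correlations are estimated without the ±180°
discontinuity.  Free-energy surfaces are 2D histograms over (Rg, backbone
RMSD) converted via F = -k_B·T·ln P.  Contact maps, turn states and salt
bridges follow the usual Cα- and sidechain-distance conventions for
disordered-peptide ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import rmsd_one_to_many
from .internal import cartesian_to_bat
from .topology import BATIndexing, Trajectory

__all__ = [
    "DPCAResult",
    "FreeEnergySurface",
    "TurnDefinitions",
    "BOLTZMANN_KCAL",
    "dihedral_pca",
    "trajectory_torsions",
    "radius_of_gyration",
    "free_energy_surface",
    "contact_map",
    "classify_turns",
    "detect_salt_bridges",
]

BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol·K)


@dataclass
class DPCAResult:
    mean: np.ndarray          # mean of the sin/cos matrix (2·n_torsions,)
    eigenvalues: np.ndarray   # descending, non-negative
    eigenvectors: np.ndarray  # columns, orthonormal
    projections: np.ndarray   # (n_frames, 2·n_torsions)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def dihedral_pca(torsions: np.ndarray) -> DPCAResult:
    """PCA of torsions on the unit circle.

    ``torsions`` is (n_frames, n_torsions) in radians.  Column layout of the
    transformed space is [cos θ_1, sin θ_1, cos θ_2, sin θ_2, ...], so a
    torsion t occupies columns (2t, 2t+1).
    """
    torsions = np.atleast_2d(np.asarray(torsions, dtype=float))
    n_frames, n_t = torsions.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    circ = np.empty((n_frames, 2 * n_t))
    circ[:, 0::2] = np.cos(torsions)
    circ[:, 1::2] = np.sin(torsions)
    mean = circ.mean(axis=0)
    centered = circ - mean
    cov = centered.T @ centered / (n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    return DPCAResult(mean, evals, evecs, centered @ evecs)


def trajectory_torsions(traj: Trajectory, indexing: BATIndexing) -> np.ndarray:
    """All construction-order torsions of a trajectory, (n_frames, N-3)."""
    return cartesian_to_bat(traj.coords, indexing).torsions


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray,
                       selection: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (Å) over a selection (default: all)."""
    frame = np.asarray(frame, dtype=float)
    if selection is not None:
        selection = np.asarray(selection, dtype=int)
        if selection.size == 0:
            raise ValueError("empty selection")
        frame = frame[selection]
        masses = np.asarray(masses, dtype=float)[selection]
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * frame).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((frame - com) ** 2).sum(axis=1)).sum() / m.sum()))


@dataclass
class FreeEnergySurface:
    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    population: np.ndarray  # normalized over occupied bins
    free_energy: np.ndarray  # kcal/mol, NaN where unoccupied
    temperature: float


def free_energy_surface(traj: Trajectory, reference_frame: np.ndarray,
                        bins: int = 30, temperature: float = 298.0,
                        selection: str = "heavy") -> FreeEnergySurface:
    """Free-energy surface over (Rg, backbone RMSD to a reference).

    P is the normalized 2D histogram population; F = -k_B·T·ln P with empty
    bins masked as NaN, so only free-energy *differences* are meaningful.
    """
    top = traj.topology
    masses = top.masses
    heavy = top.heavy_atoms() if selection == "heavy" else np.arange(top.n_atoms)
    rg = np.array([radius_of_gyration(f, masses, heavy) for f in traj.coords])
    backbone = top.backbone_atoms()
    if backbone.size == 0:
        backbone = heavy
    ref = np.asarray(reference_frame, dtype=float)[backbone]
    rms = rmsd_one_to_many(ref, traj.coords[:, backbone])
    hist, rg_edges, rmsd_edges = np.histogram2d(rg, rms, bins=bins)
    pop = hist / hist.sum()
    with np.errstate(divide="ignore"):
        f = -BOLTZMANN_KCAL * temperature * np.log(pop)
    f[pop == 0] = np.nan
    return FreeEnergySurface(rg_edges, rmsd_edges, pop, f, temperature)


def contact_map(traj: Trajectory, cutoff: float = 6.5,
                exclusion_window: int = 4) -> np.ndarray:
    """Residue-pair Cα contact probabilities.

    A contact exists in a frame iff the Cα–Cα distance is below ``cutoff``
    (Å); near-diagonal pairs with |i-j| < exclusion_window are zeroed.
    Returns a symmetric (n_res, n_res) matrix of frame-averaged contact
    probabilities in [0, 1].
    """
    ca = traj.topology.alpha_carbons()
    pos = traj.coords[:, ca]  # (frames, n_res, 3)
    d = np.linalg.norm(pos[:, :, None] - pos[:, None, :], axis=-1)
    contacts = (d < cutoff).astype(float)
    n_res = ca.size
    i, j = np.meshgrid(np.arange(n_res), np.arange(n_res), indexing="ij")
    contacts[:, np.abs(i - j) < exclusion_window] = 0.0
    return contacts.mean(axis=0)


@dataclass
class TurnDefinitions:
    """Named turn regions with the Cα probe pairs used to score them.

    Defaults are the four turns of the 42-residue amyloid-β monomer, probed
    by residue pairs flanking each turn; residue numbers are 1-based.
    """

    turns: dict = field(default_factory=lambda: {
        "A": ((4, 6), (2, 7)),    # turn F4-H6, probe Ala2:Asp7
        "B": ((11, 14), (10, 15)),  # turn E11-H14, probe Tyr10:Gly15
        "C": ((26, 28), (24, 29)),  # turn S26-K28, probe Val24:Gln29
        "D": ((36, 38), (33, 40)),  # turn V36-G38, probe Gly33:Val40
    })
    formed_cutoff: float = 6.5    # Å; probe distance below => formed
    not_formed_cutoff: float = 9.0  # Å; probe distance above => not formed

    def __post_init__(self):
        if self.formed_cutoff >= self.not_formed_cutoff:
            raise ValueError("formed cutoff must be below not-formed cutoff")


def classify_turns(traj: Trajectory, defs: TurnDefinitions | None = None) -> dict:
    """Per-frame turn states: 'formed', 'not-formed' or 'ambiguous'.

    Returns {turn name: array of states over frames}.  The band between the
    two cutoffs is left unlabeled as 'ambiguous'.
    """
    defs = defs or TurnDefinitions()
    ca = traj.topology.alpha_carbons()
    n_res = ca.size
    out = {}
    for name, (_, (ra, rb)) in defs.turns.items():
        if not (1 <= ra <= n_res and 1 <= rb <= n_res):
            raise ValueError(
                f"turn {name} probes residues {ra},{rb} but the molecule has "
                f"{n_res} residues")
        d = np.linalg.norm(traj.coords[:, ca[ra - 1]] - traj.coords[:, ca[rb - 1]],
                           axis=-1)
        states = np.full(traj.n_frames, "ambiguous", dtype=object)
        states[d < defs.formed_cutoff] = "formed"
        states[d > defs.not_formed_cutoff] = "not-formed"
        out[name] = states
    return out


_CATION_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def detect_salt_bridges(traj: Trajectory, cutoff: float = 4.0) -> list:
    """Opposite-charge sidechain N–O contacts and their occupancies.

    A salt bridge between two residues exists in a frame iff any cationic
    sidechain nitrogen of one is within ``cutoff`` Å of any anionic
    carboxylate oxygen of the other.  Returns
    [((res_i, res_j), occupancy), ...] sorted by residue pair, where
    occupancy is the fraction of frames with the contact and res indices are
    0-based.
    """
    top = traj.topology
    cations: dict = {}
    anions: dict = {}
    for idx, (rn, an, ri) in enumerate(zip(top.residue_names, top.names,
                                           top.residue_indices)):
        if (rn, an) in _CATION_ATOMS:
            cations.setdefault(ri, []).append(idx)
        if (rn, an) in _ANION_ATOMS or an == "OXT":
            anions.setdefault(ri, []).append(idx)
    results = []
    for ri, n_atoms in sorted(cations.items()):
        for rj, o_atoms in sorted(anions.items()):
            if ri == rj:
                continue
            d = np.linalg.norm(
                traj.coords[:, n_atoms][:, :, None]
                - traj.coords[:, o_atoms][:, None, :], axis=-1)
            present = (d < cutoff).any(axis=(1, 2))
            occ = float(present.mean())
            if occ > 0:
                results.append(((min(ri, rj), max(ri, rj)), occ))
    return sorted(results)
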