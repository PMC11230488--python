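"""Candidate filtering: energy screen, duplicate removal, novelty check.

Generated conformations pass through three screens, mirroring the way raw
interpolants are turned into a usable synthetic ensemble:

1. *Energy*: each candidate is briefly minimized under an energy model and
   discarded if its minimized energy exceeds a cutoff.  The energy model is a
   pluggable contract; the default :class:`StandinEnergyModel` is a simplified
   molecular-mechanics surface (harmonic bonds/angles restrained to a
   reference geometry, Lennard-Jones with element radii, Coulomb between
   formally charged atoms with a distance-dependent dielectric).  Because its
   absolute scale is not that of a physics force field, its cutoff is best
   chosen as a high percentile of the reference ensemble's own minimized
   energies (:func:`percentile_cutoff`) rather than an absolute number.
2. *Deduplication*: a sequential scan keeps a candidate only if its minimal
   heavy-atom RMSD (after optimal Kabsch superposition) to every previously
   kept candidate exceeds a cutoff (default 1.0 Å).
3. *Novelty*: candidates within an RMSD cutoff of any reference-ensemble
   frame are discarded as already-sampled.

Survivor counts are monotonically non-increasing across the steps and are
recorded in a :class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import MoleculeTopology, Trajectory

__all__ = [
    "FilterReport",
    "StandinEnergyModel",
    "rmsd",
    "rmsd_one_to_many",
    "percentile_cutoff",
    "energy_filter",
    "greedy_dedup",
    "novelty_filter",
    "run_filter_pipeline",
]

COULOMB_CONST = 332.0636  # kcal·Å/(mol·e²)

# Lennard-Jones minimum distances (Å) and well depths (kcal/mol) by element
_LJ_RMIN = {"H": 1.2, "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0}
_LJ_EPS = {"H": 0.02, "C": 0.09, "N": 0.17, "O": 0.21, "S": 0.25}


# ---------------------------------------------------------------------------
# RMSD with optimal superposition (Kabsch), batched over the second argument.
# ---------------------------------------------------------------------------

def rmsd_one_to_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Minimal RMSD of conformation x (A, 3) to each of ys (m, A, 3)."""
    x = np.asarray(x, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if ys.ndim == 2:
        ys = ys[None]
    a = x.shape[0]
    xc = x - x.mean(axis=0)
    yc = ys - ys.mean(axis=1, keepdims=True)
    cov = np.einsum("maj,ai->mij", yc, xc)  # cov[m] = xcᵀ·yc[m]
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    u[:, :, -1] *= d[:, None]
    rot = u @ vt  # optimal rotation taking yc onto xc
    aligned = np.einsum("mij,maj->mai", rot, yc)
    return np.sqrt(((aligned - xc) ** 2).sum(axis=(1, 2)) / a)


def rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal (superposed) RMSD between two conformations."""
    return float(rmsd_one_to_many(x, y[None])[0])


# ---------------------------------------------------------------------------
# Stand-in energy model
# ---------------------------------------------------------------------------

class StandinEnergyModel:
    """Simplified molecular-mechanics energy over one topology.

    Terms: harmonic bonds and angles restrained to a reference conformation's
    geometry, a 12-6 Lennard-Jones potential between atoms separated by three
    or more bonds, and Coulomb interactions between formally charged atoms
    screened by a distance-dependent dielectric ε(r) = 4r.  ``evaluate`` is
    deterministic and batched; ``minimize`` is a backtracking steepest
    descent whose energy never increases.
    """

    def __init__(self, topology: MoleculeTopology, reference_frame: np.ndarray,
                 k_bond: float = 300.0, k_angle: float = 50.0):
        self.topology = topology
        ref = np.asarray(reference_frame, dtype=float)
        self.k_bond, self.k_angle = k_bond, k_angle
        self._bonds = np.array([sorted(b) for b in topology.bonds], dtype=int)
        d = ref[self._bonds[:, 0]] - ref[self._bonds[:, 1]]
        self._b0 = np.linalg.norm(d, axis=1)
        adj = topology.adjacency
        triples = []
        for j in range(topology.n_atoms):
            nb = adj[j]
            for ai in range(len(nb)):
                for bi in range(ai + 1, len(nb)):
                    triples.append((nb[ai], j, nb[bi]))
        self._angles = np.array(triples, dtype=int).reshape(-1, 3)
        if len(self._angles):
            self._a0 = self._angle_values(ref[None], self._angles)[0]
        else:
            self._a0 = np.zeros(0)
        self._nb_pairs = self._nonbonded_pairs(adj)
        elems = [e.upper() for e in topology.elements]
        rmin = np.array([_LJ_RMIN.get(e, 1.9) for e in elems])
        eps = np.array([_LJ_EPS.get(e, 0.1) for e in elems])
        i, j = self._nb_pairs.T if len(self._nb_pairs) else (np.array([], int),) * 2
        self._lj_rmin = 0.5 * (rmin[i] + rmin[j]) * 2 ** (1 / 6) if len(i) else np.zeros(0)
        self._lj_eps = np.sqrt(eps[i] * eps[j]) if len(i) else np.zeros(0)
        charge = {"positive": 1.0, "negative": -1.0, "neutral": 0.0}
        q = np.array([charge[c] for c in topology.charge_classes])
        self._qq = q[i] * q[j] if len(i) else np.zeros(0)
        # dense scatter (incidence) matrices make the gradient a handful of
        # matmuls instead of slow indexed adds; fall back for large systems
        n = topology.n_atoms
        self._dense_scatter = n * max(len(self._nb_pairs), 1) <= 5_000_000
        if self._dense_scatter:
            def scatter(idx):
                s = np.zeros((n, len(idx)))
                s[idx, np.arange(len(idx))] = 1.0
                return s
            self._s_bond = (scatter(self._bonds[:, 0])
                            - scatter(self._bonds[:, 1]))
            if len(self._angles):
                self._s_ang = tuple(scatter(self._angles[:, c]) for c in range(3))
            if len(self._nb_pairs):
                self._s_nb = (scatter(self._nb_pairs[:, 0])
                              - scatter(self._nb_pairs[:, 1]))

    def _nonbonded_pairs(self, adj):
        n = self.topology.n_atoms
        # exclude pairs separated by fewer than 3 bonds (1-2 and 1-3)
        excl = {frozenset(b) for b in map(tuple, self._bonds)}
        for a, j, c in self._angles:
            excl.add(frozenset((int(a), int(c))))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if frozenset((i, j)) not in excl]
        return np.array(pairs, dtype=int).reshape(-1, 2)

    @staticmethod
    def _angle_values(coords, triples):
        u = coords[:, triples[:, 0]] - coords[:, triples[:, 1]]
        v = coords[:, triples[:, 2]] - coords[:, triples[:, 1]]
        cu = np.linalg.norm(u, axis=-1)
        cv = np.linalg.norm(v, axis=-1)
        cos = np.einsum("...i,...i", u, v) / (cu * cv)
        return np.arccos(np.clip(cos, -1.0, 1.0))

    def evaluate(self, coords: np.ndarray):
        """Total energy (kcal/mol) and per-term decomposition, batched."""
        coords, squeeze = self._promote(coords)
        terms = {}
        bd = coords[:, self._bonds[:, 0]] - coords[:, self._bonds[:, 1]]
        r = np.linalg.norm(bd, axis=-1)
        terms["bond"] = (self.k_bond * (r - self._b0) ** 2).sum(axis=1)
        if len(self._angles):
            ang = self._angle_values(coords, self._angles)
            terms["angle"] = (self.k_angle * (ang - self._a0) ** 2).sum(axis=1)
        else:
            terms["angle"] = np.zeros(coords.shape[0])
        if len(self._nb_pairs):
            d = coords[:, self._nb_pairs[:, 0]] - coords[:, self._nb_pairs[:, 1]]
            rr = np.linalg.norm(d, axis=-1)
            rr = np.maximum(rr, 1e-3)
            sr6 = (self._lj_rmin / rr) ** 6
            terms["lj"] = (self._lj_eps * (sr6 * sr6 - 2.0 * sr6)).sum(axis=1)
            terms["coulomb"] = (COULOMB_CONST * self._qq / (4.0 * rr * rr)).sum(axis=1)
        else:
            terms["lj"] = terms["coulomb"] = np.zeros(coords.shape[0])
        total = sum(terms.values())
        if squeeze:
            return float(total[0]), {k: float(v[0]) for k, v in terms.items()}
        return total, terms

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords, squeeze = self._promote(coords)
        g = np.zeros_like(coords)
        i, j = self._bonds[:, 0], self._bonds[:, 1]
        d = coords[:, i] - coords[:, j]
        r = np.linalg.norm(d, axis=-1, keepdims=True)
        f = 2.0 * self.k_bond * (r - self._b0[:, None]) * d / r
        if self._dense_scatter:
            g += np.matmul(self._s_bond, f)
        else:
            np.add.at(g, (slice(None), i), f)
            np.add.at(g, (slice(None), j), -f)
        if len(self._angles):
            a, c, b = self._angles[:, 0], self._angles[:, 1], self._angles[:, 2]
            u = coords[:, a] - coords[:, c]
            v = coords[:, b] - coords[:, c]
            nu = np.linalg.norm(u, axis=-1, keepdims=True)
            nv = np.linalg.norm(v, axis=-1, keepdims=True)
            uh, vh = u / nu, v / nv
            cos = np.einsum("...i,...i", uh, vh)[..., None]
            sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
            theta = np.arccos(np.clip(cos, -1.0, 1.0))
            pref = 2.0 * self.k_angle * (theta - self._a0[:, None])
            da = pref * (cos * uh - vh) / (nu * sin)
            db = pref * (cos * vh - uh) / (nv * sin)
            if self._dense_scatter:
                sa, sc, sb = self._s_ang
                g += np.matmul(sa, da) + np.matmul(sb, db) - np.matmul(sc, da + db)
            else:
                np.add.at(g, (slice(None), a), da)
                np.add.at(g, (slice(None), b), db)
                np.add.at(g, (slice(None), c), -(da + db))
        if len(self._nb_pairs):
            i, j = self._nb_pairs[:, 0], self._nb_pairs[:, 1]
            d = coords[:, i] - coords[:, j]
            r = np.linalg.norm(d, axis=-1, keepdims=True)
            r = np.maximum(r, 1e-3)
            sr6 = (self._lj_rmin[:, None] / r) ** 6
            dlj = self._lj_eps[:, None] * 12.0 * (sr6 - sr6 * sr6) / r
            dcoul = -2.0 * COULOMB_CONST * self._qq[:, None] / (4.0 * r ** 3)
            f = (dlj + dcoul) * d / r
            if self._dense_scatter:
                g += np.matmul(self._s_nb, f)
            else:
                np.add.at(g, (slice(None), i), f)
                np.add.at(g, (slice(None), j), -f)
        return g[0] if squeeze else g

    def minimize(self, coords: np.ndarray, steps: int = 1000):
        """Backtracking steepest descent, batched; energy never increases."""
        coords, squeeze = self._promote(coords)
        x = coords.copy()
        e, _ = self.evaluate(x)
        lr = np.full(x.shape[0], 1e-4)
        for _ in range(steps):
            g = self.gradient(x)
            trial = x - lr[:, None, None] * g
            e_t, _ = self.evaluate(trial)
            better = e_t < e
            x[better] = trial[better]
            e = np.where(better, e_t, e)
            lr = np.where(better, lr * 1.2, lr * 0.5)
        if squeeze:
            return x[0], float(e[0])
        return x, e

    @staticmethod
    def _promote(coords):
        coords = np.asarray(coords, dtype=float)
        squeeze = coords.ndim == 2
        return (coords[None] if squeeze else coords), squeeze


def percentile_cutoff(model, reference: Trajectory, steps: int = 50,
                      percentile: float = 99.0) -> float:
    """Energy cutoff from the sparsely-populated high tail of the reference
    ensemble's minimized-energy distribution."""
    _, energies = model.minimize(reference.coords, steps=steps)
    return float(np.percentile(energies, percentile))


# ---------------------------------------------------------------------------
# Filter report + steps
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    steps: list = field(default_factory=list)  # (name, n_in, n_out)
    reasons: dict = field(default_factory=dict)  # candidate idx -> reason

    def add_step(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("survivors exceed inputs")
        self.steps.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, n_in, n_out, n_out / n_in if n_in else 0.0)
                for name, n_in, n_out in self.steps]
        return pd.DataFrame(rows, columns=["step", "n_in", "n_out", "fraction"])

    def merged(self, other: "FilterReport") -> "FilterReport":
        rep = FilterReport(steps=self.steps + other.steps,
                           reasons={**self.reasons, **other.reasons})
        return rep


def energy_filter(candidates: Trajectory, model, cutoff: float,
                  steps: int = 1000):
    """Minimize every candidate and keep those at or below the energy cutoff.

    Minimized coordinates are carried forward for the survivors.  Non-finite
    energies eliminate the candidate (reason recorded) rather than raising.
    """
    minimized, energies = model.minimize(candidates.coords, steps=steps)
    finite = np.isfinite(energies)
    keep = finite & (energies <= cutoff)
    report = FilterReport()
    report.add_step("energy", candidates.n_frames, int(keep.sum()))
    for idx in np.nonzero(~keep)[0]:
        report.reasons[int(idx)] = "energy"
    out = Trajectory(minimized[keep], candidates.topology,
                     candidates.time_per_frame)
    return out, energies, report


def greedy_dedup(candidates: Trajectory, rmsd_cutoff: float = 1.0,
                 atom_indices: np.ndarray | None = None):
    """Sequential duplicate elimination by heavy-atom RMSD.

    A candidate survives iff its minimal superposed RMSD to every previously
    kept candidate exceeds the cutoff; deterministic in input order.
    """
    if atom_indices is None:
        atom_indices = candidates.topology.heavy_atoms()
    sel = candidates.coords[:, atom_indices]
    kept: list = []
    kept_coords: list = []
    report = FilterReport()
    for idx in range(candidates.n_frames):
        if kept_coords and rmsd_cutoff > 0:
            dists = rmsd_one_to_many(sel[idx], np.stack(kept_coords))
            if dists.min() <= rmsd_cutoff:
                report.reasons[idx] = "duplicate"
                continue
        kept.append(idx)
        kept_coords.append(sel[idx])
    report.add_step("dedup", candidates.n_frames, len(kept))
    return candidates.subset(kept), report


def novelty_filter(candidates: Trajectory, reference: Trajectory,
                   rmsd_cutoff: float = 1.2,
                   atom_indices: np.ndarray | None = None):
    """Keep candidates whose RMSD to every reference frame exceeds the cutoff."""
    if atom_indices is None:
        atom_indices = candidates.topology.heavy_atoms()
    sel = candidates.coords[:, atom_indices]
    report = FilterReport()
    if reference.n_frames == 0:
        report.add_step("novelty", candidates.n_frames, candidates.n_frames)
        return candidates.subset(np.arange(candidates.n_frames)), report
    ref = reference.coords[:, atom_indices]
    kept = []
    for idx in range(candidates.n_frames):
        if rmsd_one_to_many(sel[idx], ref).min() > rmsd_cutoff:
            kept.append(idx)
        else:
            report.reasons[idx] = "not-novel"
    report.add_step("novelty", candidates.n_frames, len(kept))
    return candidates.subset(kept), report


def run_filter_pipeline(candidates: Trajectory, reference: Trajectory,
                        energy_model, energy_cutoff: float | None = None,
                        min_steps: int = 1000, dedup_rmsd: float = 1.0,
                        novelty_rmsd: float = 1.2,
                        reference_min_steps: int = 50):
    """Energy screen → dedup → novelty, with a composed survivor report.

    When ``energy_cutoff`` is None it is derived as the 99th percentile of
    the reference ensemble's minimized energies.
    """
    if energy_cutoff is None:
        energy_cutoff = percentile_cutoff(energy_model, reference,
                                          steps=reference_min_steps)
    report = FilterReport()
    report.add_step("generated", candidates.n_frames, candidates.n_frames)
    survivors, _, rep2 = energy_filter(candidates, energy_model, energy_cutoff,
                                       steps=min_steps)
    survivors, rep3 = greedy_dedup(survivors, dedup_rmsd)
    survivors, rep4 = novelty_filter(survivors, reference, novelty_rmsd)
    return survivors, report.merged(rep2).merged(rep3).merged(rep4)
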