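"""Latent-space conformer generation by non-linear interpolation.

Consecutive conformations of an ordered ensemble map to neighbouring points
in the 3D latent space.  New conformations are generated along a randomized
spherical arc between each consecutive pair: the pair is expressed in
spherical coordinates (R, Θ, Φ) about a jittered midpoint, and interior
points are taken at equal steps of all three coordinates, so the path bends
through latent space instead of cutting straight across it.  Decoding the
interpolated points and rebuilding Cartesian coordinates yields candidate
conformations; m frames and k points per pair give exactly (m-1)·k
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autoencoder import TrainedModel, decode, encode
from .internal import BATState, vbat_to_cartesian
from .topology import BATIndexing, MoleculeTopology, Trajectory

__all__ = [
    "InterpolationConfig",
    "LatentEnsemble",
    "spherical_arc_interpolate",
    "interpolate_ensemble",
    "generate_candidates",
]


@dataclass
class InterpolationConfig:
    points_per_pair: int = 10
    jitter: float = 0.1  # arc-center offset, as a fraction of the pair separation
    seed: int = 0

    def __post_init__(self):
        if self.points_per_pair < 1:
            raise ValueError("points_per_pair must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass
class LatentEnsemble:
    """Ordered latent points plus provenance (encoded frame or arc point)."""

    points: np.ndarray  # (n, latent_dim)
    provenance: pd.DataFrame  # columns: kind, source_frame, parent_a, parent_b, t

    def __len__(self) -> int:
        return self.points.shape[0]

    @classmethod
    def from_encoding(cls, points: np.ndarray) -> "LatentEnsemble":
        n = points.shape[0]
        prov = pd.DataFrame({
            "kind": ["encoded"] * n,
            "source_frame": np.arange(n),
            "parent_a": -1, "parent_b": -1, "t": np.nan,
        })
        return cls(np.asarray(points, dtype=float), prov)


def _to_spherical(d: np.ndarray):
    r = np.linalg.norm(d)
    if r == 0:
        return 0.0, 0.0, 0.0
    theta = np.arccos(np.clip(d[2] / r, -1.0, 1.0))  # polar from +z
    phi = np.arctan2(d[1], d[0])
    return r, theta, phi


def spherical_arc_interpolate(p1, p2, n: int, jitter: float = 0.0,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Interior points of a spherical arc from p1 to p2 about a jittered center.

    The center is the midpoint of the pair, displaced by ``jitter`` times the
    pair separation along a random direction.  R, Θ and Φ are interpolated
    linearly at parameters t = 1/(n+1) … n/(n+1) (endpoints excluded), with Φ
    taken along the shorter angular arc.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng()
    sep = np.linalg.norm(p2 - p1)
    center = 0.5 * (p1 + p2)
    if jitter > 0:
        u = rng.normal(size=3)
        norm = np.linalg.norm(u)
        if norm > 0:
            center = center + jitter * sep * u / norm
    if sep == 0 and np.allclose(center, p1):
        return np.tile(p1, (n, 1))
    r1, th1, ph1 = _to_spherical(p1 - center)
    r2, th2, ph2 = _to_spherical(p2 - center)
    dphi = (ph2 - ph1 + np.pi) % (2 * np.pi) - np.pi  # shorter arc
    t = np.arange(1, n + 1) / (n + 1)
    r = r1 + t * (r2 - r1)
    th = th1 + t * (th2 - th1)
    ph = ph1 + t * dphi
    out = np.stack([
        r * np.sin(th) * np.cos(ph),
        r * np.sin(th) * np.sin(ph),
        r * np.cos(th),
    ], axis=1)
    return out + center


def interpolate_ensemble(points: np.ndarray,
                         config: InterpolationConfig) -> LatentEnsemble:
    """Arc-interpolate every consecutive pair of ordered latent points."""
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    if m < 2:
        raise ValueError("need at least 2 latent points to interpolate")
    rng = np.random.default_rng(config.seed)
    k = config.points_per_pair
    chunks, rows = [], []
    for a in range(m - 1):
        arc = spherical_arc_interpolate(points[a], points[a + 1], k,
                                        config.jitter, rng)
        chunks.append(arc)
        for s in range(k):
            rows.append(("interpolated", -1, a, a + 1, (s + 1) / (k + 1)))
    prov = pd.DataFrame(rows, columns=["kind", "source_frame", "parent_a",
                                       "parent_b", "t"])
    return LatentEnsemble(np.concatenate(chunks, axis=0), prov)


def generate_candidates(model: TrainedModel, features: np.ndarray,
                        config: InterpolationConfig, reference: BATState,
                        indexing: BATIndexing, topology: MoleculeTopology):
    """Encode an ordered ensemble, interpolate, decode, rebuild Cartesian.

    Returns (Trajectory of candidates, provenance DataFrame); for m input
    frames and k points per pair there are exactly (m-1)·k candidates.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    latent = encode(model, features)
    ensemble = interpolate_ensemble(latent, config)
    decoded = decode(model, ensemble.points)
    coords = vbat_to_cartesian(decoded, reference, indexing)
    return Trajectory(coords, topology), ensemble.provenance
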