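"""Collective variables and geometric observables.

Distances in Å, MSD in Å², angles and dihedrals in degrees.  Dihedrals are
signed torsions in (−180°, +180°] following the IUPAC convention (positive
for a clockwise rotation of the far bond viewed along the central bond);
plain angles lie in [0°, 180°].  MSD/RMSD assume pre-aligned frames — no
superposition fit is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frames import PathReference

__all__ = [
    "CvRecord", "Histogram", "OutOfPathError",
    "com_distance", "angle", "dihedral", "msd", "rmsd",
    "path_progress", "funnel_radial", "population_histogram",
]


class OutOfPathError(ValueError):
    """Frame is so far from every reference frame that all weights underflow."""


@dataclass
class CvRecord:
    """A named CV value with optional per-coordinate gradient."""

    name: str
    value: float
    gradient: Optional[np.ndarray] = None


@dataclass
class Histogram:
    """Binned CV series; ``normalized_density`` integrates to 1 when present."""

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized_density: Optional[np.ndarray] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _masses(points: np.ndarray, masses) -> np.ndarray:
    n = points.shape[0]
    if masses is None:
        return np.ones(n)
    m = np.asarray(masses, dtype=float)
    if m.shape != (n,):
        raise ValueError("masses must match the number of points")
    return m


def com_distance(points_a, points_b, masses_a=None, masses_b=None,
                 return_gradient: bool = False):
    """Distance between the mass-weighted centroids of two point groups (Å).

    With ``return_gradient=True`` also returns d(distance)/d(points_a), the
    per-point derivative (m_i/M)·û with û the unit inter-centroid vector.
    """
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if pa.size == 0 or pb.size == 0:
        raise ValueError("point groups must be non-empty")
    ma, mb = _masses(pa, masses_a), _masses(pb, masses_b)
    if ma.sum() <= 0 or mb.sum() <= 0:
        raise ValueError("total mass must be positive")
    ca = (ma[:, None] * pa).sum(axis=0) / ma.sum()
    cb = (mb[:, None] * pb).sum(axis=0) / mb.sum()
    diff = ca - cb
    d = float(np.linalg.norm(diff))
    if not return_gradient:
        return d
    if d == 0.0:
        grad = np.zeros_like(pa)
    else:
        grad = (ma / ma.sum())[:, None] * (diff / d)[None, :]
    return d, grad


def angle(p1, p2, p3) -> float:
    """Interior angle at p2 in degrees, in [0°, 180°]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = p1 - p2
    b = p3 - p2
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-length arm: p2 must differ from p1 and p3")
    c = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(c))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in degrees, wrapped to (−180°, +180°]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise ValueError("degenerate geometry: undefined torsion")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    phi = math.degrees(math.atan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def msd(frame_a, frame_b) -> float:
    """Mean squared per-point displacement (Å²), no superposition fit."""
    a = np.atleast_2d(np.asarray(frame_a, dtype=float))
    b = np.atleast_2d(np.asarray(frame_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"mismatched point counts: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.mean(np.sum(d * d, axis=1)))


def rmsd(frame_a, frame_b) -> float:
    """Root-mean-square deviation (Å) of pre-aligned frames."""
    return math.sqrt(msd(frame_a, frame_b))


def path_progress(frame, ref: PathReference) -> float:
    """Progress along a reference path on the MSD scale (Å²).

    s(R) = Σᵢ mᵢ·exp(−λ·MSDᵢ) / Σᵢ exp(−λ·MSDᵢ) with milestones
    mᵢ = (i−1)·spacing, giving values in [0, (P−1)·spacing].
    """
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    dists = np.array([msd(frame, f) for f in ref.frames])
    if ref.lam * dists.min() > 700.0:
        raise OutOfPathError(
            f"frame is off-path: min MSD {dists.min():.3g} Å² makes all weights underflow"
        )
    w = np.exp(-ref.lam * (dists - dists.min()))
    return float(np.sum(ref.milestones * w) / np.sum(w))


def funnel_radial(position, axis_origin, axis_direction,
                  return_gradient: bool = False):
    """Perpendicular distance (Å) of a position from the funnel axis line."""
    p = np.asarray(position, dtype=float)
    o = np.asarray(axis_origin, dtype=float)
    u = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0.0:
        raise ValueError("axis direction must be non-zero")
    if abs(norm - 1.0) > 1e-8:
        raise ValueError("axis direction must be a unit vector")
    rel = p - o
    perp = rel - np.dot(rel, u) * u
    d = float(np.linalg.norm(perp))
    if not return_gradient:
        return d
    grad = np.zeros_like(p) if d == 0.0 else perp / d
    return d, grad


def population_histogram(values, bin_width: float, normalize: bool = False,
                         circular: bool = False) -> Histogram:
    """Histogram of a CV series.

    With ``circular=True`` (dihedrals) values are wrapped on the ±180° circle
    and the bin grid is aligned so that one bin is centred on ±180°, i.e.
    −179° and +179° share a bin at 5° width.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty CV series")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if circular:
        n_bins = int(math.ceil(360.0 / bin_width))
        lo = -180.0 - bin_width / 2.0
        v = (v - lo) % 360.0 + lo  # wrap into [lo, lo+360)
        edges = lo + bin_width * np.arange(n_bins + 1)
    else:
        lo = float(v.min())
        n_bins = max(1, int(math.ceil((float(v.max()) - lo) / bin_width - 1e-12)))
        edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    assert counts.sum() == v.size
    density = None
    if normalize:
        density = counts / (v.size * bin_width)
    return Histogram(bin_edges=edges, counts=counts, normalized_density=density)
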