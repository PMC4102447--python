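"""Synthetic anchor-point frames and path references.

``AnchorFrame`` mimics the six-point restraint geometry used to control a
ligand's orientation and translation during unbinding: two protein anchors
(P1, P2), a fictitious projection point PC placed 5 Å from the ligand centre
LC along the unbinding axis, and two additional ligand atoms (L1, L2).

``PathReference`` is an ordered set of reference conformations with equal
mean-square-deviation spacing between consecutive frames, the input of the
path-progress collective variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnchorFrame", "PathReference", "make_anchor_trajectory",
           "make_path_frames", "UNBINDING_AXIS"]

#: Canonical unbinding axis (the funnel axis).
UNBINDING_AXIS = np.array([1.0, 0.0, 0.0])

_CANONICAL = {
    "L1": np.array([-1.2, 1.0, 0.0]),
    "L2": np.array([-2.2, -0.8, 0.5]),
    "LC": np.array([0.0, 0.0, 0.0]),
    "P1": np.array([9.5, -1.5, 2.0]),
    "P2": np.array([8.0, 2.0, 0.0]),
}

_PC_OFFSET = 5.0  # Å from LC along the unbinding axis


@dataclass
class AnchorFrame:
    """Six labelled 3-D points defining the restraint geometry (Å)."""

    P1: np.ndarray
    P2: np.ndarray
    PC: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    LC: np.ndarray

    def restraint_cvs(self) -> dict[str, float]:
        """The five restraint angles plus the axial separation r.

        α(L1, LC, PC) and θ(LC, PC, P2) are plain angles; β(L1, LC, PC, P2),
        γ(L2, L1, LC, PC) and Θ(LC, PC, P2, P1) are dihedrals; r is the
        LC→PC distance projected on the unbinding axis.
        """
        from .colvars import angle, dihedral

        return {
            "alpha": angle(self.L1, self.LC, self.PC),
            "beta": dihedral(self.L1, self.LC, self.PC, self.P2),
            "gamma": dihedral(self.L2, self.L1, self.LC, self.PC),
            "theta": angle(self.LC, self.PC, self.P2),
            "Theta": dihedral(self.LC, self.PC, self.P2, self.P1),
            "r": float(np.dot(self.PC - self.LC, UNBINDING_AXIS)),
        }


def make_anchor_trajectory(n_frames: int, noise: float, seed: int) -> list[AnchorFrame]:
    """Canonical restraint geometry perturbed by seeded Gaussian noise.

    At ``noise = 0`` every frame equals the canonical geometry.  PC is always
    reconstructed 5 Å from the (possibly perturbed) LC along the unbinding
    axis, matching its definition as a fictitious projection point.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        pts = {
            name: p + (rng.standard_normal(3) * noise if noise > 0 else 0.0)
            for name, p in _CANONICAL.items()
        }
        pts["PC"] = pts["LC"] + _PC_OFFSET * UNBINDING_AXIS
        frames.append(AnchorFrame(**{k: np.asarray(v, dtype=float) for k, v in pts.items()}))
    return frames


@dataclass
class PathReference:
    """Ordered reference frames for the path-progress CV.

    ``spacing`` is the MSD (Å²) between consecutive frames; ``lam`` the
    smoothing constant (1/Å²).  Milestone values are (i−1)·spacing, so the
    progress variable runs from 0 to (P−1)·spacing; on a linearly interpolated
    path the *geometric* MSD between the two endpoint frames is
    (P−1)²·spacing.
    """

    frames: list[np.ndarray]
    spacing: float
    lam: float

    def __post_init__(self):
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        if len(self.frames) < 2:
            raise ValueError("need at least two reference frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def milestones(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.spacing


def _endpoint_sets(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n_points, dtype=float)
    closed = np.stack([i, np.zeros(n_points), np.zeros(n_points)], axis=1)
    disp = np.stack(
        [np.where(i % 2 == 0, 1.0, -1.0), 0.5 * np.sin(1.0 + i), 0.3 * np.cos(i)],
        axis=1,
    )
    return closed, closed + disp


def make_path_frames(P: int, spacing: float, n_points_per_frame: int = 4,
                     lam: float | None = None,
                     endpoints: tuple[np.ndarray, np.ndarray] | None = None) -> PathReference:
    """Linearly interpolated reference path with exact MSD spacing.

    Consecutive frames satisfy MSD(frame_i, frame_{i+1}) = spacing to
    within floating-point round-off; the default smoothing constant is the
    standard heuristic λ = 2.3/spacing for evenly spaced frames.
    """
    if P < 2:
        raise ValueError("P must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if endpoints is None:
        a, b = _endpoint_sets(n_points_per_frame)
    else:
        a = np.asarray(endpoints[0], dtype=float)
        b = np.asarray(endpoints[1], dtype=float)
    d = b - a
    msd_ab = float(np.mean(np.sum(d * d, axis=1)))
    if msd_ab <= 0:
        raise ValueError("degenerate endpoint sets: zero total displacement")
    # rescale the displacement so consecutive interpolated frames are exactly
    # `spacing` apart in MSD: MSD(f_i, f_j) = ((i-j)/(P-1))^2 * MSD(a, b)
    scale = np.sqrt(spacing * (P - 1) ** 2 / msd_ab)
    b = a + d * scale
    ts = np.linspace(0.0, 1.0, P)
    frames = [a + t * (b - a) for t in ts]
    if lam is None:
        lam = 2.3 / spacing
    return PathReference(frames=frames, spacing=spacing, lam=lam)
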