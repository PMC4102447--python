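"""Umbrella sampling with harmonic window biases and a WHAM solver.

Each window i restrains the reaction coordinate with u_i(ξ) = k_i/2·(ξ−ξ_i)²;
the weighted histogram analysis method (WHAM) self-consistently solves

    ρ(b) = Σ_i n_i(b) / Σ_i N_i·exp(β·f_i)·c_i(b),
    exp(−β·f_i) = Σ_b ρ(b)·c_i(b),          c_i(b) = exp(−β·u_i(ξ_b))

for the unbiased density ρ and per-window offsets f_i, and the PMF is
−kB·T·ln ρ aligned to zero at its minimum.  In the single-window, zero-bias
limit the result reduces exactly to direct Boltzmann inversion of the
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .conditions import SimulationConditions
from .metad import CoordinateCV
from .potentials import ToyPotential
from .sampling import LangevinParams, ensemble_langevin

__all__ = [
    "Profile1D", "UmbrellaWindow", "WindowLadder", "WhamResult",
    "UnstitchableLadderError", "harmonic_bias", "seed_windows_from_path",
    "run_umbrella", "wham", "wham_block_uncertainty", "pmf_depth",
    "make_ladder",
]


class UnstitchableLadderError(RuntimeError):
    """Window histograms do not overlap: the RC coverage is disconnected."""


@dataclass
class Profile1D:
    """1-D free-energy profile: rc grid, free energy (kcal/mol), optional σ."""

    rc: np.ndarray
    free_energy: np.ndarray
    uncertainty: Optional[np.ndarray] = None

    def __post_init__(self):
        self.rc = np.asarray(self.rc, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.rc.shape != self.free_energy.shape:
            raise ValueError("rc and free_energy must have matching shapes")

    def aligned(self) -> "Profile1D":
        """Copy with the minimum shifted to zero."""
        return Profile1D(self.rc, self.free_energy - self.free_energy.min(),
                         self.uncertainty)

    def minimum(self) -> tuple[float, float]:
        i = int(np.argmin(self.free_energy))
        return float(self.rc[i]), float(self.free_energy[i])

    def barrier_after_minimum(self) -> float:
        """Max free energy at rc ≥ argmin, relative to the minimum."""
        i = int(np.argmin(self.free_energy))
        return float(self.free_energy[i:].max() - self.free_energy[i])


@dataclass
class UmbrellaWindow:
    """One harmonic window: centre ξ_ref, constant k, and its CV samples."""

    cv: str
    center: float
    k: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    sim_length: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class WindowLadder:
    """Ordered umbrella windows with strictly increasing centres."""

    windows: list[UmbrellaWindow]
    spacing: float

    def __post_init__(self):
        centers = [w.center for w in self.windows]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)


def make_ladder(cv: str, lo: float, hi: float, spacing: float, k: float) -> WindowLadder:
    """Evenly spaced ladder with inclusive endpoints (5–25 Å at 0.5 Å → 41 windows)."""
    n = int(round((hi - lo) / spacing)) + 1
    centers = lo + spacing * np.arange(n)
    return WindowLadder(
        windows=[UmbrellaWindow(cv=cv, center=float(c), k=k) for c in centers],
        spacing=spacing,
    )


def harmonic_bias(xi: float, window: UmbrellaWindow) -> float:
    """Window bias (k/2)·(ξ − ξ_ref)² in kcal/mol."""
    d = xi - window.center
    return 0.5 * window.k * d * d


def seed_windows_from_path(traj, centers: Sequence[float],
                           cv_name: Optional[str] = None) -> list[np.ndarray]:
    """Pick, per window centre, the trajectory frame with the nearest CV value.

    Ties are broken by the earliest frame.  Raises if a centre lies outside
    the CV range visited by the trajectory.
    """
    if cv_name is not None and cv_name in traj.cv_values:
        series = np.asarray(traj.cv_values[cv_name], dtype=float)
    else:
        series = traj.coordinates[:, 0]
    lo, hi = float(series.min()), float(series.max())
    seeds = []
    for c in centers:
        if not (lo <= c <= hi):
            raise ValueError(
                f"window center {c} outside the trajectory CV range [{lo:.3g}, {hi:.3g}]"
            )
        i = int(np.argmin(np.abs(series - c)))  # argmin returns the earliest tie
        seeds.append(traj.coordinates[i].copy())
    return seeds


def run_umbrella(
    potential: ToyPotential,
    cv: CoordinateCV,
    ladder: WindowLadder,
    params: LangevinParams,
    conditions: SimulationConditions,
    extra_restraints: Optional[ToyPotential] = None,
    seeds: Optional[Sequence[np.ndarray]] = None,
    burn_in: float = 0.5,
) -> WindowLadder:
    """Sample every window (independent replicas propagated in lockstep).

    Each replica feels U + (k_i/2)(ξ−ξ_i)² (+ optional extra restraints); the
    first ``burn_in`` fraction of saved samples is discarded (default 50%,
    i.e. keep the second half of each window's run).
    """
    dim = potential.dimensionality
    n_win = len(ladder)
    if seeds is None:
        x0 = np.zeros((n_win, dim))
        x0[:, cv.index] = ladder.centers
    else:
        x0 = np.array([np.asarray(s, dtype=float).reshape(dim) for s in seeds])
    centers = ladder.centers
    ks = np.array([w.k for w in ladder.windows])

    def bias_grad(state: np.ndarray) -> np.ndarray:
        g = np.zeros_like(state)
        g[:, cv.index] = ks * (state[:, cv.index] - centers)
        if extra_restraints is not None:
            g = g + extra_restraints.gradient(state)
        return g

    samples = ensemble_langevin(
        potential, x0, params, conditions,
        bias_gradient=bias_grad, record=lambda s: s[:, cv.index],
    )
    n_keep = samples.shape[0] - int(burn_in * samples.shape[0])
    kept = samples[samples.shape[0] - n_keep:]
    if kept.shape[0] < 100:
        raise RuntimeError(
            f"only {kept.shape[0]} post-burn-in samples per window; need >= 100"
        )
    sim_length = params.n_steps * params.timestep
    for i, w in enumerate(ladder.windows):
        w.samples = kept[:, i].copy()
        w.sim_length = sim_length
    return ladder


@dataclass
class WhamResult:
    """Unbiased PMF with per-window offsets and convergence diagnostics."""

    pmf: Profile1D
    window_offsets: np.ndarray
    iterations: int
    converged: bool
    tolerance: float


def wham(
    ladder: WindowLadder,
    conditions: SimulationConditions,
    bin_count: int = 200,
    tolerance: float = 1e-7,
    max_iterations: int = 100_000,
    bin_range: Optional[tuple[float, float]] = None,
) -> WhamResult:
    """Self-consistent WHAM solve over shared bins.

    Offsets are initialised at zero and iterated until the largest change is
    below ``tolerance`` (kcal/mol).  Raises ``UnstitchableLadderError`` when
    the occupied bins are not contiguous (non-overlapping windows).
    """
    if len(ladder) < 1:
        raise ValueError("need at least one window")
    for w in ladder.windows:
        if w.samples.size == 0:
            raise ValueError(f"window at {w.center} has no samples")
    allv = np.concatenate([w.samples for w in ladder.windows])
    if bin_range is None:
        # robust default: clip the 0.05 per-mille tails so stray outliers do
        # not open empty edge bins
        lo = float(np.quantile(allv, 5e-4))
        hi = float(np.quantile(allv, 1.0 - 5e-4))
    else:
        lo, hi = bin_range
    edges = np.linspace(lo, hi, bin_count + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_ib = np.stack([np.histogram(w.samples, bins=edges)[0] for w in ladder.windows])
    n_i = n_ib.sum(axis=1).astype(float)
    n_b = n_ib.sum(axis=0).astype(float)

    occupied = n_b > 0
    occ_idx = np.flatnonzero(occupied)
    if occ_idx.size == 0:
        raise ValueError("no samples fall inside the binned range")
    if np.any(~occupied[occ_idx[0]: occ_idx[-1] + 1]):
        raise UnstitchableLadderError(
            "empty interior bins: window coverage of the RC is disconnected"
        )

    beta = conditions.beta
    kt = conditions.kt
    u_ib = 0.5 * np.array([w.k for w in ladder.windows])[:, None] \
        * (centers[None, :] - np.array([w.center for w in ladder.windows])[:, None]) ** 2
    c_ib = np.exp(-beta * u_ib)

    f = np.zeros(len(ladder))
    it = 0
    converged = False
    while it < max_iterations:
        it += 1
        denom = (n_i * np.exp(beta * f)) @ c_ib  # Σ_i N_i e^{βf_i} c_i(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, n_b / denom, 0.0)
        z = c_ib @ rho
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta <= tolerance:
            converged = True
            break

    denom = (n_i * np.exp(beta * f)) @ c_ib
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, n_b / denom, 0.0)
    with np.errstate(divide="ignore"):
        pmf_vals = np.where(rho > 0, -kt * np.log(rho), np.inf)
    keep = np.isfinite(pmf_vals)
    pmf = Profile1D(centers[keep], pmf_vals[keep] - pmf_vals[keep].min())
    return WhamResult(pmf=pmf, window_offsets=f, iterations=it,
                      converged=converged, tolerance=tolerance)


def wham_block_uncertainty(ladder: WindowLadder,
                           conditions: SimulationConditions,
                           n_blocks: int = 4,
                           **wham_kwargs) -> Profile1D:
    """PMF with per-bin standard errors from block averaging.

    Splits every window's samples into ``n_blocks`` contiguous blocks, solves
    WHAM per block, and reports the full-data PMF with the standard error of
    the block PMFs (each min-aligned) on the shared grid.
    """
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    full = wham(ladder, conditions, **wham_kwargs)
    grid = full.pmf.rc
    block_vals = []
    for b in range(n_blocks):
        blk_windows = []
        for w in ladder.windows:
            n = w.samples.size
            lo, hi = (n * b) // n_blocks, (n * (b + 1)) // n_blocks
            blk_windows.append(UmbrellaWindow(cv=w.cv, center=w.center, k=w.k,
                                              samples=w.samples[lo:hi]))
        blk = WindowLadder.__new__(WindowLadder)
        blk.windows = blk_windows
        blk.spacing = ladder.spacing
        res = wham(blk, conditions, **wham_kwargs)
        block_vals.append(np.interp(grid, res.pmf.rc, res.pmf.free_energy))
    spread = np.std(np.stack(block_vals), axis=0, ddof=1)
    err = spread / np.sqrt(n_blocks)
    return Profile1D(grid, full.pmf.free_energy, uncertainty=err)


def pmf_depth(profile: Profile1D, site_range: tuple[float, float],
              bulk_range: tuple[float, float]) -> float:
    """Mean free energy over the bulk range minus the site minimum (≥0 for binding)."""
    rc = profile.rc
    site = (rc >= site_range[0]) & (rc <= site_range[1])
    bulk = (rc >= bulk_range[0]) & (rc <= bulk_range[1])
    if not site.any() or not bulk.any():
        raise ValueError("site or bulk range contains no profile points")
    return float(profile.free_energy[bulk].mean() - profile.free_energy[site].min())
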