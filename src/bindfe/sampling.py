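"""Overdamped (Brownian) Langevin dynamics on toy potentials.

The integrator is Euler–Maruyama for the overdamped limit:

    x(t+Δt) = x(t) − (Δt/γ)·∇U(x) + √(2·kB·T·Δt/γ)·ξ,   ξ ~ N(0, 1)

which samples the Boltzmann distribution exp(−βU) for small Δt and satisfies
equipartition on harmonic wells (Var[x] = kB·T/k).  Runs are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .conditions import SimulationConditions
from .potentials import ToyPotential

__all__ = ["LangevinParams", "Trajectory", "DivergenceError", "langevin_sample",
           "ensemble_langevin"]


class DivergenceError(RuntimeError):
    """Raised when a walker leaves the declared domain by more than 10 Å."""


@dataclass(frozen=True)
class LangevinParams:
    """Integrator controls: timestep (ps), friction (1/ps), length and stride."""

    timestep: float = 0.01
    friction: float = 1.0
    n_steps: int = 100_000
    seed: int = 0
    save_stride: int = 10

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


@dataclass
class Trajectory:
    """Saved frames of a run: times (ps), coordinates (n_frames, dim), CVs."""

    times: np.ndarray
    coordinates: np.ndarray
    cv_values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _domain_check(x: np.ndarray, domain, margin: float = 10.0) -> None:
    for i, (lo, hi) in enumerate(domain):
        v = x[..., i]
        if np.any(v < lo - margin) or np.any(v > hi + margin):
            raise DivergenceError(
                f"coordinate {i} left domain [{lo}, {hi}] by more than {margin} Å"
            )


def langevin_sample(
    potential: ToyPotential,
    params: LangevinParams,
    conditions: SimulationConditions,
    bias: Optional[ToyPotential] = None,
    x0: Optional[np.ndarray] = None,
    cv_funcs: Optional[dict[str, Callable[[np.ndarray], float]]] = None,
) -> Trajectory:
    """Run a single overdamped Langevin trajectory.

    ``bias`` is any object with a ``gradient(x)`` method (e.g. another
    :class:`ToyPotential`); the total force is −∇(U + bias).  ``cv_funcs``
    maps names to scalar functions of the coordinates recorded per saved
    frame.  The number of saved frames is floor(n_steps/save_stride) + 1
    (the initial frame included).
    """
    dim = potential.dimensionality
    if x0 is None:
        x = np.zeros(dim, dtype=float)
    else:
        x = np.array(x0, dtype=float).reshape(dim)
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    mob = dt / params.friction
    noise_scale = np.sqrt(2.0 * conditions.kt * dt / params.friction)

    n_frames = params.n_steps // params.save_stride + 1
    frames = np.empty((n_frames, dim), dtype=float)
    times = np.empty(n_frames, dtype=float)
    frames[0] = x
    times[0] = 0.0

    chunk = 4096
    frame_i = 1
    step = 0
    while step < params.n_steps:
        n = min(chunk, params.n_steps - step)
        noise = rng.standard_normal((n, dim)) * noise_scale
        for j in range(n):
            g = potential.gradient(x)
            if bias is not None:
                g = g + bias.gradient(x)
            x = x - mob * g + noise[j]
            step += 1
            if step % params.save_stride == 0:
                frames[frame_i] = x
                times[frame_i] = step * dt
                frame_i += 1
        if potential.domain:
            _domain_check(x[None, :], potential.domain)

    cvs = {}
    if cv_funcs:
        for name, fn in cv_funcs.items():
            cvs[name] = np.array([fn(f) for f in frames])
    return Trajectory(times=times, coordinates=frames, cv_values=cvs)


def ensemble_langevin(
    potential: ToyPotential,
    x0s: np.ndarray,
    params: LangevinParams,
    conditions: SimulationConditions,
    bias_gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    record: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Propagate independent replicas in lockstep (vectorised over replicas).

    Used by the umbrella-sampling driver where each replica carries its own
    harmonic bias.  ``bias_gradient`` maps the (n_replicas, dim) state to the
    per-replica bias force contribution; ``record`` maps the state to one
    recorded value per replica (default: first coordinate).  Returns an array
    of shape (n_frames, n_replicas).
    """
    x = np.array(x0s, dtype=float)
    if x.ndim != 2:
        raise ValueError("x0s must have shape (n_replicas, dim)")
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    mob = dt / params.friction
    noise_scale = np.sqrt(2.0 * conditions.kt * dt / params.friction)
    if record is None:
        record = lambda s: s[:, 0]

    n_frames = params.n_steps // params.save_stride + 1
    out = np.empty((n_frames, x.shape[0]), dtype=float)
    out[0] = record(x)
    frame_i = 1
    chunk = 1024
    step = 0
    while step < params.n_steps:
        n = min(chunk, params.n_steps - step)
        noise = rng.standard_normal((n,) + x.shape) * noise_scale
        for j in range(n):
            g = potential.gradient(x)
            if bias_gradient is not None:
                g = g + bias_gradient(x)
            x = x - mob * g + noise[j]
            step += 1
            if step % params.save_stride == 0:
                out[frame_i] = record(x)
                frame_i += 1
        if potential.domain:
            _domain_check(x, potential.domain)
    return out
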