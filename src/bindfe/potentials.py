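"""Analytic toy potentials standing in for a solvated protein–ligand complex.

Every potential exposes ``energy(x)`` and ``gradient(x)`` on arrays whose last
axis is the coordinate dimension, plus a declared rectangular ``domain``.
Gradients are exact analytic derivatives; ``check_gradient`` verifies them
against central differences and is used as a construction invariant in the
tests.

The central factory is :func:`make_binding_landscape`, which builds the 2-D
"separation × conformation" surfaces used throughout: a bound well at small
separation, an optional dissociation barrier at 4–8 Å whose crossing requires
a conformational displacement (induced fit), and a flat bulk plateau beyond
15 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ToyPotential",
    "HarmonicPotential",
    "DoubleWellPotential",
    "BindingLandscape",
    "AxialChannelPotential",
    "Angle1DPotential",
    "TabulatedPotential",
    "SumPotential",
    "HarmonicRestraintTerm",
    "SoftWalls",
    "make_binding_landscape",
    "make_potential",
    "check_gradient",
]


def _sigmoid(z):
    # numerically safe logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ToyPotential:
    """Base class: analytic energy/gradient on a declared rectangular domain."""

    form_id: str = "abstract"
    dimensionality: int = 0
    #: per-dimension (lo, hi) bounds; samplers flag divergence 10 Å past them
    domain: tuple[tuple[float, float], ...] = ()

    def energy(self, x: np.ndarray) -> np.ndarray | float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> dict:
        return {}


@dataclass
class HarmonicPotential(ToyPotential):
    """Isotropic or per-dimension harmonic well, U = Σ k_i/2 (x_i − x0_i)²."""

    k: Sequence[float]
    center: Sequence[float]
    form_id: str = "harmonic"

    def __post_init__(self):
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        if self.k.shape != self.center.shape:
            raise ValueError("k and center must have matching shapes")
        self.dimensionality = self.k.size
        self.domain = tuple((c - 50.0, c + 50.0) for c in self.center)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d = x - self.center
        return 0.5 * np.sum(self.k * d * d, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return self.k * (x - self.center)

    def parameters(self):
        return {"k": self.k.tolist(), "center": self.center.tolist()}


@dataclass
class DoubleWellPotential(ToyPotential):
    """Symmetric 1-D quartic double well, U = h·((x/a)² − 1)².

    The barrier between the wells at ±a is exactly ``h`` kcal/mol.
    """

    barrier: float = 5.0
    half_separation: float = 1.5
    form_id: str = "double_well"

    def __post_init__(self):
        if self.barrier <= 0 or self.half_separation <= 0:
            raise ValueError("barrier and half_separation must be > 0")
        self.dimensionality = 1
        a = self.half_separation
        self.domain = ((-3.0 * a, 3.0 * a),)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] / self.half_separation) ** 2 - 1.0
        return self.barrier * u * u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        a2 = self.half_separation**2
        u = x[..., 0] ** 2 / a2 - 1.0
        g = np.zeros_like(x)
        g[..., 0] = 4.0 * self.barrier * u * x[..., 0] / a2
        return g

    def scalar_gradient(self):
        h, a2 = self.barrier, self.half_separation**2

        def grad(x):
            return (4.0 * h * (x * x / a2 - 1.0) * x / a2,)

        return grad

    def parameters(self):
        return {"barrier": self.barrier, "half_separation": self.half_separation}


def _axial_profile(r, depth, r_mid, width, b_height, r_barrier, w_barrier):
    """Radial profile: sigmoidal well of given depth plus a Gaussian barrier."""
    s = _sigmoid((np.asarray(r, dtype=float) - r_mid) / width)
    f = depth * (s - 1.0)
    if b_height != 0.0:
        f = f + b_height * np.exp(-0.5 * ((r - r_barrier) / w_barrier) ** 2)
    return f


def _axial_profile_deriv(r, depth, r_mid, width, b_height, r_barrier, w_barrier):
    r = np.asarray(r, dtype=float)
    s = _sigmoid((r - r_mid) / width)
    d = depth * s * (1.0 - s) / width
    if b_height != 0.0:
        g = np.exp(-0.5 * ((r - r_barrier) / w_barrier) ** 2)
        d = d - b_height * (r - r_barrier) / w_barrier**2 * g
    return d


@dataclass
class BindingLandscape(ToyPotential):
    """2-D separation (r) × conformation (c) landscape.

    ``profile_kind='flat'`` decouples the conformational coordinate: the
    c-minimized profile is the monotone well itself.  ``profile_kind='barrier'``
    shifts the conformational minimum c_min(r) across the barrier region, so
    crossing the saddle requires a conformational displacement (the induced-fit
    topology), and adds a Gaussian barrier whose amplitude is calibrated at
    construction so that max−min of the c-minimized profile equals
    ``barrier_height`` exactly.
    """

    profile_kind: str = "barrier"
    depth: float = 5.0
    barrier_height: float = 12.0
    r_barrier: float = 6.0
    barrier_width: float = 1.0
    r_mid: float = 4.0
    well_width: float = 0.7
    k_conf: float = 2.0
    c_closed: float = 0.8
    c_open: float = 1.6
    conf_switch_width: float = 1.0
    form_id: str = "binding_landscape"
    _b_amplitude: float = field(default=0.0, repr=False)

    def __post_init__(self):
        if self.profile_kind not in ("barrier", "flat"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")
        if self.depth <= 0:
            raise ValueError("well depth must be > 0")
        self.dimensionality = 2
        self.domain = ((0.0, 25.0), (-6.0, 12.0))
        if self.profile_kind == "barrier":
            if self.barrier_height <= self.depth:
                raise ValueError(
                    "barrier_height is max−min of the minimized profile and "
                    "must exceed the well depth"
                )
            self._b_amplitude = self._calibrate_barrier()

    # -- radial profile -------------------------------------------------

    def _profile(self, r, b):
        return _axial_profile(
            r, self.depth, self.r_mid, self.well_width, b, self.r_barrier,
            self.barrier_width,
        )

    def _calibrate_barrier(self) -> float:
        """Choose the Gaussian amplitude so max−min of the profile = barrier_height."""
        grid = np.linspace(self.domain[0][0], self.domain[0][1], 25001)

        def span(b):
            f = self._profile(grid, b)
            return float(f.max() - f.min()) - self.barrier_height

        lo = max(self.barrier_height - self.depth - 2.0, 1e-6)
        hi = self.barrier_height + 2.0
        return brentq(span, lo, hi, xtol=1e-12)

    def minimized_profile(self, r) -> np.ndarray:
        """min over c of U(r, c); equals the calibrated radial profile."""
        return self._profile(np.asarray(r, dtype=float), self._b_amplitude)

    def conformational_minimum(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.profile_kind == "flat":
            return np.full_like(r, self.c_closed)
        return self.c_closed + self.c_open * _sigmoid(
            (r - self.r_barrier) / self.conf_switch_width
        )

    # -- potential interface --------------------------------------------

    def _wall(self, r, c):
        # soft confinement outside the declared domain; zero inside, so the
        # in-domain landscape shape is untouched
        (rlo, rhi), (clo, chi) = self.domain
        terms = [np.clip(rlo - r, 0.0, None), np.clip(r - rhi, 0.0, None),
                 np.clip(clo - c, 0.0, None), np.clip(c - chi, 0.0, None)]
        return 10.0 * sum(t * t for t in terms)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        r, c = x[..., 0], x[..., 1]
        dc = c - self.conformational_minimum(r)
        return (self.minimized_profile(r) + 0.5 * self.k_conf * dc * dc
                + self._wall(r, c))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        r, c = x[..., 0], x[..., 1]
        g = np.zeros_like(x)
        (rlo, rhi), (clo, chi) = self.domain
        g[..., 0] = 20.0 * (np.clip(r - rhi, 0.0, None) - np.clip(rlo - r, 0.0, None))
        g[..., 1] = 20.0 * (np.clip(c - chi, 0.0, None) - np.clip(clo - c, 0.0, None))
        dc = c - self.conformational_minimum(r)
        dfdr = _axial_profile_deriv(
            r, self.depth, self.r_mid, self.well_width, self._b_amplitude,
            self.r_barrier, self.barrier_width,
        )
        if self.profile_kind == "barrier":
            s = _sigmoid((r - self.r_barrier) / self.conf_switch_width)
            dcmin = self.c_open * s * (1.0 - s) / self.conf_switch_width
        else:
            dcmin = 0.0
        g[..., 0] += dfdr - self.k_conf * dc * dcmin
        g[..., 1] += self.k_conf * dc
        return g

    def scalar_gradient(self):
        """Closure computing (dU/dr, dU/dc) in plain floats (hot-loop path)."""
        depth, r_mid, w = self.depth, self.r_mid, self.well_width
        b, rb, wb = self._b_amplitude, self.r_barrier, self.barrier_width
        kc, c0, copen, wc = (self.k_conf, self.c_closed, self.c_open,
                             self.conf_switch_width)
        barrier_kind = self.profile_kind == "barrier"
        (rlo, rhi), (clo, chi) = self.domain
        exp = math.exp

        def sig(z):
            if z >= 0:
                return 1.0 / (1.0 + exp(-z))
            e = exp(z)
            return e / (1.0 + e)

        def grad(r, c):
            s = sig((r - r_mid) / w)
            dfdr = depth * s * (1.0 - s) / w
            if b != 0.0:
                g = exp(-0.5 * ((r - rb) / wb) ** 2)
                dfdr -= b * (r - rb) / (wb * wb) * g
            if barrier_kind:
                sc = sig((r - rb) / wc)
                cmin = c0 + copen * sc
                dcmin = copen * sc * (1.0 - sc) / wc
            else:
                cmin = c0
                dcmin = 0.0
            dc = c - cmin
            gr = dfdr - kc * dc * dcmin
            gc = kc * dc
            if r < rlo:
                gr -= 20.0 * (rlo - r)
            elif r > rhi:
                gr += 20.0 * (r - rhi)
            if c < clo:
                gc -= 20.0 * (clo - c)
            elif c > chi:
                gc += 20.0 * (c - chi)
            return gr, gc

        return grad

    def parameters(self):
        return {
            "profile_kind": self.profile_kind,
            "depth": self.depth,
            "barrier_height": self.barrier_height if self.profile_kind == "barrier" else None,
            "r_barrier": self.r_barrier,
            "r_mid": self.r_mid,
            "well_width": self.well_width,
            "k_conf": self.k_conf,
            "c_open": self.c_open,
        }


@dataclass
class AxialChannelPotential(ToyPotential):
    """3-D point ligand: axial binding well plus transverse confinement.

    U(x, y, z) = f(x) + k_perp/2·(y² + z²)·h(x) where f is a Gaussian binding
    well on the unbinding axis and h(x) a smooth switch that is 1 in the
    binding site and 0 in bulk: the bound ligand is held near the axis with
    stiffness ``k_perp`` while the unbound ligand explores the funnel
    cross-section freely (the πR² area entering the standard-state
    correction).  Soft one-sided walls cap the axial coordinate so biased runs
    stay on the declared reaction-coordinate range.
    """

    depth: float = 10.0
    well_center: float = 5.0
    well_width: float = 0.7
    k_perp: float = 15.0
    switch_x: float = 9.0
    switch_width: float = 0.8
    wall_lo: float = 2.0
    wall_hi: float = 23.5
    k_wall: float = 20.0
    form_id: str = "axial_channel"

    def __post_init__(self):
        if self.depth <= 0 or self.k_perp <= 0:
            raise ValueError("depth and k_perp must be > 0")
        self.dimensionality = 3
        self.domain = ((0.0, 25.0), (-30.0, 30.0), (-30.0, 30.0))

    def axial_profile(self, x):
        x = np.asarray(x, dtype=float)
        f = -self.depth * np.exp(-0.5 * ((x - self.well_center) / self.well_width) ** 2)
        below = np.clip(self.wall_lo - x, 0.0, None)
        above = np.clip(x - self.wall_hi, 0.0, None)
        return f + 0.5 * self.k_wall * (below * below + above * above)

    def _axial_deriv(self, x):
        x = np.asarray(x, dtype=float)
        d = (x - self.well_center) / self.well_width
        df = self.depth * d / self.well_width * np.exp(-0.5 * d * d)
        below = np.clip(self.wall_lo - x, 0.0, None)
        above = np.clip(x - self.wall_hi, 0.0, None)
        return df + self.k_wall * (above - below)

    def _switch(self, x):
        return _sigmoid((self.switch_x - np.asarray(x, dtype=float)) / self.switch_width)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        ax, y, z = x[..., 0], x[..., 1], x[..., 2]
        rho2 = y * y + z * z
        return self.axial_profile(ax) + 0.5 * self.k_perp * rho2 * self._switch(ax)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        ax, y, z = x[..., 0], x[..., 1], x[..., 2]
        rho2 = y * y + z * z
        h = self._switch(ax)
        g = np.zeros_like(x)
        dh = -h * (1.0 - h) / self.switch_width
        g[..., 0] = self._axial_deriv(ax) + 0.5 * self.k_perp * rho2 * dh
        g[..., 1] = self.k_perp * y * h
        g[..., 2] = self.k_perp * z * h
        return g

    def parameters(self):
        return {
            "depth": self.depth, "well_center": self.well_center,
            "well_width": self.well_width, "k_perp": self.k_perp,
            "switch_x": self.switch_x,
        }

    def scalar_gradient(self):
        """Closure computing the gradient in plain floats (hot-loop path)."""
        depth, x0, w = self.depth, self.well_center, self.well_width
        kp, sx, sw = self.k_perp, self.switch_x, self.switch_width
        lo, hi, kw = self.wall_lo, self.wall_hi, self.k_wall
        exp = math.exp

        def grad(x, y, z):
            d = (x - x0) / w
            gx = depth * d / w * exp(-0.5 * d * d)
            if x < lo:
                gx -= kw * (lo - x)
            elif x > hi:
                gx += kw * (x - hi)
            t = (sx - x) / sw
            if t >= 0:
                h = 1.0 / (1.0 + exp(-t))
            else:
                e = exp(t)
                h = e / (1.0 + e)
            rho2 = y * y + z * z
            gx += -0.5 * kp * rho2 * h * (1.0 - h) / sw
            return gx, kp * y * h, kp * z * h

        return grad


@dataclass
class Angle1DPotential(ToyPotential):
    """1-D effective potential for an angular coordinate (degrees).

    ``U(φ) = k/2·Δφ² − kBT·ln sin(φ)·[jacobian]``, where Δφ is the (optionally
    periodic) deviation from the centre.  Folding the sin φ Jacobian of polar
    angles into the effective potential makes a 1-D Langevin walker sample the
    physical marginal density, so the resulting PMF feeds directly into the
    Boltzmann-factor restraint integrals.
    """

    center: float
    k: float
    kt: float = 0.61603
    jacobian: bool = False
    periodic: bool = False
    lo: float = 0.0
    hi: float = 180.0
    form_id: str = "angle1d"

    def __post_init__(self):
        self.dimensionality = 1
        self.domain = ((self.lo, self.hi),)

    def _dev(self, phi):
        d = phi - self.center
        if self.periodic:
            d = (d + 180.0) % 360.0 - 180.0
        return d

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        phi = x[..., 0]
        d = self._dev(phi)
        u = 0.5 * self.k * d * d
        if self.jacobian:
            s = np.sin(np.clip(np.radians(phi), 1e-9, math.pi - 1e-9))
            u = u - self.kt * np.log(s)
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        phi = x[..., 0]
        g = np.zeros_like(x)
        g[..., 0] = self.k * self._dev(phi)
        if self.jacobian:
            rad = np.clip(np.radians(phi), 1e-9, math.pi - 1e-9)
            g[..., 0] -= self.kt / np.tan(rad) * (math.pi / 180.0)
        return g

    def parameters(self):
        return {"center": self.center, "k": self.k, "jacobian": self.jacobian,
                "periodic": self.periodic}


class TabulatedPotential(ToyPotential):
    """1-D potential defined by values on a dense grid (cubic-spline interp)."""

    form_id = "tabulated"

    def __init__(self, grid: np.ndarray, values: np.ndarray):
        from scipy.interpolate import CubicSpline

        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or grid.size < 4 or grid.shape != values.shape:
            raise ValueError("grid/values must be matching 1-D arrays (n ≥ 4)")
        self._spline = CubicSpline(grid, values)
        self._deriv = self._spline.derivative()
        self.grid = grid
        self.values = values
        self.dimensionality = 1
        self.domain = ((float(grid[0]), float(grid[-1])),)

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self._spline(np.clip(x[..., 0], self.grid[0], self.grid[-1]))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 0] = self._deriv(np.clip(x[..., 0], self.grid[0], self.grid[-1]))
        return g


class SumPotential(ToyPotential):
    """Sum of potentials sharing one coordinate space."""

    form_id = "sum"

    def __init__(self, *terms: ToyPotential):
        if not terms:
            raise ValueError("need at least one term")
        self.terms = terms
        self.dimensionality = terms[0].dimensionality
        self.domain = terms[0].domain

    def energy(self, x):
        return sum(t.energy(x) for t in self.terms)

    def gradient(self, x):
        g = self.terms[0].gradient(x)
        for t in self.terms[1:]:
            g = g + t.gradient(x)
        return g


@dataclass
class HarmonicRestraintTerm(ToyPotential):
    """Harmonic bias on one coordinate index, optionally periodic (degrees)."""

    index: int
    center: float
    k: float
    periodic: bool = False
    form_id: str = "harmonic_restraint"

    def __post_init__(self):
        self.dimensionality = self.index + 1
        self.domain = ()

    def _dev(self, v):
        d = v - self.center
        if self.periodic:
            d = (d + 180.0) % 360.0 - 180.0
        return d

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d = self._dev(x[..., self.index])
        return 0.5 * self.k * d * d

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., self.index] = self.k * self._dev(x[..., self.index])
        return g


@dataclass
class SoftWalls(ToyPotential):
    """One-sided quadratic walls keeping a walker inside per-dim bounds."""

    bounds: tuple
    k_wall: float = 100.0
    form_id: str = "soft_walls"

    def __post_init__(self):
        self.bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        self.dimensionality = len(self.bounds)
        self.domain = self.bounds

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        u = np.zeros(x.shape[:-1], dtype=float)
        for i, (lo, hi) in enumerate(self.bounds):
            below = np.clip(lo - x[..., i], 0.0, None)
            above = np.clip(x[..., i] - hi, 0.0, None)
            u = u + 0.5 * self.k_wall * (below * below + above * above)
        return u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for i, (lo, hi) in enumerate(self.bounds):
            below = np.clip(lo - x[..., i], 0.0, None)
            above = np.clip(x[..., i] - hi, 0.0, None)
            g[..., i] = self.k_wall * (above - below)
        return g


def make_binding_landscape(profile_kind: str, **params) -> BindingLandscape:
    """Build a 2-D separation×conformation landscape.

    Parameters
    ----------
    profile_kind:
        ``'barrier'`` for the induced-fit topology with a dissociation barrier
        in the 4–8 Å region, ``'flat'`` for a decoupled monotone well.
    params:
        Forwarded to :class:`BindingLandscape` (depth, barrier_height, ...).
    """
    return BindingLandscape(profile_kind=profile_kind, **params)


_FORMS: dict[str, Callable[..., ToyPotential]] = {
    "harmonic": HarmonicPotential,
    "double_well": DoubleWellPotential,
    "binding_landscape": BindingLandscape,
    "axial_channel": AxialChannelPotential,
    "angle1d": Angle1DPotential,
}


def make_potential(form_id: str, **params) -> ToyPotential:
    """Instantiate a registered functional family by name (config entry point)."""
    try:
        ctor = _FORMS[form_id]
    except KeyError:
        raise ValueError(
            f"unknown potential form {form_id!r}; known: {sorted(_FORMS)}"
        ) from None
    return ctor(**params)


def check_gradient(potential: ToyPotential, points: np.ndarray,
                   rel_tol: float = 1e-5, h: float = 1e-5) -> float:
    """Max relative mismatch between analytic gradient and central differences."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    worst = 0.0
    for p in points:
        g = np.asarray(potential.gradient(p), dtype=float)
        num = np.zeros_like(g)
        for i in range(p.size):
            dp = p.copy(); dm = p.copy()
            dp[i] += h; dm[i] -= h
            num[i] = (potential.energy(dp) - potential.energy(dm)) / (2 * h)
        scale = max(float(np.max(np.abs(g))), float(np.max(np.abs(num))), 1e-3)
        worst = max(worst, float(np.max(np.abs(g - num))) / scale)
    if worst > rel_tol:
        raise AssertionError(
            f"gradient mismatch {worst:.2e} exceeds rel tol {rel_tol:.1e}"
        )
    return worst
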