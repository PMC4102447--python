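"""Integrated toy binding systems with quadrature oracles.

Two linked representations of one synthetic binding problem:

* :class:`WooRouxToy` — a separable restraint-decomposition system: a
  Gaussian separation well W(r), a conformational coordinate c, and five
  restraint angles (α, β, γ with the bulk-orientation role; θ, Θ with the
  translational role).  Native site potentials hold the ligand's
  conformation and orientation when bound and switch off smoothly in bulk;
  harmonic restraints act on every coordinate during the separation stage.
  Because the system is separable, every configuration integral reduces to
  products of 1-D quadratures, so the exact binding constant — and therefore
  the exact standard-state ΔG — is available as an oracle for the full
  sampled pipeline.

* the matched funnel system (:meth:`WooRouxToy.funnel_potential`) — a 3-D
  point ligand sharing the same axial well, transversally confined in the
  site with a stiffness chosen so that its exact binding constant equals the
  restraint toy's.  Funnel metadynamics on this system and the
  umbrella-sampling route on the restraint toy therefore measure the same
  ΔG, which is what makes the two routes comparable.

All landscape parameters are artifact choices (the source study used an
all-atom kinase complex, not a reference toy); they are chosen so that every
stage is well-conditioned at desk scale and are documented in the package's
methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .abf import AbfEstimator, run_abf
from .assembly import (HarmonicRestraint, RestraintComponents, RestraintPmfSet,
                       assemble_components)
from .conditions import SimulationConditions
from .potentials import (Angle1DPotential, AxialChannelPotential,
                         HarmonicPotential, TabulatedPotential, ToyPotential)
from .sampling import LangevinParams
from .umbrella import Profile1D, WindowLadder, make_ladder, run_umbrella, wham
from .metad import CoordinateCV

__all__ = ["AngleSpec", "WooRouxToy"]


def _sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class AngleSpec:
    """One restrained angle: native site potential + separation-stage restraint."""

    center: float        # degrees
    k_native: float      # kcal/mol/deg², native site potential (off in bulk)
    k_restraint: float   # kcal/mol/deg²
    polar: bool          # True → [0°,180°] with sinφ Jacobian (α, θ)
    abf_range: tuple[float, float]  # sampled window for the ABF stage


@dataclass
class WooRouxToy:
    """Separable toy system for the restraint-decomposed binding free energy."""

    conditions: SimulationConditions = field(default_factory=SimulationConditions)

    # separation well W(r) = −depth·exp(−(r−r0)²/(2σ²)); bulk flat at 0
    depth: float = 10.0
    r0: float = 5.0
    well_width: float = 1.6
    r_min: float = 4.0
    r_max: float = 25.0
    # native site potentials switch off across r = switch_x (bound → bulk)
    switch_x: float = 12.0
    switch_width: float = 0.8

    # conformational coordinate (unbounded toy analog of a ligand RMSD)
    c_site_center: float = 1.5
    k_c_site: float = 2.0
    c_bulk_center: float = 2.5
    k_c_bulk: float = 0.5
    k_r_conf: float = 2.0

    site_range: tuple[float, float] = (4.5, 10.0)
    bulk_range: tuple[float, float] = (16.0, 23.0)
    r_star: float = 24.0

    # ABF windows span ±50–52° around each centre: wide enough that the
    # combined native+restraint Boltzmann weight at the window edge is < 1e-6
    # of its maximum, narrow enough to fill at desk-scale run lengths
    angles: dict[str, AngleSpec] = field(default_factory=lambda: {
        "alpha": AngleSpec(65.0, 0.004, 0.005, True, (15.0, 115.0)),
        "beta": AngleSpec(30.0, 0.003, 0.004, False, (-22.0, 82.0)),
        "gamma": AngleSpec(-45.0, 0.003, 0.004, False, (-97.0, 7.0)),
        "theta": AngleSpec(70.0, 0.004, 0.005, True, (20.0, 120.0)),
        "Theta": AngleSpec(100.0, 0.003, 0.004, False, (48.0, 152.0)),
    })

    # -- analytic pieces ---------------------------------------------------

    def separation_well(self, r):
        r = np.asarray(r, dtype=float)
        return -self.depth * np.exp(-0.5 * ((r - self.r0) / self.well_width) ** 2)

    def switch(self, r):
        """Native-potential scale h(r): 1 bound, 0 in bulk."""
        return _sigmoid((self.switch_x - np.asarray(r, dtype=float)) / self.switch_width)

    def restraints(self) -> dict[str, HarmonicRestraint]:
        out = {"conf": HarmonicRestraint(self.c_site_center, self.k_r_conf)}
        for name, a in self.angles.items():
            out[name] = HarmonicRestraint(a.center, a.k_restraint,
                                          periodic=not a.polar)
        return out

    # -- per-dof partition functions (vectorised over the switch value) -----

    def _angle_partition(self, name: str, h: np.ndarray,
                         with_restraint: bool, n: int = 2001) -> np.ndarray:
        """∫ jac·e^{−β(h·v_nat + u_r)} dφ in radians, for each switch value h."""
        a = self.angles[name]
        beta = self.conditions.beta
        if a.polar:
            phi = np.linspace(1e-6, math.pi - 1e-6, n)
            jac = np.sin(phi)
        else:
            phi = np.linspace(-math.pi, math.pi, n)
            jac = np.ones(n)
        deg = np.degrees(phi)
        d = deg - a.center
        if not a.polar:
            d = (d + 180.0) % 360.0 - 180.0
        b_nat = beta * 0.5 * a.k_native * d * d
        w = jac.copy()
        if with_restraint:
            u = HarmonicRestraint(a.center, a.k_restraint, periodic=not a.polar)
            w = w * np.exp(-beta * u.energy(deg))
        h = np.atleast_1d(np.asarray(h, dtype=float))
        vals = np.trapezoid(w[None, :] * np.exp(-np.outer(h, b_nat)), phi, axis=1)
        return vals

    def _conf_partition(self, h: np.ndarray, with_restraint: bool,
                        n: int = 2001) -> np.ndarray:
        """∫ e^{−β(h·u_site + (1−h)·u_bulk + u_r)} dc for each switch value."""
        beta = self.conditions.beta
        c = np.linspace(-6.0, 10.0, n)
        u_site = 0.5 * self.k_c_site * (c - self.c_site_center) ** 2
        u_bulk = 0.5 * self.k_c_bulk * (c - self.c_bulk_center) ** 2
        base = beta * u_bulk
        if with_restraint:
            base = base + beta * 0.5 * self.k_r_conf * (c - self.c_site_center) ** 2
        h = np.atleast_1d(np.asarray(h, dtype=float))
        expo = -base[None, :] - np.outer(h, beta * (u_site - u_bulk))
        return np.trapezoid(np.exp(expo), c, axis=1)

    # -- quadrature PMFs (the "exact" inputs for the assembly oracle) -------

    def site_pmf(self, name: str, n: int = 2001) -> Profile1D:
        """Exact bound-state PMF of one restrained coordinate (h = 1)."""
        kt = self.conditions.kt
        if name == "rmsd_site":
            c = np.linspace(-2.5, 5.5, n)
            w = 0.5 * self.k_c_site * (c - self.c_site_center) ** 2
            return Profile1D(c, w)
        if name == "rmsd_bulk":
            c = np.linspace(-4.0, 9.0, n)
            w = 0.5 * self.k_c_bulk * (c - self.c_bulk_center) ** 2
            return Profile1D(c, w)
        a = self.angles[name]
        lo, hi = a.abf_range
        phi = np.linspace(lo, hi, n)
        w = 0.5 * a.k_native * (phi - a.center) ** 2
        if a.polar:
            w = w - kt * np.log(np.sin(np.radians(np.clip(phi, 1e-6, 180 - 1e-6))))
        return Profile1D(phi, w - w.min())

    def separation_profile(self, n: int = 1051) -> Profile1D:
        """Exact restrained separation PMF W_r(r), bulk-referenced to 0.

        W_r(r) = W(r) − kB·T·ln[Q_rest(r)/Q_rest(bulk)] where Q_rest collects
        the restrained partition functions of all other coordinates at r.
        """
        kt = self.conditions.kt
        r = np.linspace(self.r_min, self.r_max, n)
        h = self.switch(r)
        q = self._conf_partition(h, True)
        for name in self.angles:
            q = q * self._angle_partition(name, h, True)
        q_bulk = self._conf_partition(np.array([0.0]), True)[0]
        for name in self.angles:
            q_bulk = q_bulk * self._angle_partition(name, np.array([0.0]), True)[0]
        w = self.separation_well(r) - kt * np.log(q / q_bulk)
        return Profile1D(r, w)

    def quadrature_pmfset(self) -> RestraintPmfSet:
        return RestraintPmfSet(
            rmsd_site=self.site_pmf("rmsd_site"),
            rmsd_bulk=self.site_pmf("rmsd_bulk"),
            alpha=self.site_pmf("alpha"),
            beta_dihedral=self.site_pmf("beta"),
            gamma=self.site_pmf("gamma"),
            theta=self.site_pmf("theta"),
            Theta=self.site_pmf("Theta"),
            separation=self.separation_profile(),
            restraints=self.restraints(),
        )

    def quadrature_components(self) -> RestraintComponents:
        return assemble_components(self.quadrature_pmfset(), self.r_star,
                                   self.site_range, self.conditions)

    # -- direct configuration-integral oracle --------------------------------

    def direct_kbind(self, n_r: int = 1501) -> float:
        """K_bind (Å³) by dense quadrature of the toy's configuration integrals.

        K = r*²/(8π²·C_b) · ∫_site dr e^{−βW(r)}·Q_nat(r) with Q_nat the
        product of the unrestrained per-coordinate partition functions at r
        and C_b the bulk conformational integral — no restraint bookkeeping
        involved, so this is an independent check of the assembled K_bind.
        """
        beta = self.conditions.beta
        r = np.linspace(self.site_range[0], self.site_range[1], n_r)
        h = self.switch(r)
        q = self._conf_partition(h, False)
        for name in self.angles:
            q = q * self._angle_partition(name, h, False)
        c_bulk = self._conf_partition(np.array([0.0]), False)[0]
        integrand = np.exp(-beta * self.separation_well(r)) * q
        integral = np.trapezoid(integrand, r)
        return float(self.r_star**2 / (8.0 * math.pi**2 * c_bulk) * integral)

    # -- stage potentials for the sampled pipeline ---------------------------

    def conf_site_potential(self) -> ToyPotential:
        return HarmonicPotential(k=[self.k_c_site], center=[self.c_site_center])

    def conf_bulk_potential(self) -> ToyPotential:
        return HarmonicPotential(k=[self.k_c_bulk], center=[self.c_bulk_center])

    def angle_potential(self, name: str) -> Angle1DPotential:
        a = self.angles[name]
        return Angle1DPotential(center=a.center, k=a.k_native,
                                kt=self.conditions.kt, jacobian=a.polar,
                                periodic=False)

    def separation_stage_potential(self, n: int = 1051) -> TabulatedPotential:
        prof = self.separation_profile(n)
        return TabulatedPotential(prof.rc, prof.free_energy)

    # -- sampled pipeline -----------------------------------------------------

    def conf_ladder(self, where: str) -> WindowLadder:
        if where == "site":
            return make_ladder("rmsd_site", -1.5, 4.5, 0.5, 2.0)
        return make_ladder("rmsd_bulk", -1.5, 6.5, 0.5, 2.0)

    def separation_ladder(self) -> WindowLadder:
        # 41 windows of 0.5 Å over 5–25 Å, k = 5 kcal/mol·Å²
        return make_ladder("separation", 5.0, 25.0, 0.5, 5.0)

    def sampled_pmfset(self, seed: int, quality: float = 1.0) -> RestraintPmfSet:
        """Run the staged pipeline (conformational US, angular ABF, separation US).

        ``quality`` scales all run lengths; the defaults target component
        errors of a few hundredths of kcal/mol in a couple of minutes.
        """
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
        cond = self.conditions

        def conf_stage(potential, ladder, sd) -> Profile1D:
            params = LangevinParams(timestep=0.01, friction=1.0,
                                    n_steps=int(200_000 * quality),
                                    seed=sd, save_stride=5)
            run_umbrella(potential, CoordinateCV("c", 0), ladder, params, cond)
            return wham(ladder, cond, bin_count=160).pmf

        pmf_site = conf_stage(self.conf_site_potential(), self.conf_ladder("site"),
                              seeds[0])
        pmf_bulk = conf_stage(self.conf_bulk_potential(), self.conf_ladder("bulk"),
                              seeds[1])

        angle_pmfs: dict[str, Profile1D] = {}
        for i, name in enumerate(self.angles):
            a = self.angles[name]
            est = AbfEstimator(lo=a.abf_range[0], hi=a.abf_range[1],
                               bin_width=0.2, ramp_threshold=200)
            params = LangevinParams(timestep=0.01, friction=0.01,
                                    n_steps=int(600_000 * quality),
                                    seed=seeds[2 + i], save_stride=50)
            run_abf(self.angle_potential(name), 0, est, params, cond,
                    x0=np.array([a.center]))
            from .abf import integrate_pmf
            angle_pmfs[name] = integrate_pmf(est)

        ladder = self.separation_ladder()
        params = LangevinParams(timestep=0.01, friction=1.0,
                                n_steps=int(400_000 * quality),
                                seed=seeds[7], save_stride=5)
        run_umbrella(self.separation_stage_potential(), CoordinateCV("r", 0),
                     ladder, params, cond)
        sep = wham(ladder, cond, bin_count=320).pmf

        return RestraintPmfSet(
            rmsd_site=pmf_site, rmsd_bulk=pmf_bulk,
            alpha=angle_pmfs["alpha"], beta_dihedral=angle_pmfs["beta"],
            gamma=angle_pmfs["gamma"], theta=angle_pmfs["theta"],
            Theta=angle_pmfs["Theta"], separation=sep,
            restraints=self.restraints(),
        )

    def sampled_components(self, seed: int, quality: float = 1.0) -> RestraintComponents:
        return assemble_components(self.sampled_pmfset(seed, quality),
                                   self.r_star, self.site_range, self.conditions)

    # -- matched funnel representation ---------------------------------------

    def lateral_area(self) -> float:
        """Effective bulk-per-site lateral area X = K_direct/∫_site e^{−βW} (Å²)."""
        beta = self.conditions.beta
        r = np.linspace(self.site_range[0], self.site_range[1], 1501)
        i_w = float(np.trapezoid(np.exp(-beta * self.separation_well(r)), r))
        return self.direct_kbind() / i_w

    def matched_k_perp(self) -> float:
        """Transverse stiffness giving the funnel system the same K_bind."""
        return 2.0 * math.pi * self.conditions.kt / self.lateral_area()

    def funnel_potential(self) -> AxialChannelPotential:
        """3-D funnel representation of the same binding problem."""
        return AxialChannelPotential(
            depth=self.depth, well_center=self.r0, well_width=self.well_width,
            k_perp=self.matched_k_perp(), switch_x=10.0, switch_width=0.5,
            wall_lo=2.0, wall_hi=23.5, k_wall=20.0,
        )

    def funnel_metad(self, radius: float, seed: int,
                     n_steps: int = 2_000_000, average_tail: float = 0.5):
        """Well-tempered funnel metadynamics on the matched 3-D system.

        Returns (ΔG_bind-Meta, profile, hills log, trajectory): the 1-D FES
        along the separation axis, its depth between ``site_range`` and
        ``bulk_range``, and the standard-state corrected binding free energy.
        """
        from .assembly import dg_bind_meta
        from .metad import (FunnelSpec, WellTemperedSchedule, reconstruct_fes,
                            run_metad)

        pot = self.funnel_potential()
        schedule = WellTemperedSchedule(omega=1.0, tau=1.0, delta_T=3100.0,
                                        sigmas=(0.4,))
        funnel = FunnelSpec(origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0),
                            radius=radius, wall_constant=100.0)
        params = LangevinParams(timestep=0.01, friction=1.0, n_steps=n_steps,
                                seed=seed, save_stride=100)
        log, traj = run_metad(
            pot, [CoordinateCV("r", 0)], schedule, funnel, params,
            self.conditions, grid=((pot.wall_lo, pot.wall_hi, 430),),
            x0=np.array([self.r0, 0.0, 0.0]),
        )
        fes = reconstruct_fes(log, self.conditions, average_tail=average_tail)
        profile = Profile1D(fes.axes[0], fes.free_energy)
        dg = dg_bind_meta(profile, funnel, self.site_range, self.bulk_range,
                          self.conditions)
        return dg, profile, log, traj
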