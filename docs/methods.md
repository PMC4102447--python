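# Methods

This note documents the models, defaults and numerical choices behind
`bindfe`: what each estimator computes, what the synthetic systems emulate,
and where genuinely open design decisions were settled.

## Units and conditions

Energies in kcal/mol, lengths in Å, angles in degrees (angular quadratures
run in radians internally), time in ps.  kB = 0.0019872041 kcal/mol/K,
T = 310 K by default (kB·T = 0.61603 kcal/mol), and the standard
concentration C° = 1 M corresponds to 1661 Å³ per molecule.  These choices
make the published decomposition-table arithmetic exact.

## Dynamics: overdamped Langevin

All samplers use Euler–Maruyama for the overdamped (Brownian) limit,

    x(t+Δt) = x(t) − (Δt/γ)·∇U + √(2·kB·T·Δt/γ)·ξ,

with defaults Δt = 0.01 ps and γ = 1 ps⁻¹ (γ = 0.01 for angular
coordinates, whose effective stiffnesses per degree² are ~100× smaller).
Inertial thermostats, constraints and barostats are irrelevant at toy scale.
The integrator is exact for free diffusion and inflates the variance of a
harmonic mode by 1/(1 − k·Δt/2γ); the stiffest default mode
(k ≈ 18 kcal/mol/Å²) therefore carries a ~9% variance bias, worth
≈ 0.05 kcal/mol in the funnel-toy transverse partition function — well
inside the tolerances used anywhere.  Seeded runs are bit-reproducible; all
stage seeds derive from one `numpy.random.SeedSequence`.

## Synthetic binding landscapes

`make_binding_landscape` builds the 2-D separation × conformation surfaces:

* radial profile: a sigmoidal well of depth `depth` (default 5 kcal/mol)
  flattening to a bulk plateau (flat to < 0.01 kcal/mol beyond 15 Å), plus,
  for the `barrier` kind, a Gaussian barrier near r = 6 Å whose amplitude is
  calibrated at construction (Brent root-find on a dense grid) so that
  max − min of the conformationally minimised profile equals
  `barrier_height` exactly;
* induced fit: the conformational minimum c_min(r) switches sigmoidally
  from a closed value (0.8) to an open value (0.8 + 1.6) across the barrier
  region, so crossing the saddle requires a conformational displacement —
  the `flat` kind decouples c entirely;
* soft harmonic walls act only outside the declared domain, leaving the
  in-domain landscape untouched.

All landscape parameters are artifact choices: the study this machinery
reimplements ran on an all-atom kinase–inhibitor complex and published no
reference toy.  Parameters were picked once so that every stage is
well-conditioned at desk scale (wells of 4–10 kcal/mol, barriers within the
4–8 Å region, run lengths of seconds to a minute).

## Collective variables

Centre-of-mass distance, interior angle, signed dihedral (IUPAC convention:
positive for clockwise rotation of the far bond viewed along the central
bond; the source material states no convention), MSD/RMSD without
superposition fit (toy frames are generated pre-aligned — a deliberate
simplification versus all-atom practice), funnel radial distance, and the
path-progress CV

    s(R) = Σᵢ mᵢ·e^{−λ·MSDᵢ} / Σᵢ e^{−λ·MSDᵢ},   mᵢ = (i−1)·spacing,

reported on the MSD scale [0, (P−1)·spacing] Å² with the defaults P = 7 and
spacing = 1 Å².  λ defaults to the standard even-spacing heuristic
2.3/spacing; at that smoothing the interior milestones are reproduced within
5% of the spacing while the two endpoint frames are biased inward by
e^{−2.3}/(1+e^{−2.3}) ≈ 0.09·spacing — an analytic property of the
one-sided endpoint sums, documented rather than hidden by a stiffer λ.
Reference paths are linear interpolations with exact consecutive-frame MSD
spacing, which makes the endpoint-to-endpoint MSD grow quadratically,
(P−1)²·spacing.  Dihedral histograms bin circularly with one bin centred on
±180°.

## Well-tempered funnel metadynamics

Hills of initial height ω = 1 kcal/mol are deposited every τ = 1 ps with
widths σ = (0.4 Å, 0.05 Å²) and height scaling exp(−V/(kB·ΔT)),
ΔT = 3100 K.  The bias-factor convention is γ = ΔT/T (= 10 at 310 K); ΔT is
authoritative and `WellTemperedSchedule.from_bias_factor` exposes the other
spelling.  The FES estimator is F(s) = −(T+ΔT)/ΔT·V(s,t) (scale 1.1 at the
defaults).  `reconstruct_fes(average_tail=f)` optionally replaces the
final-time bias with its time average over the last fraction f of
deposition times — the standard variance-reduced estimator with the same
asymptote; the convergence-sensitive toy studies use f = 0.5–0.75.

The running bias and its CV-derivatives are accumulated on the FES grid
(default 400 bins over 0–24 Å × 350 bins over 0–6 Å²) at deposition time
with a 6σ patch cutoff (per-hill truncation below ω·e⁻¹⁸) and looked up by
multilinear interpolation during dynamics.  Hills landing outside the grid
are clamped to its edge and counted.  The cylindrical funnel applies a
one-sided harmonic wall (k/2)(d−R)² beyond radius R (defaults R = 15 Å,
k = 100 kcal/mol·Å²).  The anti-drift restraints used for solvated protein
systems have no analog here: toy systems have no drift mode.

Convergence is diagnosed by completed bound→unbound→bound cycles with
hysteresis thresholds (`recrossing_count`); pipeline runs flag fewer than
10 cycles as non-converged but still write outputs.

### Standard-state correction

With the unbound ligand confined to the funnel cross-section πR², each
ångström of bulk plateau holds it at concentration 1/(πR²·1 Å).  Writing
K = πR²·∫_site e^{−βF(r)}dr and ΔG° = −kB·T·ln(K·C°), replacing the site
integral by the PMF depth gives

    ΔG_bind-Meta = −depth − kB·T·ln(π·R²·C°·1 Å) = −depth + 0.526 kcal/mol

at R = 15 Å and 310 K.  The sign follows from the algebra: π·225 Å²·Å is
*smaller* than 1661 Å³, the funnel over-concentrates the unbound state, and
the correction must weaken binding.  Only this sign makes the corrected ΔG
independent of R (verified across R ∈ {10, 15, 20} Å) and consistent with
the restraint-route ΔG; the magnitude matches the value quoted in the
funnel-metadynamics literature.  The implicit 1 Å length that makes the
logarithm dimensionless is absorbed into the depth-for-integral
approximation, which is exact when the site well's Boltzmann width
∫e^{−β(F−F_min)}dr equals 1 Å; the funnel toy's well width (1.6 Å Gaussian,
Boltzmann width ≈ 0.91 Å) keeps the approximation error below
0.1 kcal/mol.

## Umbrella sampling and WHAM

Windows are harmonic, (k/2)(ξ−ξ_ref)².  Ladders are inclusive of both
endpoints — 5–25 Å at 0.5 Å gives 41 windows (the arithmetic-consistent
reading where the source material says both 40 and 41).  Defaults: burn-in
50% (keep the second half of each window), separation constant
5 kcal/mol·Å².  Window seeding from a metadynamics trajectory picks the
frame with the nearest CV value, earliest frame on ties.

WHAM iterates the standard self-consistent equations on shared bins
(default 200; the default bin range clips the 5·10⁻⁴ sample quantiles so
stray outliers cannot open empty edge bins), offsets initialised at zero,
tolerance 10⁻⁷ kcal/mol on the offsets, 10⁵ iteration cap.  Disconnected
occupied-bin coverage raises an error (unstitchable ladder).  In the
single-window zero-bias limit the solver reduces exactly to Boltzmann
inversion of the histogram.  Window uncertainty, where reported, comes from
block averaging over 4 blocks.

The published umbrella constant for the conformational (ligand-RMSD) stage,
0.01 kcal/mol·Å², is anomalously weak and its units ambiguous; it is kept
fully configurable and not asserted to be meaningful.  The toy's
conformational ladders use k = 2 kcal/mol·Å² with window ranges matched to
the toy coordinate so that the sampled PMF support covers the restraint
Boltzmann weight to the 10⁻⁶ level required by the assembly integrals.

## Adaptive biasing force

1-D estimator with 0.2-unit bins and one window per angle.  The
instantaneous force −∂U/∂ξ is projected directly on the coordinate CV (the
extended-Lagrangian fictitious-particle construction used for all-atom
angular CVs is out of scope at toy scale).  The applied bias force cancels
the running mean-force estimate, ramped linearly until a bin holds 200
samples (standard practice; no published value).  PMFs follow by trapezoid
integration of −⟨F⟩ over the contiguous sampled bins; interior gaps raise,
and periodic CVs report the end-to-end closure mismatch.  Angular stage
constants (1 kcal/mol·Å² conformational, then 0.3 on the angles, units
ambiguous as published) are treated as kcal/mol per (CV unit)².

## The Woo–Roux assembly

Each restraint free energy is a Boltzmann-factor integral over its PMF,

    ΔG = −kB·T·ln[∫e^{−β(w+u_r)}dξ / ∫e^{−βw}dξ] ≥ 0,

rejected as truncated if the restrained weight at a PMF boundary exceeds
10⁻⁶ of its maximum.  The bulk orientational term integrates
e^{−β(u_α+u_β+u_γ)}·sinα over the full Euler domain normalised by 8π²
(isotropic bulk, no simulation).  S* = r*²·∫∫e^{−β·u_t}·sinθ dθ dΘ adopts
the convention that the r² Jacobian lives in S* (the published table cannot
discriminate); r* defaults to the bulk end of the separation coordinate.
I* integrates e^{−β(W−W_bulk)} over the site range, with the bulk reference
taken as the mean over the last 2 Å of the profile, required flat to
0.05 kcal/mol/Å.  Quadratures are composite trapezoid with ≥ 1000 points
per dimension and a doubled-resolution Richardson check that warns below
3-digit convergence.

The K_bind algebra (the equation bodies are not machine-readable in the
source material) was fixed by requiring the published table to be
internally consistent; it reproduces both printed K_bind values to 3
significant figures and is verified independently against dense direct
quadrature on the separable toy (agreement ~0.04%, tolerance 5%).

ΔΔG columns follow the published row conventions exactly: restraint
component rows print (mutant − wild-type); the separation-PMF and total ΔG
rows (ΔG_bind-US, ΔG_off, ΔG_bind-Meta) print (wild-type − mutant).  The
published table itself mixes these conventions and the report reproduces it
as printed.

## The quadrature-checkable toy (`WooRouxToy`)

A separable model of one binding problem: a Gaussian separation well
(depth 10 kcal/mol at r = 5 Å, width 1.6 Å, flat bulk), a conformational
coordinate with distinct bound/unbound native potentials, and five
restrained angles (α, θ polar with sinφ Jacobian; β, γ, Θ dihedral-like)
whose native site potentials switch off sigmoidally across r = 12 Å.
Because every degree of freedom factorises, the exact binding constant is a
product of 1-D quadratures (`direct_kbind`) — the oracle for the whole
pipeline.  Polar-angle stages fold −kB·T·ln sinφ into the effective 1-D
potential so a 1-D walker samples the physical marginal.

The separation stage samples the exact restrained marginal
W_r(r) = W(r) − kB·T·ln[Q_rest(r)/Q_rest(bulk)] as a tabulated 1-D
potential (cubic spline); in a full simulation this marginalisation is done
by the dynamics itself, here it is done by quadrature once — the sampled
route still exercises every estimator on every stage.

The funnel representation shares the same axial well, with transverse
confinement k_perp chosen so that its exact binding constant equals the
restraint toy's (k_perp = 2π·kB·T/X with X the toy's effective lateral
area, ≈ 18 kcal/mol/Å² at the defaults).  This is what "the same toy
landscape" means for the two-route comparison; it is a construction, not a
fit to any measured outcome.

What the toys do *not* emulate: solvent friction anisotropy, multiple
unbinding pathways, CV hysteresis from hidden slow modes, force-field
error, and sampling noise at all-atom cost.  Passing tests therefore
validate the estimators and the bookkeeping, not the ability of these
methods to converge on a real protein.

## Problem sizes

The validation studies use: 6·10⁵ steps for the double-well metadynamics
recovery (RMS ≈ 0.16–0.23 kcal/mol against the analytic well, threshold
0.3); 21 windows × 1.5·10⁶ steps at Δt = 0.002 for WHAM (RMS ≈ 0.08,
threshold 0.15 — the smaller timestep keeps the Euler variance bias of the
stiffest window modes, k_eff ≈ 33 kcal/mol/Å², out of the recovered
barrier); 7·10⁵ ABF steps with 0.1-unit bins on the steep double well
(RMS ≈ 0.02 versus the analytic well; the 0.2 default bin width would leave
a ~0.13 within-bin Boltzmann-skew systematic there, while the gentle
angular stages are insensitive); 2–4·10⁵ steps per stage for the staged toy
route (ΔG within ~0.1 kcal/mol of the oracle); and 8·10⁶ steps per funnel
run (route agreement ≈ 0.05–0.3 kcal/mol, radius spread ≈ 0.03–0.3
kcal/mol, thresholds 0.5).  These sizes were chosen as the package's own
validation conditions: small enough to run in minutes on one CPU, large
enough that the statistical plus discretisation error sits well inside each
threshold.

## Known limitations

* Overdamped Euler–Maruyama carries O(k·Δt) sampling bias on stiff modes;
  stiff stages use smaller Δt/γ but the bias is not extrapolated away.
* The metadynamics FES error is dominated by hill corrugation; the
  tail-averaged estimator reduces but does not eliminate it, and the
  min-based PMF depth is biased slightly downward by noise at the site
  minimum.
* WHAM bins are unweighted within bins (no M-estimator refinement), and
  ABF ignores within-bin density skew at bin edges.
* The separable toy cannot probe errors that arise from coupling between
  restrained coordinates, which real systems have.
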