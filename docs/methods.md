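# Methods

`nucleophase` simulates the coupled dynamics of a phase-separating nuclear
protein and actively transcribed RNA in a 2-D circular nuclear domain, and
provides the equilibrium and analytical theory needed to interpret the
simulations.  This note records the model, the numerical choices, the
calibration of defaults, and the limits of what the test suite shows.

## Model

Two coarse-grained pseudospecies live on the domain: a protein
concentration field phi_P and an RNA concentration field phi_R.  The bulk
free-energy density is

    f = rho_P (phi_P - alpha)^2 (phi_P - beta)^2
        - chi phi_P phi_R + c phi_P^2 phi_R^2 + rho_R phi_R^2

plus a square-gradient surface energy (kappa/2)|grad phi_P|^2.  The double
well drives protein demixing with binodals alpha = 0.1 (dilute) and
beta = 0.7 (dense).  The linear heterotypic term (chi) makes small amounts
of RNA stabilise the dense phase; the quartic term (c) penalises high
joint concentrations, so RNA in excess re-dissolves the dense phase —
together they produce the re-entrant dependence of protein partitioning on
the RNA:protein ratio.  rho_R keeps the RNA field thermodynamically
well behaved.

Protein is conserved and relaxes by Model B dynamics,
dphi_P/dt = M_p lap(delta F / delta phi_P); RNA obeys reaction-diffusion
dynamics, dphi_R/dt = M_r lap(phi_R) + k_p(x) phi_P - k_d phi_R, with
production proportional to the local protein concentration (transcription
is catalysed by the protein machinery) and a spatially clustered rate
constant k_p(x): a Gaussian of total activity k_T and extent sigma, or a
uniform field with the same total as the declustered control.  Both
species carry no-flux boundary conditions on the circular wall.

## Equilibrium coexistence

Two-phase equilibria satisfy equal protein chemical potential, equal RNA
chemical potential, equal osmotic pressure Pi = f - mu_P phi_P -
mu_R phi_R, and the two lever-rule closures for the overall composition;
five equations for the four phase compositions and the dense-phase volume
fraction nu.  The solver uses the Powell hybrid trust-region method with
warm-started continuation along composition scans, and accepts a root only
if the phases are distinct (gap > 1e-3), locally stable (positive Hessian
determinant), nonnegative, and the residual is below 1e-8.

The polynomial free energy has no entropic barrier at zero concentration,
so at small total RNA the interior root places *negative* RNA in the light
phase.  The physical equilibrium there lies on the boundary of the
composition simplex: the solver falls back to a constrained branch with
phi_R_light = 0 in which the RNA chemical-potential equality is replaced
by the complementary-slackness inequality mu_R(light) >= mu_R(dense).
This makes the zero-RNA limit coincide exactly with the pure double well
and produces a clean rise-and-fall (re-entrant) enrichment curve.

## Numerical scheme

Space: a cell-centred Cartesian grid masked to the disk (reference
geometry radius 30, spacing 0.2; reduced test geometry radius 15, spacing
0.4).  The 5-point graph Laplacian simply omits out-of-domain neighbours,
which is exactly the zero-flux condition; its rows and columns sum to
zero, so any update routed through it conserves mass to solver precision.

Time: backward-Euler steps solved by chord-Newton "sweeps".  Each sweep
solves the sparse linear system

    (I - dt M_p L D + dt M_p kappa L^2) phi^(s+1)
        = phi^n + dt M_p L (mu_b(phi^s) - D phi^s)

where D = diag(d2f/dphi_P^2) is the local linearisation of the bulk
chemical potential and the biharmonic surface term is fully implicit.  The
LU factorisation of the left-hand side is reused across sweeps *and*
across steps while sweeps still contract (near steady state one factor
serves for hundreds of steps); when sweeps stall the matrix is rebuilt at
the current fields, and only if that also fails is the step rejected and
dt halved.  Sweeps iterate to an infinity-norm residual of 1e-6 (at most
5 per attempt).  The RNA update is a single implicit linear solve with
production evaluated at the end-of-step protein field, which makes the
discrete production/degradation balance exact at the endpoint values.

Adaptive stepping: dt starts at 0.05, grows by 1.1 per accepted step to a
cap of 0.5, halves on rejection, aborts below 1e-4.  A run stops at its
step budget (reference 15,000; test scale <= 2,000-3,000) or when the
maximum rate of change max|dphi|/dt stays below 1e-6 for 50 consecutive
steps; the stop reason is recorded in the trajectory metadata.

Negative transient concentrations are tolerated (the polynomial energy is
defined there; clipping would break conservation); the integrator only
monitors the running minimum and rejects a step if phi_P drops below
-0.05.

## Calibrated defaults

The double well is fixed at rho_P = 1, alpha = 0.1, beta = 0.7.  The
coupling constants are a package calibration, chosen once so that the
model exhibits the full phenomenology and then frozen:

- chi = 0.6, c = 1.6, rho_R = 0.4.  With these, the partition scan at
  total protein 0.4 rises from enrichment 7 (no RNA) to ~15 at total RNA
  ~0.09, falls back, and is single-phase by total RNA ~3 (the calibration
  scan is versioned at docs/calibration_log.csv and regenerated by
  scripts/calibrate_free_energy.py).  c = 1.6 also places the
  dense-to-vacuole composition path inside the spinodal, so core-shell
  states show the two unstable det(J) < 0 bands expected of dual
  interfaces; at weaker repulsion the crater is smoothly graded and only
  one band appears.
- kappa = 0.08: a relaxed 1-D interface has a tanh profile of 10-90%
  width ~1.5 length units, about 7 cells at the reference spacing and
  ~4 at the test spacing — resolved but sharp.

Kinetics default to M_p = M_r = 1 and k_d = 0.5 (the distal-activity flow
study's stated mobility and turnover), giving an RNA decay length
sqrt(M_r/k_d) ~ 1.4 length units.  Nucleation and vacuole formation
require RNA no more mobile than protein; raising M_r/M_p much above one
removes them.

## Scenario conditions

The presets encode the study conditions at two scales (reference: radius
30, dx 0.2, 15,000 steps; test: radius 15, dx 0.4, <= 2,000-3,000 steps).
Seeded droplets start at phi_P = 0.63 inside and 0.13 outside with RNA at
zero; nucleation runs start uniform at 0.13.  Activity values per
scenario (total k_T at test scale): droplet growth/vacuole studies at
sigma = 4 use k_T = 64 (vacuole) and 256 (symmetry breaking); the flow
study uses separation r = 10, sigma = 4, k_T = 20, M_r = 1, k_d = 0.5 and
a condensate radius R_c = 2.5 at test scale (4 at reference scale).
Dimensionless velocities are reported as v R_c / D_p with
D_p = M_p d2f/dphi_P^2|0 = 1.56 M_p for the default well.

Symmetry handling: the discretisation preserves mirror symmetry of
symmetric problems to round-off, so symmetry-broken outcomes are obtained
by explicit, seeded asymmetry — a small random perturbation of the
initial protein field (amplitude 1e-3, recorded seed) plus, in the
high-activity vacuole scenario, a slightly offset seed position (0.6,
0.4).  The instability is real (a centred, perturbed vacuole develops
growing asymmetry) but its linear growth rate is slow at test scale; the
offset selects the broken branch within the step budget.  Different
offsets/seeds break in different directions.

## Analytical RNA-gradient theory

For a constant-rate disk source (rate k_P inside radius sigma) with
frozen protein phi_P0, the steady radial balance has the closed-form
modified-Bessel solution implemented in `theory_flow`, with decay length
l = sqrt(M_r/k_d) and sigma_tilde = sigma/l.  The gradient is steepest at
r = sigma with magnitude phi_R0 / L_dr.  Evaluation uses exponentially
scaled Bessel functions (ive/kve), exact for sigma_tilde up to at least
5000.  The small-sigma_tilde scaling laws are normalised against the
exact formula at sigma_tilde = 0.01 (the theory states only
proportionalities).  Peak condensate drift speed is related to the
maximum gradient by a zero-intercept least-squares fit over simulated
sweeps.

The theory assumes an infinite domain; the simulation's outer no-flux
wall is a good approximation when the domain radius exceeds the source
radius by several decay lengths, and comparisons use geometries where the
wall correction is below the comparison tolerance.

## Morphometrics

Dense regions are connected components of phi_P > (alpha+beta)/2 = 0.4.
The effective radius sqrt(area/pi) uses sub-cell coverage weights from
the local gradient so the area does not quantise to whole cells.
Vacuoles are dilute regions fully enclosed by dense material (binary hole
filling); a dilute bay open to the exterior does not count.  Interfaces
are counted as contiguous det(J) < 0 bands along a ray from the cluster
centre, with compositions bilinearly interpolated at quarter-cell
resolution so that narrow unstable bands crossed between cell centres are
not missed: one band for a plain droplet, two for a core-shell vacuole.

Centroid and eccentricity come from the first and central second moments
of the protein field restricted to the dense region (a raw-field mode is
available).  The default eccentricity ((I_xx - I_yy)^2 + 4 I_xy^2) /
(I_xx + I_yy)^2 is rotation-invariant and dimensionless; a `literal`
switch evaluates the variant with -4 I_xy in the numerator, which agrees
whenever I_xy = 0 (axis-aligned geometries) but is not rotation-invariant
and is kept only for comparison.

Outcome classification is rule-based and threshold-exposed: morphology
dissolved / vacuole / aspherical (eccentricity > 0.05) / spherical, and
dynamics at-site / flow (net approach to the cluster > R_c/2) /
dissolution-renucleation / no-effect.  Condensates are tracked across
snapshots by nearest centroid with a maximum jump of 2 R_c per interval.

## Verification strategy

- Chemical potentials and Hessians against central finite differences of
  the energy; coexistence against an independent dense-scan common
  tangent construction on the decoupled well.
- The semi-implicit integrator against an independently written explicit
  Euler integrator on a tiny disk at small fixed dt (1e-3 relative L2).
- The closed-form RNA profile against a finite-difference radial ODE
  solve, and the frozen-protein dynamics against the closed form (1e-3
  relative L2 on a fine grid).
- Conservation: total protein drift < 1e-6 relative over full runs
  (measured ~1e-12); the discrete RNA production/degradation balance
  holds step by step by construction.
- Qualitative phase behaviour (activity-dependent growth and vacuole
  formation, bounded nucleation region, directed flow, two-cluster
  competition) at the reduced test scale.

## Known limitations

- 2-D only; no hydrodynamic coupling, no thermal field noise, no
  chromatin mechanics or viscoelasticity.
- The test-scale geometry (radius 15) puts outer walls within a few decay
  lengths of distal condensates; wall interactions cap how far flow
  scenarios can be pushed before boundary effects intrude.
- The clustered high-activity end state at test scale is an expanding
  dense ring around a growing RNA-rich core rather than complete
  dissolution: with the default localised RNA (decay length ~1.4) the
  displaced ring escapes the RNA-rich region instead of dissolving, so
  "activity dissolves the condensate" manifests as loss of the compact
  droplet (vacuole/ring states and shrinking dense area), with complete
  dissolution only for the uniform-activity control at very high k_T.
- The equilibrium solver reports a second two-phase branch at very large
  total RNA (>~3.5 at default couplings); the package treats the
  single-phase window it returns between the re-entrant branch and that
  regime as the physically relevant excess-RNA limit.
- Classification thresholds (eccentricity 0.05, displacement fractions)
  are heuristics exposed in configuration, not fitted quantities.
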