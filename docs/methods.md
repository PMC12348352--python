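# Methods

## The reduced model

The package replaces an all-atom simulation of 4-pyridone-3-carboxylic acid
with stochastic dynamics directly in the slow coordinates: the two torsions
(φ, ψ) that carry the conformational transformation.  This is defensible
because every quantity of interest — mean forces, the minimum free-energy
path (MFEP), the potential of mean force (PMF) — depends only on the
stationary distribution in the order parameters, not on the microscopic
dynamics that generate it.  The electronic-structure quantities (barriers,
AIM densities, ESP statistics, imaginary frequencies) are not computed;
their published magnitudes enter only as calibration constants of the
synthetic data generators.

## The calibrated landscape

The free-energy surface is a "tube" construction on the torus
[−180°, 180°)²:

    F(z) = P(s*) + ½ k_t d²(z) + c · E · w(s*),

where (s*, d) is the nearest-point projection of z onto a reference curve,
P is the along-path free-energy profile, k_t = 0.02 kJ mol⁻¹ deg⁻² is a
harmonic transverse confinement, and the last term is the field coupling.

**Geometry.**  The curve runs from conformation 1 at the origin to
conformation 2 at (168.5°, 153.0°) — the measured torsion differences taken
as absolute coordinates — through the saddle waypoint (48.0°, 92.7°).  The
pre-saddle leg is a gentle circular detour on which ψ (the C3–O5 rotation)
leads φ, and the post-saddle plateau ends in a rounded corner into the
hydrogen-bond step, where ψ advances ~35° while φ barely moves: the
asynchronous progression of the two rotations.  Two geometric choices are
deliberate calibration, not fits: the pre-saddle arc is sized so the
saddle sits at arc fraction 8/19, i.e. exactly on one of the 20 equal-arc
string images (so the pipeline can report the transition state as a
converged image, the way a practitioner reads it off a converged string), and the tail corner is rounded (radius ≈ 25°) so the
per-iteration smoothing of the string does not equilibrate it off-path.

**Profile.**  P is a C¹ cubic through the control values
(2.0, 8.0, 18.3, 14.0, 17.0, 2.4, 7.0, 0.0) kJ/mol with shape-preserving
(PCHIP) interior slopes — so the saddle value 18.3 is an exact maximum with
no spline overshoot — and zero end slopes, so both basins are true
stationary points.  Conformation 1 sits 2.0 kJ/mol above conformation 2, a
small offset keeping the two barrier maxima nearly equal as seen from
either basin; the second (rotation) maximum is 17.0 kJ/mol, within ~7% of
the principal 18.3 ("almost equal") while leaving the saddle argmax
statistically unambiguous at the pipeline's noise level (~0.5 kJ/mol).  The
profile necessarily creates two on-path intermediates (the 14.0 dip and the
2.4 hydrogen-bond minimum); they are genuine 2-D minima of the surface.

**Arc parameterization.**  The profile parameter runs along normalized arc
length, warped by a smooth monotone map pinned at the endpoints, at the
saddle (profile parameter 0.40 ↔ the saddle waypoint), and at two stretch
points ((0.58 ↔ 0.68), (0.80 ↔ 0.80)).  The stretch pins spread the
17.0 → 2.4 descent over ~55° of arc.  Without them the descent would span
~16°, which no 20-window estimator can resolve: the line-integral PMF would
clip the barrier by >10 kJ/mol even with exact gradients, and the WHAM
cross-check could not agree with it.  Features must live at or above the
window spacing (~14°) for a 20-image string to see them; this is a property
of the method being modeled, and the calibration respects it.

**Projection.**  The curve is discretized at 4001 nodes; the squared
distance to the curve is interpolated parabolically through the three nodes
nearest the query point (found by a KD-tree on a 3×3 torus tiling).  The
parabolic form keeps F differentiable across node boundaries — a
nearest-segment projection has a derivative kink at every node-corner fan.
F is still genuinely discontinuous on the seams where the projection
switches between distant path branches; those seams lie well outside the
sampled tube.

**Field coupling.**  A C¹ cosine bump w(s), 1 at the saddle and 0 outside
profile parameters [0.18, 0.68], times c·E with c calibrated so the saddle
rises 4.8 kJ/mol at the maximum field 41.14×10⁸ V/m — inside the <5.5
kJ/mol bound — identically for the x, y, z axes (the transformation hardly
changes the molecular dipole, so the field direction is irrelevant to it).
The bump's zero slope at its peak and feet means the field moves neither
the saddle nor the basins, making F exactly affine in field strength at
every point.

## Window sampling

Euler–Maruyama integration of overdamped Langevin dynamics in radians,

    z ← z − Δt·m·∇(F + U) + √(2 RT m Δt) ξ,    U = ½ κ |z − c|²,

with κ = 100 kJ mol⁻¹ rad⁻² per torsion and T = 298.15 K.  Defaults:
Δt = 5×10⁻⁴, mobility m = 1 rad² mol kJ⁻¹ (reduced time units), 25000 steps
per window of which 20% are burn-in — 2×10⁴ production steps per
mean-force averaging window.  The spring constant is
read as rad⁻² (a harmonic restraint's rad⁻¹ would be dimensionally
inconsistent).

Numerical choices: the stability precheck requires Δt·m·(κ + C) < 0.5 with
C the analytic stiffness bound (transverse stiffness plus the largest
positive along-path curvature, ~320 rad⁻² for the default landscape); the
Euler–Maruyama stationary variance of a stiffness-a mode is inflated by
2/(2 − Δt·m·a), i.e. +2.6% at the default step for the restraint mode —
below the sampling error at the default budget.  During sampling the
gradient is a bilinear interpolant of ∇F tabulated on a 0.5° periodic grid
(error ≪ the thermal scale); all deterministic operations use the exact
projection gradient.

Two mean-force estimators are provided.  The restraint average
κ(c − ⟨z⟩) equals ⟨∇F⟩ over the biased ensemble exactly, i.e. the gradient
smoothed over the window width √(RT/κ) ≈ 9°.  The default for the pipeline
is the umbrella-integration refinement RT Σ⁻¹(c − ⟨z⟩) (Σ the sampled
covariance), exact for locally quadratic F of any curvature; with κ = 100
rad⁻² the 9° smoothing otherwise clips the 18.3 kJ/mol barrier by ~2.5
kJ/mol, outside the target accuracy, while the refinement recovers it.

## String evolution

20 images; interior images move by −step·P M f with P = I − t̂t̂ᵀ (central
difference tangents, one-sided at the anchored endpoints), displacement
capped at 3°/iteration; step = 20 deg² per (kJ mol⁻¹ deg⁻¹), chosen so the
restoring force dominates the smoothing pull and the mean-force noise floor
(~0.15–0.2°) stays below the convergence tolerance.  Each iteration then
applies local smoothing with λ = 0.1 (suppressing sampling-noise zig-zag)
and equal-arc reparameterization by cubic-spline resampling, iterated until
chord lengths match their mean to 10⁻⁶ (spline resampling preserves
curvature; repeated piecewise-linear redistribution progressively cuts
corners and was measured to drag the converged string several degrees
off-path).  Convergence: RMS image displacement < 0.3° for 5 consecutive
iterations; typical runs converge in 20–40 iterations (max_iterations =
100).  Per-iteration randomness comes from a counter-based split of one
master seed; endpoints are anchored at the deterministically located basin
minima.

With exact gradients substituted for sampled forces (force_mode="exact"),
the converged string reproduces the reference path to <1° RMS transverse
distance — the zero-noise limit of the method.

## PMF reconstruction

The line integral of the mean force interpolates the tangential force
component with a cubic spline in arc length and integrates it analytically;
the plain node-trapezoid rule is kept as an option but at 20 images it
aliases profile features of width comparable to the spacing (≈1.4 kJ/mol of
barrier clipping on this landscape with exact forces).  The independent
cross-check is 1-D WHAM: window samples are projected to the arc-length
coordinate of the final string (with the terminal segments unclamped, so
excursions past a basin keep a signed coordinate instead of piling onto the
boundary bin), binned into 100 bins over the extended range, and reweighted
self-consistently (shift tolerance 10⁻⁶ kJ/mol) using the along-path
component of the harmonic window bias.  Line integral and WHAM agree to
about 1 kJ/mol RMS on default runs; the barrier is read as max F minus F at
the conformation-2 end, ties broken toward smaller α.

## Synthetic field scans

Each observable/direction series is linear through its exact no-field
reference with the slope anchored at the 41.14×10⁸ V/m change, plus
Gaussian noise of 2% of the anchor (strength-0 rows are noiseless).  Series
are generated per signed direction because the published responses are
asymmetric (e.g. −11.6 vs +2.6 kJ/mol for ±x).  Printed calibration
constants: ΔR anchors ±0.051 Å (x) and ±0.031 Å (y); Δν −234.2 cm⁻¹ (+x);
ΔG anchors −11.6/+2.6/+2.1/−3.0 kJ/mol on the 17.3 kJ/mol reference; ESP
references 42.8 and −25.2 kcal/mol; the imaginary-frequency reference
1102.5 cm⁻¹ is the value implied by the Wigner form at κ = 2.18 and 298.15
K.  The remaining anchors (AIM density, ESP variances, −x/y frequency
responses, the aqueous-phase table) are invented once as realistic
magnitudes with the qualitative signs of the reported trends; they are
calibration constants, not predictions.  z-axis series are not generated
(no systematic response).

## Kinetics and Stark formulas

Wigner's quadratic tunneling correction is used because only the factor's
value (2.18 at 298.15 K) is reported, not its functional form; the implied
imaginary frequency is recorded alongside results.  Physical constants are
CODATA-2018.  Reported rate constants of order 10¹⁶ s⁻¹ are irreconcilable
with the Eyring prefactor k_BT/h ≈ 6.2×10¹² s⁻¹ times κ ≈ 2 and are not
reproduction targets.  The second-order rotational Stark energy is
implemented exactly as published — linear in μEΩ with Ω a user-supplied
field-specific constant — although the textbook second-order shift is
quadratic in E; Ω is never assigned a value here because none is published.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the modeled system — barrier heights and
locations, sub-barrier, field-coupling magnitude and direction
insensitivity, linear field responses with realistic noise — so a passing
pipeline demonstrates that the estimators (string evolution, mean forces,
PMF, WHAM, regressions) recover known ground truth under the stated
conditions (20 windows, κ = 100 rad⁻², 2×10⁴ production steps).  It does
not demonstrate force-field accuracy, solvent effects beyond a second
calibration table, coupling between the torsions away from the path tube,
or any electronic-structure quantity.  Known limitations: the tube
construction has free-energy seams between distant path branches (outside
the sampled region); window width ~9° bounds the feature sizes the sampled
pipeline can resolve; and the two on-path intermediates make simple
two-basin analyses of this surface incomplete.

## Problem sizes

Default test and acceptance runs use 20 images × 25000 steps × ≤100
iterations per FTS run (seconds to ~2 minutes each), a 0.5° gradient grid,
20001-point dense profiles, and 9-point regression series — sizes at which
every stochastic target is stable to well within its stated tolerance
across seeds.
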