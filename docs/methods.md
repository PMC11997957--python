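# Methods

This note documents the models implemented in `megjoint`, the
assumptions of the synthetic data generator, the numerical choices
behind the solvers, and the limits of what the test suite shows.

## Source space and geometry

The template source space is a surrogate cortical surface: two
icosphere hemispheres (recursive edge-midpoint subdivision of the
icosahedron) with one fixed-orientation dipole per vertex. At
subdivision level `s` each hemisphere has `10·4^s + 2` vertices; level
4 gives the conventional 2562 source points per hemisphere, and the
desk-scale defaults use level 3 (642/hemisphere, ~9 mm spacing) for
simulations and level 2 (162/hemisphere) in fast tests. The default
radius is 70 mm (head scale) and the hemisphere centers are offset
laterally by 60 mm. The offset matters: with near-coincident spheres,
mirror vertices on the two hemispheres would have almost identical
leadfield columns (correlation ≈ 0.98), making left/right sources
physically indistinguishable — unlike real MEG, where the field
patterns of the two occipital banks differ. At 60 mm the median mirror
correlation is ≈ 0.5 while all sources stay inside the 120 mm sensor
helmet.

All spatial error metrics are geodesic distances computed by Dijkstra
on the edge-length-weighted mesh graph. Graph geodesics on the
icosphere overestimate great-circle arcs by at most ~6% (and can
undershoot marginally, since edges are chords); this metrication error
is far below the mm-level differences the evaluation cares about.
Hemispheres share no edges, so cross-hemisphere distances are infinite
— which is exactly the semantics the wrong-hemisphere outlier rule
needs.

## Forward model

Leadfields come from the closed-form magnetic field of a current dipole
in a spherically symmetric conductor (the Sarvas solution), projected
onto radially oriented magnetometers: 64 sensors on a Fibonacci lattice
covering a 120 mm helmet cap. Radially oriented dipoles are exactly
silent, so each vertex carries one deterministic *tangential* unit
orientation (`ẑ × r̂`, with an `x̂ × r̂` fallback near the poles).
A single orientation per vertex keeps the linear (eLORETA) and sparse
(MWE) solvers on the same scalar unknowns. Units are physical: columns
in T/(A·m), amplitudes in A·m.

Inter-subject anatomical variability is modelled by recomputing each
subject's leadfield from tangentially perturbed source positions
(uniform magnitude up to 6 mm) and scaling each column by a gain factor
uniform in ±15%. The 6 mm scale is about one vertex spacing at the
default resolution and is consistent with the ~1 cm inter-subject
variability of V1 position reported after surface-based alignment;
jitter below the vertex spacing would leave per-subject localization
biases fully correlated and could not express anatomical variability at
all on this mesh.

## Stimulus, targets and evoked responses

The stimulus is a dartboard of 3 eccentricity rings × 8 polar wedges
(24 regions; ring radii 0.5/2.3/4.7/8.4 degrees). Wedges whose angular
span touches the vertical meridian (90° or 270°) are flagged bilateral
and drive one source per hemisphere; all other regions drive only the
hemisphere contralateral to their visual hemifield.

Ground-truth targets live in a posterior "V1 surrogate" patch around an
occipital-pole anchor on each hemisphere: eccentricity ring k maps to a
geodesic distance of 10/20/30 mm from the anchor, polar angle to the
direction around it. Per subject, the active vertex is re-drawn within
8 mm (geodesic) of the template target, standing in for
individual retinotopic variability. For reference, the generator can
report each target's distance to its same-hemisphere neighbours
(~10–25 mm at default settings — comparable crowding to real
retinotopic target constellations).

Evoked responses are `Y = L x(t) + E` on a −50…450 ms axis at 1 kHz:
`x(t)` is a Gaussian pulse (σ = 10 ms) at the target vertex with 30%
leakage to its 1-ring neighbours (so the truth is not perfectly
pointlike), peaking at 83 ms with ±5 ms per-subject and ±3 ms
per-region jitter. Noise is drawn from a per-subject diagonal-plus-
low-rank SPD covariance (heterogeneous sensor variances plus a few
shared noise modes — a stand-in for a resting-state covariance). The
source amplitude is calibrated per response so that the realized
amplitude SNR — time-mean over 0–300 ms of the whitened-signal RMS
across sensors — equals the requested target (default 2, scaled by
1/0.8/0.6 across rings so outer-eccentricity stimuli are weaker, with a
±10% trial-level jitter). Because pure noise has whitened RMS ≈ 1, this
estimator includes the noise floor; calibration solves for the exact
amplitude by root finding on the actual noise realization. The
overlapping multifocal responses of a real experiment are assumed
already separated (the state of the data entering source analysis);
the generator's 258 flashes/run × 7 runs = 1806 flashes per region are
recorded as metadata only.

What the generator does *not* emulate: realistic cortical folding and
retinotopic map geometry (polar-angle reversals, V2/V3 neighbours and
their crosstalk), sensor-level preprocessing artifacts, gradiometers,
head movement, or a GLM separation step. Passing tests therefore show
correctness of the estimators and the claimed qualitative behaviour
under controlled conditions — not performance on real recordings.

## eLORETA

The inverse operator is `W = D⁻¹Lᵀ(LD⁻¹Lᵀ + λ²Σ)⁻¹` with diagonal
weights iterated to the fixed point `dᵢ = √(Lᵢᵀ M Lᵢ)/x₀`,
`M = (LD⁻¹Lᵀ + λ²Σ)⁻¹`, `x₀ = 1 A·m`. The square-root form of the
weight update is essential: it is what gives exact single-dipole
localization at λ² = 0, which the test suite verifies for every
template vertex and end-to-end on 120 noiseless region/subject cases.

Scale handling deserves a note. Iterating the textbook equations
directly on physical units is numerically meaningless: `LD⁻¹Lᵀ` lives
at ~10⁻⁹ T² while a unit-scaled `λ²Σ` is O(1). The implementation
therefore (i) rescales `Σ` to unit mean diagonal and whitens `L` by its
inverse square root, and (ii) renormalizes the implicit source
covariance `D⁻¹` every iteration so that `trace(L D⁻¹ Lᵀ) = N`. This
makes `λ² = 1/SNR²` meaningful across noise scales and makes the
operator exactly equivariant under leadfield rescaling (`L → cL` gives
`d → c·d`, `W → W/c`) for every λ², not only λ² = 0. Fixed-point
iteration starts uniform, stops at 10⁻⁶ maximal relative weight change,
caps at 100 iterations, and fails loudly (with the residual history)
otherwise. Ill-conditioned kernels fall back to a pseudo-inverse.

The default regularization uses SNR 2, i.e. λ² = 0.25, matching the
generator's calibrated SNR. Estimates are emitted signed; magnitudes
are taken only at evaluation and averaging time.

## Generalized Wasserstein cost and barycenter

Signed amplitude vectors are compared channel-wise: `x = x⁺ − x⁻`, and
each sign channel is transported independently per hemisphere (the
ground cost is squared geodesic distance in m², hemisphere-blocked —
cross-hemisphere transport is anatomically meaningless and the blocks
decouple exactly). Each block solves the KL-relaxed entropic problem

    min_P ⟨M, P⟩ + ε·KL(P | K) + γ·KL(P1 | a) + γ·KL(Pᵀ1 | b)

by log-domain scaling iterations. Defaults: ε = 5/(3P) (P the template
vertex count; in m² units this sits at a sane ratio to the ~0.05 m²
cost scale), γ = 1. The reported cost is the transport term plus the
two marginal penalties at the entropic optimum — so it tends to the
exact unbalanced cost as ε → 0⁺, and the cost against an empty marginal
is exactly γ times the surviving mass (mass destruction). The marginal
penalties are evaluated analytically through the fixed-point identities
`P1 = a·e^{−f/γ}`, `Pᵀ1 = b·e^{−g/γ}` (duals f, g), which stays
accurate even at γ = 10⁶ where evaluating KL on the iterated plan would
amplify residual error; with ε at 10⁻⁵ of the cost scale the result
matches an exact linear-program oracle to well under 1%.

Numerics: iterations run on dual potentials in cost units, warm-started
across neighbouring solves; when ε is below 2% of the cost block scale
an ε-annealing schedule (halving from 10% of the scale) stabilizes
convergence. The stopping rule is a potential-change tolerance of
`tol · max(M_max, γ)` with tol = 10⁻³ by default and a 2000-iteration
cap; non-convergence raises with diagnostics.

The barycenter of S channels uses the joint scaling algorithm with the
power-mean update `b = (Σₛ wₛ (Kᵀuₛ)^{ε/(ε+γ)})^{(ε+γ)/ε}` — the
unbalanced generalization of the iterative-Bregman geometric mean; the
balanced limit γ → ∞ recovers it exactly. For sparse inputs the
barycenter support is restricted to the geodesic 25 mm dilation of the
input supports (a speed optimization; exact for the transport blocks
themselves, which only ever couple supports).

The derivative of the cost with respect to a marginal is
`γ(1 − e^{−f/γ})`, clipped to [−γ, γ] (the unregularized problem's
range; the entropic term makes the raw derivative −∞ at empty
coordinates). On the zero set of a signed vector the gradient reports
the steeper of the two profitable mass-creation directions, so a
gradient solver can activate vertices the barycenter attracts — the
mechanism behind the sparsity-loss transition at large coupling.

## MWE solver

The joint objective (S subjects, n sensors)

    Σₛ [ 1/(2n)‖Yˢ − LˢXˢ‖² + λ‖Xˢ‖_½^½ + (μ/S)·W(Xˢ, X̄) ]

is minimized by block-coordinate descent: per-subject proximal-gradient
steps (closed-form half-thresholding prox, derived from the
trigonometric root of the depressed cubic and an explicit energy
comparison against zero) with backtracking line search on the exact
objective, alternating with a barycenter update that is accepted only
if the stored objective does not increase. Every accepted move updates
stored objective terms, so the recorded trace is non-increasing *by
construction* — the monotonicity tests check the contract, and any
future regression would surface as a rejected step, not a silent
increase.

Two scale choices matter. First, `n` is the number of sensor channels
(the objective's `1/(2n)` and `λmax = maxₛ‖LᵀY‖∞/n` use the same n).
Second, the ℓ_½ penalty and the transport mass are not scale-invariant,
and MEG's physical units (Y ~ 10⁻¹³ T, X ~ 10⁻⁸ A·m) would push the
useful λ fractions to absurd values; the solver therefore optimizes an
internally normalized problem (leadfield columns scaled to unit mean
norm, data to unit sup-norm) and converts the estimates back to A·m.
λ is always specified as a fraction of λmax of the normalized problem;
at fraction 1 the solution is uniformly zero (verified).

Initialization: the library solver starts at zero. The pipeline
initializes each subject from its signed eLORETA estimate truncated to
the top-8 magnitudes: zero is a *fixed point* of the half-thresholding
dynamics at strong coupling (creating mass costs γ before any
barycenter exists), and zero-started runs frequently settle in
mirror-hemisphere local minima of the nonconvex problem. A
data-informed start is standard practice for nonconvex sparse solvers
and does not change the objective being minimized.

The MWE path operates on a single time sample per subject — each
subject's evoked column at its own median peak time — matching the
per-time-point character of the analysis; multi-sample MWE is out of
scope.

## Hyperparameter calibration

MWE regularization is tuned against sparsity behaviour. `find_lambda`
bisects the λ fraction in [0, 1] for a mean active count (vertices
above 10⁻⁶ of each subject's maximum) within ±1 of the target — 3
active points per subject for unilateral stimuli, 6 for
vertical-meridian stimuli; monotonicity of the trace is verified, and
an unreachable ±1 window (the nonconvex activation size is discrete and
can jump, e.g., 0 → 5) raises, with the pipeline falling back to the
evaluated λ closest to target. `find_mu_max` expands a geometric
bracket until the active count exceeds `spread_factor` (default 5×) the
target — the coupling strength at which the estimate loses sparsity and
spreads — then bisects on the log scale; the working value is
`μmax / 2`. Because the transition is abrupt, the recovered μmax is
insensitive to the spread factor (tested). The search order is: λ at a
provisional small μ, then μmax at that λ, then one λ re-check at
μmax/2. Both searches are deterministic and are also validated on stub
solvers with planted transitions.

At pipeline scale, hyperparameters are calibrated once per laterality
class (on a middle-eccentricity representative region) per group size
rather than per region — a desk-scale compromise; per-region
calibration is available via `calibrate_per_region`.

## Evaluation

Sensor-space peak times are global-field-power argmaxima (RMS across
channels after removing each channel's temporal mean) within
60–100 ms; window-edge hits are excluded from each subject's median
peak time, and that single median time is used for all of the subject's
inversions. Peak vertices are magnitude argmaxima — global for
unilateral regions, per-hemisphere for bilateral ones (ties break to
the lower vertex id). A peak on the wrong hemisphere, or farther than
80 mm geodesically from its target, is an outlier; outliers are
replaced by 80 mm (Winsorized) in the mean, median and sample standard
deviation (ddof = 1). Bilateral regions contribute one row per region:
the mean of the two per-hemisphere Winsorized side distances, flagged
only if both sides are outliers. An all-zero estimate (an
over-regularized sparse solve) has no peak and counts as an outlier
row.

Group combination averages eLORETA magnitudes and MWE absolute values
vertex-wise (signed sparse estimates would cancel across subjects);
subjects are ordered from the most representative one — the subject
whose median peak-target distance is closest to the group median, ties
to the lower id — followed by ascending id, and groups are nested
prefixes of that order.

## Problem sizes and determinism

Default simulations run 642 vertices/hemisphere, 64 sensors, 24
regions; the test suite uses 42–162 vertices/hemisphere for solver
tests and the benefit study runs 20 master seeds × 10 subjects at the
default resolution. Every random quantity derives from a single master
seed via a seed tree recorded in the experiment metadata; identical
seeds reproduce experiments, solver runs and summary CSVs bit-for-bit.

## Known limitations

- Exact localization is a single-dipole property: bilateral
  (two-dipole) regions incur a one-to-two-vertex crosstalk bias even
  noiselessly; this is inherent to linear inverses, not a bug.
- The sparse solver is nonconvex; results depend on initialization (see
  above), and the active-count target is reachable only up to the
  discrete activation granularity.
- The surrogate geometry (overlapping spheres, single conductor) is
  chosen for testability, not anatomical realism; absolute millimetre
  values are not comparable to real-data studies, only the qualitative
  orderings and mechanisms are.
- Distractor sources in neighbouring visual areas (V2/V3 crosstalk) are
  acknowledged but not modelled.
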