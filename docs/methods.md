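# Methods

`coxhawk` fits point-process models for event data that cluster in time,
space, or both: temporal Hawkes processes (self-exciting, self-inhibiting,
marked, multivariate, or with a user-defined time-varying background),
log-Gaussian Cox processes (LGCPs) on a finite-element mesh, joint models
of an LGCP and point-referenced marks, and a spatiotemporal self-exciting
model with a Gaussian spatial triggering kernel.  All models are fitted by
maximum likelihood; latent Gaussian fields are integrated out with a
Laplace approximation.

## Temporal Hawkes processes

The conditional intensity on an observation window (0, T] is

    λ(t) = μ + α Σ_{i: τ_i < t} m(τ_i) exp(−β (t − τ_i)),

with background rate μ (events per time unit), excitation jump α per unit
mark, decay rate β (1/time), and optional positive marks m(τ_i) supplied
by the user (fixed at 1 when absent; marks multiply the kernel and are
never estimated).  The log-likelihood Σ log λ(τ_i) − Λ(T) is evaluated in
O(n) with the standard exponential-kernel recursion, and the compensator
Λ(T) = μT + (α/β) Σ m(τ_i)(1 − e^{−β(T−τ_i)}) in closed form.  A test
asserts exact agreement (1e-10) with a brute-force O(n²) double sum.

Optimisation runs on an unconstrained internal scale — log μ,
logit(α/β), log β — so that 0 < α < β (sub-criticality) holds by
construction.  With `allow_inhibition=True`, α is left unconstrained and
parameter values that make λ non-positive at any event receive an
infinite penalty.  The optimizer is Nelder-Mead followed by BFGS
refinement (gradient tolerance 1e-8); standard errors are the
delta-method image of the inverse observed information computed by
central differences on the internal scale.  Tied event times are refused;
`jitter_times` adds Uniform(0, resolution) noise (seeded, deterministic)
for data recorded at coarse resolution, e.g. daily.

A time-varying background is supplied as a `BackgroundFn` holding the
rate μ(t; θ), its exact antiderivative, starting values and bounds for θ.
θ is estimated jointly with (α, β); the scalar μ is dropped in that case
rather than kept alongside the function.  Simulation uses Ogata thinning
with the rate bound taken as the grid maximum of μ(t) over the window
(4096 points) times a safety factor, exact for the constant-background
case.

Derived summaries of a fit: expected background count μ̂T, branching
ratio α̂/β̂ (triggered events per event), cluster size β̂/(β̂−α̂)
(descendants per immigrant, including itself), and decay e-folding time
1/β̂.

Goodness of fit uses the random time change: under the true model the
transformed inter-arrival times Λ(τ_i) − Λ(τ_{i−1}) are i.i.d. Exp(1),
checked with a Kolmogorov–Smirnov test.

## Multivariate Hawkes

For N streams, stream j has intensity
λ_j(t) = μ_j + Σ_k Σ_{i: τ_i<t, stream_i=k} α_{jk} e^{−β_j (t−τ_i)}.
The decay is specific to the receiving stream (N decay parameters, not
N²).  The branching matrix α_{jk}/β_j must have spectral radius < 1 for
stationarity; fitting adds a soft quadratic penalty above 0.999 rather
than a hard constraint.  Internal scale: log μ_j, per-row logit of
α_{jk}/β_j, log β_j.  Simulation is exact multivariate thinning: every
event of stream k raises every λ_j by α_{jk}.

## The SPDE/GMRF Matérn field

Gaussian random fields use the Matérn covariance with smoothness ν = 1
(the SPDE order α = ν + d/2 = 2 in two dimensions), represented as a
Gaussian Markov random field on the nodes of a triangulation via the
finite-element construction: with lumped P1 mass matrix C and stiffness
matrix G, the precision is Q = τ²(κ⁴C + 2κ²G + G C⁻¹ G).  Mass lumping
keeps C⁻¹ diagonal and Q sparse.  Reported parameters are the practical
range r = √8/κ — the distance at which the ν = 1 correlation
ρ(d) = κd·K₁(κd) falls to ≈ 0.139 — and the marginal standard deviation
σ = 1/(√(4π)·κ·τ).  These are the standard ν = 1 conventions; a test
verifies that correlations implied by Q⁻¹ on a fine mesh match the
analytic Matérn curve within 0.05 over [0.25r, 1.5r].

Meshing places nodes along the (optionally buffered) polygon boundary at
spacing ≤ `max_edge` and on an interior grid of spacing `max_edge`/√2,
thins them by `cutoff`, Delaunay-triangulates the node set, and keeps
triangles whose centroid lies inside the region.  Area conservation
(triangulated area = polygon area) is asserted in tests.  Because the
GMRF boundary condition inflates the field variance near the mesh edge,
a buffer of at least one range r is recommended (`buffer=` argument);
the default of 0 warns.  Coordinates are planar Euclidean throughout —
longitude/latitude input is accepted verbatim with a logged warning, no
geodesy is attempted.

Integration weights for point-process likelihoods are the areas of the
Voronoi cells of the mesh nodes (the dual mesh) clipped to the domain
polygon; cells entirely outside the domain get weight zero and such
nodes inform the model only through the field prior.  The weights sum
exactly to the domain area.  Node fields are evaluated at arbitrary
points by barycentric interpolation (a sparse n×M projector); points on
shared edges are assigned to the lowest-indexed containing triangle.

## Log-Gaussian Cox processes

The intensity is Λ(s) = exp(Xβ + G(s)) with G the Matérn GMRF.  The
likelihood is discretised onto the dual mesh: node k carries the count
y_k of points in its Voronoi cell and a Poisson term with mean
w_k exp(η_k), η_k = (Xβ)_k + g_k — a Poisson regression with offset
log w_k plus the GMRF prior.  This binned dialect (rather than a
per-point likelihood with barycentric evaluation) was chosen because it
matches the dual-mesh weight interpretation and makes the expected-total
estimator Σ_k w_k exp((Xβ̂)_k + ĝ_k) exact under the fitted model.  Any
error term in the log intensity beyond the field is taken as exactly
zero (absorbed by G).

The marginal likelihood of θ = (β, log κ, log τ[, atanh ρ]) integrates g
out by a Laplace approximation: a damped Newton iteration (convex inner
problem; sparse LU factorisations) finds the conditional mode ĝ, and the
marginal NLL is the joint NLL at ĝ plus ½ log det H(ĝ) − dim(g)/2·log 2π,
H = Q + diag(w e^η).  A test checks agreement within 1e-3 against dense
tensor Gauss–Hermite integration on a 4-node toy, and the σ → 0 limit
against plain Poisson regression.  The outer optimiser is Nelder-Mead
with warm-started inner modes; standard errors come from a central-
difference Hessian of the marginal NLL.

Spatiotemporal fits couple per-knot fields G_i by a stationary AR(1),
G_i = ρ G_{i−1} + ε_i, with innovations standardised so every knot keeps
the Matérn marginal variance σ²; the joint precision is the Kronecker
product Q_time(ρ) ⊗ Q_space, and ρ is optimised on the atanh scale.
With a single knot the spatiotemporal likelihood equals the spatial one
identically.

Initial values, unless overridden: β₀ = log(n/|A|), r = 0.2 × mesh
diameter, σ = 1, ρ = 0.

Simulation draws g ~ N(0, Q⁻¹) by dense Cholesky (intended mesh sizes
are a few thousand nodes at most), Poisson counts per dual cell, and
uniform point placement inside each clipped cell by rejection sampling.

## Marked LGCP

A mark observed at each point is modelled jointly with the locations:

    Λ(s)  = exp(X β + G(s))
    M_j(s) = f⁻¹(X β_m + G_m(s) + α_m G(s))

The loading α_m carries the point–mark dependence (the preferential-
sampling construction): α_m = 0 decouples marks from clustering, and an
estimate within ~2 standard errors of zero is read as no dependence.
G_m is an optional mark-specific field (`fields=1`).  Mark families:
normal (identity link, fixed sd), Poisson (exp), binomial (inverse
logit, fixed trials; trials = 1 gives Bernoulli marks), and gamma where
the linear predictor is the *shape* on the log scale with a user-fixed
log scale parameter, so the mark mean is shape·scale.  Auxiliary
parameters are supplied by the user, never estimated.  The integer
`methods` codes 0/1/2/3 map to normal/poisson/binomial/gamma.

The point process keeps the binned dual-cell likelihood while the mark
likelihood is evaluated at the exact point locations via the barycentric
projector — a deliberately mixed dialect, since marks are point-
referenced observations.  The fields (g, g_m) are integrated out by a
joint Laplace approximation whose curvature couples the two blocks
through α_m; the gamma family's mark Hessian in the predictor is not
globally positive, so its curvature contribution is floored at a small
positive value inside the Newton iteration.  Any nugget beyond the
normal family's fixed σ is taken as zero.  One mark per point is
supported.

## Spatiotemporal self-exciting model

The intensity combines the ingredients above:

    λ(s,t) = μ + G(s) + α Σ_{i: τ_i<t} e^{−β(t−τ_i)} N(s − x_i; 0, Σ_i)

with a bivariate Gaussian triggering kernel of covariance
Σ = [[σ_x², ρσ_xσ_y], [ρσ_xσ_y, σ_y²]].  `time_independent=True` (the
package default) keeps Σ fixed; otherwise Σ is scaled by the elapsed
time t − τ_i, so excitation radiates outward.  The optional GMRF G(s) is
additive on the rate itself (not log-linear, and so not guaranteed
positive — positivity is enforced by an infinite likelihood penalty);
this literal additive form is a modelling caveat worth knowing about.

The compensator uses the closed form μ|A|T + T Σ_k w_k g_k +
(α/β) Σ_i (1 − e^{−β(T−τ_i)}), i.e. the spatial kernel mass is taken as
1 with **no edge correction**.  Tests quantify the consequence: for
events ≥ 3 kernel sd inside the boundary the closed form agrees with
dense space-time quadrature within 0.5%, for events ~1.5 sd from the
boundary within 2%, and the leakage always makes the closed form an
over-count.  In simulate-then-fit studies on a 10×10 domain with
σ_y = 0.8 this produces a visible downward bias in the fitted kernel
scales (largest for the widest axis) while μ, β, ρ recover cleanly; see
Limitations.  Event terms skip history older than 40/β (relative error
below 4e-18).  Internal scale: log μ, logit(α/β), log β, log σ_x,
log σ_y, atanh ρ (+ log κ, log τ with the GMRF).

Simulation uses the branching (cluster) construction: background events
are Poisson(μ|A|T) uniform over the domain (or dual-cell-modulated when
field values are given), each event spawns
Poisson((α/β)(1 − e^{−β(T−τ)})) direct offspring with truncated-Exp(β)
delays and Gaussian displacements (scaled by √Δt for the time-dependent
kernel); offspring outside the domain or window are discarded and spawn
nothing.  This is exact for the domain-restricted model; the likelihood's
unit-kernel-mass compensator is the approximation.

## Synthetic data and what the tests show

All test inputs are produced by the package's own seeded simulators at
these default study conditions: Hawkes (μ, α, β) = (0.5, 1, 2) with
T = 5000 (n ≈ 5000); bivariate Hawkes μ = 0.3, within-stream α = 0.8,
between-stream α = 0.2, β = 1.5, pooled n ≈ 5000; LGCP on a 10×10 square
with β₀ = 1, r = 3, σ = 1 (n ≈ 800); Bernoulli-marked LGCP with
α_m = 1; spatiotemporal model (μ, α, β, σ_x, σ_y, ρ) =
(0.02, 0.4, 0.8, 0.5, 0.8, 0.2) on the 10×10 square with T = 500
(n ≈ 2000).  The simulators emulate the generative models exactly
(thinning and branching are exact samplers) but none of the messiness of
real sightings data: no observation error in locations, no reporting
gaps, no covariate confounding, no coarse time resolution (tests create
ties only to exercise the jitter path).  Passing recovery tests
therefore demonstrate correctness of likelihoods and optimisers under
the assumed models, not robustness to misspecification.

## Numerical choices

- Sparse LU (`splu`) supplies factorisations and log-determinants of the
  GMRF precisions and Laplace curvatures; for symmetric positive-definite
  matrices the product of |U| diagonal entries equals the determinant.
- Inner Newton: damped with step halving, gradient tolerance 1e-9
  (LGCP) / 1e-8 (joint and additive-GMRF variants), hard iteration caps
  with informative errors.
- Outer optimisers: Nelder-Mead then BFGS for the Hawkes family and the
  spatiotemporal model; Nelder-Mead alone for Laplace-marginal surfaces
  (whose numerical gradients are noisier).  A BFGS "precision loss" stop
  at the Nelder-Mead optimum still counts as converged; a genuinely
  failed fit is returned with `converged=False`, never silently.
- Numerical Hessians use relative central-difference steps (1e-4 of the
  parameter magnitude; 1e-3 for Laplace-marginal surfaces).  Non-PD
  Hessians yield NaN standard errors rather than fabricated ones, and the
  JSON reports render them as explicit nulls.
- Degenerate inputs: empty series are valid for likelihood evaluation
  (pure background) but refused for fitting; zero-area triangles raise;
  points outside the mesh raise with the offending index; duplicate
  times raise with advice to jitter.
- All simulators take an integer seed and are bit-reproducible.

## Limitations

- The spatiotemporal likelihood's missing spatial edge correction biases
  kernel-scale estimates downward when a non-negligible share of
  triggering mass falls outside the domain (quantified above).  Work
  far from the boundary, or on domains several kernel sd wide, for
  clean kernel inference.
- The additive (rather than log-linear) GMRF in the spatiotemporal model
  can propose negative rates during optimisation; the penalty handles it
  but makes that surface less smooth.
- Dense Cholesky sampling and dense curvature inverses (for field SDs)
  limit comfortable mesh sizes to a few thousand nodes.
- The binned LGCP likelihood's resolution is the dual mesh: intensity
  variation inside a Voronoi cell is not resolved; refine `max_edge`
  accordingly.
- Mark auxiliary parameters (normal sd, binomial trials, gamma scale)
  are fixed inputs, not estimated.
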