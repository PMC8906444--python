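# Methods

This note records the statistical model, the numerical procedures and the
design choices behind `pl2design`, in the order the pipeline uses them.

## Model and likelihood

A model is a set of states x(t) obeying ẋ = f(x, p, u), with initial
values x₀ (numbers or free parameters), observation functions
y = g(x, s_obs) + ε and Gaussian errors ε ~ N(0, σ²). The full parameter
vector θ = {p, x₀, s_obs, s_err} is stored on per-parameter scales:
rate-like parameters live on the log10 axis (they are bounded, optimized
and profiled there), so profile widths are relative (decade) quantities.
Observables declare a data scale; with `data_scale="log10"` both data and
predictions are log10 values and a constant σ_log corresponds to
log-normal (relative) measurement noise, the usual situation for
concentration measurements.

The objective is LL = −2 ln L = Σᵢ (yᵢ − Fᵢ(θ))²/σᵢ². The additive
constant Σ ln(2πσᵢ²) is dropped when every σ is parameter-free (it shifts
all comparisons equally) and included when any σ depends on parameters;
the choice is global and recorded in the fit result.

Integration uses LSODA with rtol = 1e-8, atol = 1e-10. A model may carry a
closed-form solution (the ABC chain and the straight line do); it is used
as a fast path and cross-checked against the integrator in the tests.
Integration failures surface as +∞ objective values (optimizers retreat)
or as a large finite residual plateau inside least squares, chosen far
above any genuine weighted residual so misfit is never mistaken for
failure.

## Estimation

With parameter-free σ the MLE is a bound-constrained least-squares problem
on the weighted residuals, solved by scipy's trust-region-reflective
method (gtol 1e-8, xtol/ftol 1e-10, finite-difference Jacobians — the
fixture models are far too small for sensitivity equations to pay off).
With parametric σ a quasi-Newton (L-BFGS-B) run on the full objective is
used instead.

Multistart fits draw start points from a *scrambled Sobol sequence* inside
the bounds (first start: the model defaults or a caller-supplied point).
Sobol was chosen over Latin hypercube because the sequence is
prefix-stable: enlarging the start budget for a fixed seed extends the
start set instead of reshuffling it, so the best objective is
non-increasing in the number of starts — a property the test suite
asserts. Default budget: 20 starts for initial fits; all re-fits inside
profiles are single warm-started local optimizations.

## Parameter profiles and confidence intervals

Profiles are sampled by an adaptive bidirectional walk from β̂. The step
controller targets ΔPL ≈ 0.1·icdf(χ²₁, 0.95) per step, halves the step on
a > 4× overshoot, doubles it at most per step otherwise, and clamps steps
to [1e-6, 0.25] of the bound span. A side terminates when PL exceeds the
95% threshold plus a margin of 0.5, when a parameter bound is reached, or
after 100 steps. Each grid point's nuisance optimization is warm-started
from its neighbour. Failed grid points are dropped (with a warning); more
than 20% drops is an error. These constants are not statistically
meaningful — they trade grid resolution against optimization count — and
are recorded in the run configuration.

If the walk stumbles on an objective value below the global fit (the
multistart missed an optimum), the curve is re-anchored so its minimum is
exactly zero and the event is logged; downstream consumers use the
re-anchored reference objective.

Confidence intervals locate the threshold crossing between adjacent grid
points by interpolating **linearly in √PL**, not in PL. For a locally
quadratic profile √PL is exactly piecewise linear in β, so the
interpolation is exact there; linear-in-PL interpolation on the
deliberately coarse near-minimum part of the adaptive grid biases
small-level interval widths inward by tens of percent, which would
corrupt the average-width summary below. Sides with no crossing inside
the bounds are clipped to the bound and flagged open.

Identifiability at level α (default 0.95): *identifiable* if both sides
cross; *structurally non-identifiable* if the profile maximum stays below
5% of the threshold (flat); *practically non-identifiable* otherwise.

## Average confidence-interval width

The scalar uncertainty summary is the integral of the interval width over
confidence levels, w̄ = ∫₀^α_max w(CI_α) dα, computed by trapezoidal
quadrature on an equispaced α grid (defaults α_max = 0.95, 50 nodes). Two
conventions deserve note:

* the integral is **not renormalized** by α_max. Renormalizing is a
  monotone transform that cannot change any design ranking; the raw
  integral keeps the closed-form oracles simple (for an exact quadratic
  profile with sd s: w̄ = s·√(8/π) ≈ 1.596·s at α_max = 1 and ≈ 1.362·s
  at α_max = 0.95).
* open (bounds-clipped) interval sides contribute their clipped width.
  This is what makes the expected width *penalize* designs that leave the
  target non-identifiable instead of silently discarding them.

## Validation (prediction) profiles

For a candidate condition D with current prediction ẑ = F(θ̂ | D), the
validation profile at outcome z refits **all** parameters on Y ∪ {(D, z,
σ_z)} and reports the −2 log-likelihood ratio to the fit that would see
its own prediction, which makes VPL(ẑ) = 0 by construction and VPL ≥ 0
for parameter-free σ. σ_z is taken from the observable's error model
(fixtures: the known constant σ_log), i.e. the future measurement is
treated as one more noisy observation. The same adaptive walk samples z,
with the step scale set by 10·σ_z.

Observables may declare an **outcome range** (assay dynamic range, on the
data scale); hypothetical outcomes are never proposed outside it. This is
both physical — no instrument measures a concentration 50 decades below
its calibration — and numerical: with rate bounds of 10³ acting over
t = 40, the unbounded outcome space of an unobserved state reaches
magnitudes ~10⁻³⁰⁰ where only floating-point underflow would terminate
the profile.

If a side of the VPL fails to cross the 95% threshold within the outcome
range and step budget — a practically non-identifiable *prediction* — a
weak quadratic prior λ·((z − ẑ)/R)² with λ = 0.1 is added and the walk
resumes with its step scale widened to R, guaranteeing a finite sampled
outcome space. R is the 2.5–97.5 percentile span of the prediction over a
Sobol sample of the parameter-bounds box (clipped to the outcome range);
results carry a `regularized` flag plus λ and R.

## Two-dimensional profiles and the design criterion

The predictive confidence C(z) = cdf(χ²₁, VPL(z)) is allocated
equal-tailed around ẑ: F_pred(z) = (1 − C)/2 left of ẑ and (1 + C)/2
right of it — exact when the VPL is quadratic (Gaussian prediction).
Outcome rows are placed at equidistant two-sided confidence levels, so
each row carries equal predictive mass and the expected width reduces to
the **unweighted mean of per-row widths**. Rows span the *reachable*
confidence per side, capped at 0.95: outcomes beyond the 95% predictive
level are deliberately not sampled, and when the outcome range truncates
a side earlier the quantile grid conditions on the measurable range
instead of stacking duplicate rows at the bound. Default: 19 rows.

Each row refits the model on the augmented dataset (warm-started from the
previous row and from the nearest validation-profile solution, keeping
the better) and profiles the target parameter on it. The grid is
assembled through the decomposition identity

    PL2D(z, β) = PL(β | Y ∪ {z}) + VPL(z),

which holds algebraically because the three ratios share the denominator;
the test suite and the acceptance script verify it cell-by-cell with
fresh re-optimizations. The per-profile cost is reported as `budget`
(count of local optimizations): at default grids ~400–650 for the ABC
fixture, the warm-start regime the method is designed for.

Candidate ranking is ascending in W; ties below 1e-9 are broken by
earlier measurement time, then candidate list order (recorded in
`tie_note`). The confidence-scale export shifts each row's minimum to
zero and maps PL2D values through cdf(χ²₁, ·), giving the
prediction-confidence × parameter-confidence grid used for plotting.

## Sequential design loop

Per iteration: fit, profile every parameter, classify; stop if none is
non-identifiable. The target is the first still-non-identifiable name in
the user's policy list (the experimenter's priority order), else the
non-identifiable parameter with the widest average CI. Candidates are
ranked, the winner is measured through the oracle (simulation from a
ground truth, or replay of held-out data), the point joins the dataset and
the condition leaves the candidate list. Additional stop conditions:
candidates exhausted; iteration budget; and *uninformative candidates* —
no sampled outcome row of any remaining candidate closes the target's 95%
interval, i.e. no single measurement can make it identifiable. The loop
records every parameter's status each iteration, not just the target's.

## Fixture models

**ABC chain** (Ȧ = −p1·A, Ḃ = p1·A − p2·B, Ċ = p2·B): free parameters
{p1, p2, A0} on log10 scale with bounds [−5, 3]; B₀ = C₀ = 0 known; A
unobserved by default; observed B and C carry log-normal noise
σ_log = 0.2 and log(A0) = 0 — those two values are fixed by the study
conditions. The true rates (p1 = 0.05, p2 = 0.1) and the observation
times (t = 3 and 6 for both B and C, well before the B peak at ≈ 13.9)
are repository choices, calibrated once so that the seeded fixture sits
in the intended regime: p2 identifiable, p1 and A0 practically
non-identifiable, and measuring A at t = 40 guaranteed to close p1's
interval for every sampled outcome. The closed-form chain solution
(including the p1 ≈ p2 limit) backs the fast path.

**EPO receptor model**: six states (free receptor EpoR, extracellular
Epo, membrane complex EpoEpoR, internalized complex EpoEpoR_i, degraded
pools dEpo_i and dEpo_e), seven dynamic rates (k_t, k_on, k_off, k_ex,
k_e, k_de, k_di), two free initial values (Epo0, EpoR0) and one scale
parameter per composite observable (external = Epo + dEpo_e, membrane =
EpoEpoR, internal = EpoEpoR_i + dEpo_i). Total EPO over the five
EPO-containing states is conserved — a structural check in the tests.
The ground-truth parameter vector is a *synthetic surrogate* chosen to
give well-behaved dynamics on an 8-point grid per observable; it does not
reproduce any published estimates. The censoring utility holds out the
latest ⌈fraction·n⌉ time points per observable (ceiling rule, so a single
time point is held out at fraction 0.5), yielding 12 kept and 12 held-out
points at the defaults — a ready-made replay oracle for the sequential
loop.

**Straight line** y = a·t + b with known constant σ, written as the
degenerate ODE ẏ = a, y(0) = b: the analytic reference for everything —
closed-form MLE, quadratic profiles, the prediction-variance form of the
VPL, outcome-independent 2D rows, and the coverage simulation.

## What the generators do and do not emulate

The synthetic data are exactly the model plus independent additive
Gaussian noise on the declared data scale, with known constant σ. Real
data deviate from this in ways the fixtures do not exercise: model
misspecification, replicate correlation, heteroscedastic or estimated
error models, missing values, and perturbation-dependent designs. Passing
tests therefore demonstrate the correctness of the estimation/profiling/
design machinery under its stated assumptions, not robustness to their
violation. The error-parameter path of the objective (σ as a free
parameter, constant included) is implemented and unit-tested but not used
by any fixture.

## Numerical choices and degenerate inputs

* χ²₁ thresholds throughout, also for validation profiles (df = 1).
* Level 0 gives the degenerate interval [β̂, β̂]; level 1 the
  bounds-clipped open interval.
* A flat profile (all PL = 0) yields the full parameter range with both
  open flags set and classifies as structurally non-identifiable.
* Duplicate candidates get identical W; the tie rule picks the first.
* Profiles with fewer than 3 points, empty candidate lists and 2D
  profiles with fewer than 3 surviving rows are validation errors.
* JSON output rounds floats to 12 significant digits so re-runs are
  byte-identical.

## Problem sizes

The test suite and the acceptance script run the ABC study at its native
size (4 data points, 3 candidates, 19 rows per 2D profile), the
linear-Gaussian oracle at 4 points, a 200-replicate coverage simulation,
and the EPO surrogate at 24 points (12 after censoring) with
truth-warm-started fits; together they complete in a few minutes on one
CPU. Larger models work unchanged but scale linearly in the number of
local optimizations per profile row.

## Known limitations

* Single-point designs only: no batch selection, no continuous-time
  optimization over t, and no design for prediction targets (functions of
  parameters), although the criterion extends to them conceptually.
* Individual-parameter intervals only; no simultaneous/joint confidence
  regions.
* No SBML/PEtab import, events, delays or stochastic dynamics; models are
  registered in code.
* The χ²₁ calibration of profile thresholds is asymptotic; the coverage
  simulation checks it on the linear model only.
* Warm-started single refits inside profiles can in principle miss a
  distant optimum in heavily multimodal landscapes; re-anchoring detects
  the event but a richer multistart inside rows is not attempted.
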