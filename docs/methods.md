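# Methods

## The race-equality model

A race equality `RT1 =P RT2` asserts that two reaction-time laws coincide,
where each side is the distribution of the minimum over independent draws
from its racer conditions.  The analysis treats one equality, one observer
and one scene-color pool at a time; RTs within a (observer, singleton type,
scene color) cell are modeled as i.i.d., and racers are independent of each
other.  The *goal* type — the most feature-rich singleton in the equality —
is the one whose distribution is predicted from the others.

The eight catalogued equalities (`racert.race_algebra.equality_catalog`)
comprise the non-spurious
`min(RT_CMO, RT_C, RT_M, RT_O) =P min(RT_CM, RT_CO, RT_MO)` (RE1), the
two-racer models for CO, MO, CM (RE2-RE4), the three-racer model for CMO
(RE5), and the three complex corollaries of RE2-RE4 (RE6-RE8).  Only RE1's
premise (no triple-conjunction cells in the saliency cortex) is believed
true; the others serve as positive controls that the test can falsify.

## Binning

All distribution comparisons happen on a two-stage histogram:

* **Fine bins.**  All RTs of all types in the equality are pooled and cut
  into L equal-count bins (default L = 100).  Interior edges sit at
  midpoints between the order statistics at the required ranks, so bin
  occupancies differ by at most one; the outermost edges bracket the pooled
  range strictly.  Tied samples that collapse candidate edges reduce the
  effective L with a warning.
* **Coarse bins.**  N + 1 edges (N = 8-12, default 9) are *selected from*
  the fine edges: t_0 and t_N bracket the collective range of the goal
  samples, the predicting side's race-winner samples, and (for RE1,
  RE6-RE8) the partial-race winner samples; t_1 / t_{N-1} additionally hug
  the goal-sample range when it is strictly interior; the remaining edges go
  to the unassigned fine edges closest to goal-sample quantiles at fractions
  F_i — either uniform i/(N'+1) or the erf spacing
  F_i = (erf(-x + 2x(i-1)/(N'-1)) + 1)/2 with x ∈ {1.25, 1.35, 1.45}
  (default 1.35), which concentrates edges where goal mass lives.

Because every coarse edge is a fine edge, distributions defined on fine bins
aggregate to coarse bins without splitting mass, and the race operation
commutes with the aggregation (a minimum's coarse bin is determined by its
fine bin).  Conventions the data do not dictate, fixed once: bins are
half-open [t_{i-1}, t_i); quantiles use linear interpolation; an exact tie
in "closest fine edge" picks the smaller edge.

## Race algebra and prediction

The race-winner distribution of racers with empirical samples is computed
through survival products: for half-open bins,
P(winner ≥ t) = Π_k #{x_k ≥ t}/n_k at every edge t, so bin masses are
differences of survival products — exactly the histogram of the enumerated
per-combination minima at a fraction of the cost (enumeration is retained as
the test oracle).  Ties across racers in one bin are handled exactly by the
joint terms of the two-racer formula; no random tie-breaking exists
anywhere.

For RE2-RE5 the predicted goal distribution is the binned side-2 winner.
For the complex equalities, with q the binned partial-race winner and Q the
binned side-2 winner, the race equation is lower-triangular in the goal
masses p and is solved sequentially; the last component comes from
normalization.  When the solution leaves the simplex (sampling noise or a
false equality), p is chosen to minimize a distance between race(p, q) and Q
over the simplex, by SLSQP from multiple starts (the clipped algebraic
solution, the uniform vector, and five Dirichlet draws), objective tolerance
1e-10.  Distances implemented: squared Hamming Σ(P−Q)²; Hellinger
Σ(√P−√Q)² (a square-root-free literal variant is kept for sensitivity
checks); 1-norm Σ|P−Q|; and the KL-like Σ max(Q,ε) log(max(Q,ε)/max(P,ε))
with ε = 1e-300, which equals the Kullback-Leibler divergence away from
empty bins while remaining finite on them.

## Null construction (constrained multinomial MLE)

The Monte-Carlo null requires, per singleton type, a probability vector over
the L fine bins such that the race equality holds exactly while the
multinomial log-likelihood Σ_α Σ_i n_αi ln p̂_αi of the observed fine-bin
counts is maximal.  The fit parameterizes only the non-goal distributions
(softmax of unconstrained reals, started at smoothed empirical proportions)
and derives the goal distribution from the constraint — the same optimum as
optimizing all types under explicit equality constraints, but far better
conditioned at L = 100:

* RE2-RE5: the goal distribution is the race of the free distributions —
  automatically on the simplex.  The gradient of the race output with
  respect to each racer's masses reduces to cumulative sums over
  leave-one-out survival products, so the fit uses an exact analytic
  gradient (validated against finite differences in the tests).
* RE1, RE6-RE8: in survival space the constraint factorizes,
  S_goal(e) = S_Q(e)/S_q(e) at every fine edge e, giving the derived goal
  masses as differences of a survival ratio (numerically stable where the
  triangular solve's pivots degenerate).  Nonnegativity of the derived
  masses is enforced by an augmented-Lagrangian loop (multiplier updates
  with a moderately growing weight); the goal's likelihood term uses the
  smooth surrogate σ(p) = (p + √(p²+δ²))/2, δ = 1e-6, evaluated in a
  cancellation-free form.  The target residual is 1e-8; when the active
  constraint sits in empty tail bins the loop may stop at a residual up to
  1e-5, which is accepted with a warning since it is orders of magnitude
  below the sampling noise (≈ n^{-1/2} ≈ 0.08) the null is used against,
  and the achieved residual is always reported in the result.

Zero-count bins contribute nothing to the likelihood, so no ε enters the
objective itself.

## The Monte-Carlo test

Given the observed distance D, m = 500 surrogate datasets are drawn from the
null (per type: a fine bin from p̂_α, then a uniform position inside the
half-open bin), each re-run through the *identical* pipeline — same fine
edges, fresh coarse edges, prediction, distance.  p is the fraction of
simulated distances strictly larger than D (ties do not count), floored at
the resolution bound 1/m = 0.002; rejection at p < 0.05.  The null fit and
fine edges depend only on (data, equality, L), so they are computed once and
reused across the m simulations and across sweep configurations.

Group decisions use the exact binomial tail: with per-observer accident rate
α = 0.05, the equality is declared broken at the smallest breaker count k
whose tail probability P(X ≥ k | n, α) falls below α — k = 2 for n = 6 and
k = 3 for n = 8 observers; for other n the same rule extrapolates the
argument.  The parameter sweep enumerates all 5 × 4 × 4 (= 80) combinations
of N, fraction scheme and distance metric, times 4 objective metrics
(= 320) for the complex equalities; each configuration gets an independent
RNG stream derived from the master seed and the configuration index, so
results are independent of execution order, and individual configuration
failures are recorded without aborting the sweep.

A two-sample Kolmogorov-Smirnov test is deliberately *not* offered for
equality testing: race-winner samples built from shared component samples
are not independent draws.

## The synthetic observer

The generator exists so every pipeline stage, and the theory it rests on, is
testable without behavioral data.  Per trial, each neuron type tuned to at
least one of the singleton's unique dimensions contributes one independent
response; RT = floor + gain·g(max response).  Choices the theory does not
constrain, and how that is handled:

* **Response family**: lognormal (medians in spikes/s, log-SD 0.3).
  Single-feature cells respond at median 20 to their singleton; conjunction
  cells at median 12 when one tuned dimension is unique and 30 when fully
  released from iso-feature suppression (45 for the triple-conjunction cell
  of `cmo_present`); background responses at median 6.  Magnitudes follow
  the ballpark that singleton responses far exceed background responses
  (tens vs. below ten spikes/s).
* **Mapping g**: reciprocal 1/r by default, exp(−r/20) as the alternative.
  The theorem-level tests run under both mappings, so the claim that results
  do not depend on f beyond monotonicity is itself tested, not assumed.
* **Calibration**: floor 0.3 s (minimum manual RT); gain solved once per
  preset and mapping from a large fixed-seed draw so the single-feature mean
  RT is 0.6 s, then cached.
* **Observer individuality**: multiplicative lognormal jitter (SD 5%) on the
  gain and on all response medians — enough to make observers distinct
  without moving the cohort mean materially.
* **Trial structure**: 300 trials per type per observer, split exactly and
  interleaved randomly between purple and green scenes (the model is
  color-symmetric); all generated trials are correct.  Contamination (fast
  guesses < 0.2 s, error trials, slow outliers at mean + 4-8 SD) is injected
  by a separate operation at configurable rates, to exercise the exclusion
  pipeline.
* **Saliency assumption**: background responses are generated for
  diagnostics but clipped below the trial's singleton response, making the
  assumption that the singleton always wins the response maximum true by
  construction; they never enter the RT.
* **Scene geometry** is metadata only (30 × 22 jittered grid, ≈ 39° × 29°,
  1° × 0.2° bars, singleton at one of 18 locations near 12.8°
  eccentricity); it pins the stimulus parameters and supports documentation
  and tests, not rendering.

What the generator does *not* emulate: sequential effects and learning
across trials, RT autocorrelation, attention lapses with a separate RT
component, asymmetries between scene colors, spatially explicit contextual
interactions (e.g. colinear facilitation), and eccentricity-dependent
response variation.  Passing tests therefore show the *procedure* is correct
and calibrated under the model's assumptions — not that real data satisfy
those assumptions.

## Trial exclusions

Error trials and RTs below 0.2 s are removed first; then, per (observer,
singleton type), RTs above mean + 3 SD of the surviving trials are removed
in a single non-iterated pass (the minimal reading; whether the cut's
moments should be computed before or after the 0.2 s filter is not dictated
by the procedure — this implementation computes them after).  Groups left
with fewer than two trials skip the SD cut with a warning so partial
datasets stay usable.  Thresholds are arguments with these defaults.

## Problem sizes used by the shipped runs

The package default is the full setting (L = 100, m = 500).  The analysis
drivers run at L = 30, m = 200 (m = 50 in the sweep) and the type-I-error
study (tests and acceptance script) at L = 20, m = 500 over 100-200
synthetic observers — the fine-bin resolution affects only how finely the
null resembles the data, not the test's calibration logic, and these sizes
reproduce the nominal 5% rejection rate well within binomial error.

## Known limitations

* The complex-equality null fit can leave a ≤ 1e-5 negative-mass residual in
  empty tail bins (clipped, warned, reported) rather than the 1e-8 target.
* The group threshold beyond 6 or 8 observers extrapolates the binomial
  argument.
* The constrained prediction's optimizer is local; multi-start makes the
  small-N simplex problems reliable in practice, and the grid-search oracle
  bounds it in the tests, but global optimality is not guaranteed.
* `hellinger` follows the metric's standard definition with square roots;
  the literal squared-difference variant is available for sensitivity
  analysis and coincides with `sq_hamming`.
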