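# Methods

## The training problem

The binary soft-margin SVM is trained entirely in its dual form.  For a
training set {(xᵢ, yᵢ)}ᵢ₌₁…ₙ with yᵢ ∈ {−1, +1}, the objective

    L(α) = Σᵢ αᵢ − ½ Σᵢⱼ αᵢ αⱼ yᵢ yⱼ exp(−γ‖xᵢ − xⱼ‖²)

is maximized subject to the box 0 ≤ αᵢ ≤ C and the equality
Σᵢ αᵢ yᵢ = 0.  L is concave (the quadratic form is built from a
positive-semidefinite Gram matrix), so for any fixed (C, γ) the exact
SMO solver's value upper-bounds the objective of every feasible α —
the property the test suite uses as its oracle throughout.

The metaheuristic searches the joint space: a solution string is
(α₁,…,αₙ, log₂C, log₂γ) with log₂C ∈ [−15, 15], log₂γ ∈ [−5, 5] — the
classical exponential search ranges — and its fitness ("brightness")
is L(α) evaluated at the string's own (C, γ).  The trained machine
keeps the points with αᵢ > 10⁻⁸·C as support vectors (a threshold
proportional to C is invariant under rescaling the box) and predicts
via f(x) = sgn(Σᵢ αᵢ yᵢ K(xᵢ, x) + b).

**Bias.**  b is the mean of yᵢ − Σⱼ αⱼ yⱼ K(xⱼ, xᵢ) over the *free*
support vectors (0 < αᵢ < C), where the Karush-Kuhn-Tucker conditions
make the margin exact; bound support vectors (αᵢ = C) only satisfy an
inequality there, so including them would shift b by a constant.  If no
free support vector exists the average falls back to all support
vectors.  Ties f(x) = 0 deterministically map to +1.

## Constraint repair

Continuous moves almost never land exactly on the hyperplane
Σ αᵢ yᵢ = 0, so discarding infeasible proposals would stall the search.
Every proposal is instead repaired by alternating projection: exact
Euclidean projection onto the hyperplane (a shift along y, since y has
±1 entries) followed by clipping to [0, C], iterated until
|Σ αᵢ yᵢ| ≤ 10⁻⁸·n·C (a tolerance scale-invariant in C), with the
always-feasible zero vector as a fallback after 200 sweeps.  Both sets
are convex, so the iteration converges; the repair is idempotent and a
feasible vector passes through unchanged.  When a move changes log₂C,
the multipliers are re-clipped to the new box before the equality
repair, because the box bound co-evolves with the string.

## Firefly dynamics

Each iteration scans the population in index order; firefly i moves
toward every member j of the *current* (already updated) population
that is brighter, then the best-so-far string performs a random walk
accepted only on strict improvement (elitism), so the recorded best
brightness is non-decreasing — an invariant asserted on every run.

- **Distance** between strings is Euclidean after per-dimension
  normalization: each multiplier by the larger of the two strings' box
  widths C, log₂C by its range (30), log₂γ by its range (10).  Without
  this the n multiplier dimensions (scale up to 2¹⁵) dominate and the
  attractiveness decay saturates.
- **Attractiveness** β = s(βd·e^(−γₐ·r)), where βd is the sum of the
  two brightness values floored at 10⁻³, γₐ is the light absorption
  coefficient (default 1.0; distinct from the kernel width, though the
  literature reuses the symbol γ for both) and s(x) = x/(1+x) squashes
  into (0, 1) so the subsequent move stays a convex combination.
  Brighter pairs pull harder; farther pairs pull less; the floor keeps
  early populations with negative dual values moving.
- **Move**: per-dimension (1−β)·sᵢ + β·sⱼ plus a uniform random walk,
  then clip / repair / re-score.
- **Random walk**: uniform in (−1, +1) per dimension by default.  A
  fraction-of-range variant (half-width = walk_frac × each dimension's
  range) is available via `walk_frac`.  The literal ±1 default was
  chosen because the fraction-of-range walk scales the multiplier
  kicks with C: once the search reaches large-C regions the walk can
  no longer refine α finely enough, and measured search quality drops
  from ≥ 0.90 of the exact dual optimum (20/20 seeds) to below it in
  most seeds, with a corresponding loss of cross-validated accuracy on
  ring-shaped data.  Fixed ±1 kicks keep α-refinement resolution
  independent of where the hyperparameter search has wandered.
- Defaults m = 20 fireflies and 200 iterations — the standard swarm
  size and budget for this training scheme; the per-iteration history
  (best brightness, training CCR) is returned for convergence plots,
  and on the synthetic suite the best-brightness trace plateaus well
  before the iteration cap.

A known property of the joint fitness: maximizing L over γ and C as
well as α rewards regions where the data are hard to separate in
feature space (there the dual optimum grows with C), e.g. the
small-γ/large-C corner for data whose pairwise squared distances are
≲ 1 after scaling.  The search therefore tends toward large C with a
wide kernel on such data; prediction quality there depends on how
exactly α approaches the dual optimum, which is why the walk
resolution above matters and why the suite measures search quality as
a fraction of the SMO optimum at the returned (C, γ).

## PSO baseline

Global-best particle swarm over the identical encoding, fitness and
repair: velocity v ← ωv + c₁r₁(p − x) + c₂r₂(g − x) with inertia
ω = 0.72 and cognitive/social coefficients c₁ = c₂ = 1.49 (standard
constriction-equivalent values), velocities clamped per dimension to
half the parameter range, elitist global-best recording.  It shares
every contract with the firefly trainer (monotone best trace,
feasibility closure, determinism given a seed).

## Exact solvers

`smo_solve` implements sequential minimal optimization with
maximal-violating-pair working-set selection on the dense Gram matrix
(guarded to n ≤ 2000): repeatedly pick the most KKT-violating pair,
solve the two-variable subproblem analytically, clip to the box, and
stop when the violation falls below tolerance.  `grid_search`
exhaustively scores all 31 × 11 = 341 integer-exponent (C, γ) pairs by
inner-cross-validated CCR with SMO and returns the first-encountered
argmax.  In the tests the SMO optimum is additionally cross-checked
against an SLSQP solve of the same QP and against the reference RBF
SVC of scikit-learn at identical (C, γ).

## Multiclass, metrics, preprocessing

k-class problems use one-against-all aggregation: one class-vs-rest
binary machine per class (per-machine seeds offset so the k searches
are independent), prediction by maximal decision value with ties going
to the lowest class tag.

All metrics derive from TP/TN/FP/FN: CCR = 100·(TP+TN)/total; MCC with
the convention that a zero factor in the denominator yields 0;
sensitivity, specificity, false-negative rate, accuracy, precision,
Youden's index (sensitivity + specificity − 100, reported in
percentage points) and F-score, with any rate whose denominator is
zero flagged as undefined rather than raised.  Cross-validation is
stratified k-fold (default 5): per-class counts across folds differ by
at most one, every sample is tested exactly once, and the summary
reports the across-fold mean and sample standard deviation (ddof = 1).

Features are scaled to [−1, 1] by x' = 2(x−min)/(max−min) − 1 with the
extrema taken from the training partition only (test points may exceed
the range; constant columns map to 0).  A paper-faithful global-scaling
variant is a one-liner — fit the scaler on the full dataset — but the
train-only default avoids leakage.  Feature relevance is the plug-in
mutual information (natural log) between the label and the feature
discretized into 10 equal-frequency bins (configurable); ranking is
descending with ties broken by feature index.

## Synthetic data

The generator is a pure function of its spec (seed included) and emits
three geometries: isotropic unit-variance Gaussian blobs whose means
sit `separation` within-class standard deviations apart (k = 2 on an
axis, k > 2 on a circle with adjacent means `separation` apart); two
concentric annuli with radial standard deviation 0.1, inner mean
radius 1 and a radial gap of `separation` thicknesses (a case that
defeats any linear separator but not an RBF machine); and four
alternating-label corner blobs (XOR).  Optional label noise flips the
stated fraction of labels.  These fixtures exercise separable,
RBF-necessary and non-separable regimes, and a 50%-noise setting
produces a chance-level regime for harness sanity checks — but they
are low-dimensional, noise-free (unless requested) and exactly
class-balanced, so passing on them demonstrates correctness of the
machinery, not performance on real tabular data with correlated,
heterogeneous features.

## Problem sizes and numerical choices

The test suite runs the full protocol (m = 20, 200 iterations, 5-fold
CV, 20 seeds) at n = 20 for search-quality measurements and n = 60 for
cross-validated recovery — sizes at which the exact solver is an
uncontestable oracle and the whole suite completes in a few minutes.
Key tolerances: SMO KKT tolerance 10⁻⁸ (10⁻¹⁰ where used as an
oracle); feasibility tolerance 10⁻⁸·n·C; support-vector threshold
10⁻⁸·C; dominance assertions allow 10⁻⁶ slack.  Degenerate inputs are
errors, not silent states: single-class training sets, classes smaller
than the fold count, no multiplier above the support-vector threshold.

## Known limitations

- The joint fitness pathology described above means the returned
  hyperparameters are whatever maximizes the dual value, which is not
  a generalization criterion; on some geometries good accuracy rests
  on the α coming close to the exact optimum.
- The firefly sweep costs O(m²) fitness evaluations per iteration,
  each O(n²); training is practical for hundreds, not tens of
  thousands, of samples.
- No shrinking/caching heuristics in the SMO solver; it is an oracle
  and baseline, not a production SVM.
- One-against-all uses raw decision values; machines are not
  calibrated against each other.
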