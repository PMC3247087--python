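# Methods

## Model and procedure

The package targets binary classification of n samples described by p
numeric features with n ≪ p. The scoring primitive is plug-in
quadratic discriminant analysis: class-conditional Gaussians N(μ_c,
Σ_c) with priors π_c, classified by the sign of the log-posterior
difference. Sample means and unbiased (n_c − 1 denominator) sample
covariances are substituted for the population parameters. The rule's
zero set is a hyperquadric, so one classifier family covers linear,
XOR-like (hyperbolic), circular (elliptical) and band-shaped
separations; this breadth is what lets a single error criterion screen
for bivariate interaction patterns of unspecified shape.

Error rates are stratified k-fold (default k = 10) cross-validation
estimates, pooled: total misclassified test samples over n. Pooling and
per-fold averaging coincide when fold sizes are equal; pooling is used
because stratified folds can differ by one sample for unbalanced
classes.

The detector runs in two stages. Stage 1 partitions the columns into
consecutive blocks of `bsize` features (optionally after a seeded
permutation of columns) and scores every unordered pair of blocks by
the CV error of a QDA on the union of their columns; the constraint
2·bsize ≤ p* keeps every union inside the dimension range where QDA
error still separates signal-bearing from noise-only chunks (see the
overlap experiment below). Stage 2 takes the `top_m` (default 6)
best-ranked matchings and scores **all** feature pairs within each
matching's union — within-block as well as cross-block — plus the
univariate error of each feature on the diagonal. Scoring the full
union rather than only the bsize × bsize cross pairs costs little and
makes the heat matrix self-contained: the diagonal exposes "not so
weak" single components (the V-shaped pattern's second coordinate), and
a signal pair that happens to share a block is still found. Pairs are
pooled over matchings, deduplicated and returned sorted ascending by
error; no numeric hot-spot threshold is imposed — callers read the top
of the list.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bsize` | 5 | block size (features); 2·bsize ≤ p* enforced |
| `p_star` | 10 | dimension up to which QDA error is trusted to flag signal chunks |
| `k` | 10 | CV folds; every class must have ≥ k samples |
| `top_m` | 6 | matchings rescanned in stage 2 |
| `priors` | empirical | class priors: training-fold proportions; `balanced` or explicit pair available |
| `ridge` | 1e-6 · tr(Σ̂_c)/p | per-class diagonal regularization, always applied |

The ridge default is scale-aware (proportional to the mean per-feature
variance) and small enough not to move any well-conditioned boundary,
while keeping folds with n_c ≤ p usable: there the raw covariance is
singular and the ridge alone makes the Cholesky factorization succeed,
which is exactly the regime that produces the near-chance errors the
peaking study measures. Explicit `ridge=0` restores the unregularized
fit where per-class counts allow it.

Empirical priors equal 0.5/0.5 in all balanced simulations; for
unbalanced designs (e.g. 40 tumours vs 22 normals) they weight the
discriminant toward the prevalent class, which is the standard plug-in
choice.

## Synthetic scenarios

Four generators plant a two-dimensional signal whose marginals overlap
between classes while the joint distribution separates them, each with
n₀ = n₁ = 40 by default:

1. **linear** — bivariate Gaussians, μ₀ = (0,0), μ₁ = (−1,1), shared
   Σ = [[1, 0.9], [0.9, 1]]. Unit variances keep each marginal overlap
   large (|Δmean| = 1 per axis, univariate Bayes error ≈ 0.31) while
   the strong correlation makes the mean shift nearly orthogonal to the
   principal noise axis (bivariate Mahalanobis distance √20, Bayes
   error ≈ 0.013).
2. **xor** — class 0 uniform on [0,1]² ∪ [−1,0]², class 1 on the two
   mixed-sign quadrants; identical marginals, separable jointly.
3. **circular** — standard bivariate normal labelled by squared radius;
   both thresholds default to the χ²₂ median (≈ 1.386) so classes are
   balanced in expectation with no gap; rejection sampling until the
   exact class counts are met.
4. **vshape** — x₁ uniform on [−1,1]; class 0 occupies the band
   [|x₁|, |x₁|+0.3] above the V-curve, class 1 the disjoint band
   [|x₁|+0.5, |x₁|+0.8]. x₂ is deliberately only *partly* weak
   (univariate Bayes error 0.25) — its diagonal entry in the stage-2
   heat matrix illustrates a "not so weak" component.

Noise features are i.i.d. standard normal, independent of the labels
and of the signal draws (separate salted PCG64 streams per operation,
so padding a dataset never changes the signal columns). The generators
emulate the idealised study conditions — Gaussian noise, exactly one
planted pair, exact class counts — and not realities of expression
data such as heavy tails, batch effects, gene-gene correlation among
"null" genes, or technical missingness. Passing tests therefore show
the machinery finds the patterns it was designed for under its stated
model, not that it is robust to those artefacts; the preprocessing
utilities (log transform, standardization, outlier exclusion,
importance screening) are the bridge the user applies to real data.

## The peaking and overlap studies

The peaking curve pads a planted pair with p − 2 noise columns over a
dimension grid and records the mean CV error over B replicates:
near-separable at p = 2, near chance by p = 100 at n = 80. The overlap
experiment draws, per dimension, B = 100 signal-bearing and B = 100
noise-only datasets (paired seeds: replicate b of both arms uses root
seed + b), scores each by CV error, and summarises the separation of
the two error populations by Δ = |mean₁ − mean₂| / s_pooled, reported
as the Gaussian overlap Φ(−Δ/2) — the error rate of the linear
discriminant between two equal-variance Gaussians at that separation.
The pooled SD uses (B−1, B−1) weights; with equal arm sizes this equals
the simple average of variances. Two identical populations give Δ = 0
(overlap 0.5); a zero pooled SD with unequal means raises an error.

Measured at n₀ = n₁ = 40, the overlap stays below 5% for all four
scenarios at p ∈ {2, 5} and grows with p, which fixes p* = 10 and hence
bsize ≤ 5. The acceptance script recomputes exactly this quantity.

External classifiers plug into the bench via a two-method adapter
contract (`fit(X, y)` / `error(X, y)`); the package ships and tests the
internal QDA adapter only.

## Numerical and design choices

- **Determinism.** Every stochastic step derives from an integer seed
  through salted `numpy` PCG64 streams; fold assignment depends only on
  (y, k, seed), so all subsets scored within one search share folds and
  rankings compare like with like. All ties (matching ranks, pair
  ranks) break lexicographically on indices, making every ranking a
  total order and reruns identical.
- **Subset evaluation.** The blockwise search evaluates thousands of
  small-column-subset QDAs per fold. Class means and covariances are
  computed once per fold on the full matrix; a subset's moments are the
  corresponding sub-vector/sub-matrix, and batched Cholesky
  factorizations score all same-size subsets at once. Results equal a
  direct per-subset fit (the sample moments of a column slice are the
  slice of the sample moments); the test suite asserts this equality.
- **Tie at the boundary.** A discriminant of exactly zero predicts
  class 0, documented and fixed.
- **Degenerate inputs.** Absent classes, classes smaller than k, zero
  within-class variance (CorScor), non-positive values under the log
  transform and singular regularized covariances raise errors naming
  the offending class/feature rather than propagating NaNs.
- **Remainder blocks.** When bsize does not divide p the last block is
  smaller; every union still satisfies the 2·bsize ≤ p* bound.
- **Block order.** Blocks follow the original column order by default;
  a seeded shuffle is available as a robustness check since block
  composition does affect which matching a pair lands in (never whether
  its own pairwise error is low).
- **Screening.** The importance-based screen removes the top-ranked
  features given *any* user-supplied importance vector (e.g. a random
  forest's mean-decrease-Gini with 5000 trees); computing importances
  and choosing the cutoff (screeplot elbow) stay outside the package,
  as does outlier detection — exclusions are passed as 1-based case
  numbers.
- **TSP ties.** Samples with x_i = x_j contribute 1/2 to the
  within-class fraction (midrank convention).
- **CorScor variant.** Implemented as |r₀ − r₁| on [0, 2] — the
  gap/substitution form consistent with published score magnitudes
  above 1; the on/off variant is out of scope.

## Problem sizes used in the shipped studies

The test suite and acceptance script run the studies at their design
sizes where those are cheap — B = 100 replicates for the overlap
experiment (8 cells), 100 seeded runs of the p = 200 detector
experiment per scenario — and at reduced grids elsewhere (e.g. the
peaking degradation check uses p ∈ {2, 100} with B = 10). The p = 2000
workload appears only as fit-count arithmetic; running the detector at
that scale is a matter of minutes, not of different code paths.

## Known limitations

- Binary outcomes only; the multi-class extension is future work.
- The search targets *bivariate* interactions; higher-order planted
  interactions and non-Gaussian noise generators are out of scope.
- Stage-1 ranking can in principle split a signal pair across two
  blocks that never reach the top_m matchings together; the seeded
  shuffle and a larger top_m are the mitigations.
- The Φ(−Δ/2) summary assumes the two error populations are roughly
  Gaussian with similar spread; at very small B or near-zero variance
  it is a coarse summary.
- Real expression data needs the preprocessing pipeline (and an
  externally computed importance vector) before the detector's
  assumptions are even approximately met.
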