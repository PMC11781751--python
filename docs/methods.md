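# Methods

This note documents the models, the synthetic-data mechanism, the numerical
choices and the known limitations of `lbwdetect`.

## Problem framing

Birth-weight screening is cast as three nested one-class problems. Labels
are derived from the gram-valued outcome by strict inequalities — LBW:
weight < 2500 g, VLBW: < 1500 g, ELBW: < 1000 g — so the boundary value
2500 g is *normal* for the LBW tier, and every deeper-tier positive is a
positive of all shallower tiers. Rows with missing or non-positive weight
are dropped (with a logged count) before stratification. Detectors are
fitted on normal rows only; test folds contain both classes. Scores follow
one orientation everywhere: higher = more anomalous. External scorers with
the opposite convention must declare it at adapter registration and are
negated.

## Preprocessing

Per feature kind: numeric → mean imputation; binary/categorical → mode
imputation with ties broken by the lexicographically smallest level (a
determinism choice; any fixed tie-break would do). Binary features map
Yes/No (and 0/1, True/False spellings) to a single 0/1 column; categorical
features get a *full* one-hot block in a fixed level order — no dropped
level, so per-level perturbation semantics stay intact for attribution.
All encoded columns are min-max scaled to [0, 1].

Degenerate cases are pinned down: a constant column scales to 0; values
outside the fitted range at transform time are clipped into [0, 1]; an
unseen categorical level at transform time is a hard error by default
(an opt-in mode encodes it as an all-zero block with a warning); an
all-missing column is a hard error naming the column.

Two fitting modes exist because the classical pipeline computes imputation
and scaling statistics on the full dataset before cross-validation, which
leaks test information into the transform. The default `global` mode
reproduces that behaviour for fidelity; the `fold-safe` mode refits the
transform on each training fold's *normal* rows only. Both run through the
same `Preprocessor`, whose fitted parameters serialize to JSON for exact
replay.

## Detectors

Six scorers are implemented natively; their defaults are fixed and
overridable through `ScorerSpec.params`:

| name | score | key defaults |
|---|---|---|
| `iforest` | 2^(−E[h(x,T)]/c(ψ)) over random isolation trees | 100 trees, ψ = min(256, n) |
| `hbos` | Σ_j −log(normalized bin height) | ⌈√n⌉ equal-width bins, floor 0.1/n |
| `ecod` | Σ_j −log(min(F_j(x), 1−F_j(x⁻))) | tail floor 1/(n+1) |
| `knn` | Euclidean distance to k-th nearest training row | k = 5 |
| `gmm` | negative log-likelihood of a diagonal Gaussian mixture | 1 component, ridge 1e−6 |
| `pca` | squared reconstruction error in the top-q principal subspace | q = smallest count explaining 90% variance |

Notes:

- The isolation forest evaluates c(n) = 2H(n−1) − 2(n−1)/n with *exact*
  harmonic numbers (cached cumulative sums), not the usual log+γ
  approximation, so path-length identities hold to machine precision; trees
  are stored as flat arrays with a vectorized batch traversal, and per-tree
  path lengths are public because the depth-based attribution needs them.
- ECOD here is the symmetric min-tail variant: per dimension the tail
  probability min(left, right ECDF) with a 1/(n+1) floor, summed as
  −log. The published method additionally selects sides by skewness; the
  simplification is deliberate and documented at the class.
- The GMM default of one component reduces to a ridge-regularized Gaussian
  fit with a closed-form M-step and no EM iterations; k > 1 runs diagonal
  EM initialized from k seeded training rows.
- kNN requires strictly more than k training rows; when scoring a training
  row, the row counts as its own zero-distance neighbor.
- Every stochastic fit derives its streams from one integer seed via
  `SeedSequence.spawn` in a fixed order (one child per tree, etc.), so fits
  are bit-reproducible across platforms that share numpy's generator.

## Evaluation protocol

Fold planning is stratified: positives and negatives are independently
shuffled per repeat and dealt round-robin over folds, so positive counts
differ by at most one and every test fold has both classes; fewer positives
than folds is a hard error naming the category. Per repeat × fold the
detector is fitted on the training folds' normal rows and scores the whole
held-out fold (the only reading of "train on normals, loop folds" that uses
all data and keeps test folds mixed-class). The reported value per
detector/category is the arithmetic mean of the 10 fold values.

AUCROC uses the Mann–Whitney form on average ranks (ties credited 0.5).
AUCPR is average precision under a descending, stable sort — ties keep row
order — rather than trapezoidal PR interpolation, which is biased for rare
positives; its chance level equals the prevalence. A detector failure on a
fold is recorded with its message, excluded from means, and logged loudly
rather than aborting the run.

Detectors are compared per category by one-way ANOVA over their fold-level
AUCROC vectors (k detectors × 10 values; df = (k−1, N−k)). The fully
degenerate case — all values identical — is defined as F = 0, p = 1.

## Attribution

Both methods substitute a baseline value μ_i into feature i of an instance
x. The baseline defaults to training-normal column means (avoiding test-set
leakage); test-set means are available as an explicit option. For a one-hot
encoded feature all its indicator columns are substituted *together* by
their fractional baseline means — the literal mean-substitution rule; the
alternative of substituting the modal category's exact one-hot vector was
considered and rejected as a default because it silently changes the
perturbation target for skewed features.

- Score perturbation: ΔS_i = S_o − S_{m,i}. With higher-is-anomalous
  scores, ΔS_i > 0 means the observed value *raised* the anomaly score.
  Features are ranked by |ΔS_i|, average ranks on ties. The implementation
  batches the d+1 score calls but each ΔS_i equals the one-at-a-time
  computation exactly (a tested invariant).
- Depth-based local importance (isolation forest only):
  I_i = mean over trees of |h(x,T) − h(x_i′,T)|. A feature never used on
  the instance's paths gets I_i = 0.

Aggregation across outlier points (labeled positives by default, top-k by
score as an option) reports the per-feature mean rank, sorted ascending.
On synthetic cohorts the two methods agree positively (Spearman) but not
identically; perturbation reflects the score, depth importance the tree
geometry.

## Synthetic cohort generator

The generator defines the study conditions, not a tunable benchmark. Each
row draws a latent risk z ~ N(0,1); birth weight is a strictly decreasing
piecewise-linear function of the risk percentile with anchors
(4500, 2500, 1500, 1000, 500) g placed at cumulative probabilities
(0, 1−p_lbw, 1−p_vlbw, 1−p_elbw, 1). This yields nested labels by
construction and sampled prevalences binomial around the targets, which
default to (0.116, 0.0128, 0.0054) on 3509 rows.

The default schema is 22 features: 12 numeric (feature j ~ N(10(j+1),
(1+j/2)²) — varied scales so min-max scaling is exercised), 6 binary
(Yes/No with base rates 0.15 + 0.05j) and 4 categorical (3–5 levels,
level weights ∝ 1/rank). Six features (3 numeric, 2 binary, 1 categorical)
are informative by default; the remaining 16 are nuisance, which keeps
attribution recovery non-trivial. In anomalous rows, informative numeric
features shift by ±severity·σ·tier (alternating sign across features),
binary rates shift by 0.5·severity·tier·√(p(1−p)) (clipped to [0.01,
0.99]), and categorical draws mix toward the rarest level with weight
0.25·severity·tier, where tier is 1 / 1.5 / 2 for LBW / VLBW / ELBW —
deeper tiers deviate more, so detectability rises with severity and tier
depth. Severity 0 produces label-independent features (chance-level
detection), the calibration anchor for the no-signal tests. Missingness is
MCAR over feature cells at a default 5% rate (the weight column is never
masked); MCAR is the simplest mechanism compatible with mean/mode
imputation, and the default rate is a placeholder choice, not an estimate
of any real registry.

What the generator does **not** emulate: realistic obstetric marginal
distributions or inter-feature correlations, measurement error structure,
informative (MNAR) missingness, or longitudinal visits. Passing tests
therefore demonstrate correctness and recoverability of the machinery
under a known generating process — not clinical performance on real
cohorts.

## Problem sizes used in the test battery

The recovery check runs the full-size condition (3509 × 22, severity 2,
the 0.0128-prevalence tier, 20 seeds). The severity-monotonicity grid
{0, 1, 2, 3} uses 500-row cohorts × 20 seeds × 6 detectors with a
held-out-rows protocol (training rows are excluded from scoring so the
severity-0 point sits at chance). The determinism check reruns the complete
pipeline twice on the 3509 × 22 cohort with 2×5 CV and all six native
detectors on the LBW tier and compares output bytes.

## Known limitations

- The global preprocessing mode leaks test statistics by design (fidelity
  to the classical pipeline); use `fold-safe` for unbiased estimates.
- ECOD omits skewness-based side selection (see above).
- The one-component GMM default cannot model multi-modal normality;
  raise `components` where that matters.
- Hyperparameter search is out of scope: defaults are documented constants,
  exposed through `ScorerSpec`, not optimized per dataset.
- Fractional one-hot substitution produces baseline vectors that are not
  valid one-hot rows; detectors score them anyway, and the deltas remain
  exact, but attributions for categorical features should be read as
  "distance from the average level mix", not "switch to another level".
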