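# Methods

## Problem and scope

`modelrank` formalizes classifier selection for two-class biomedical
screening as a multi-criteria decision problem. Five supervised families
(SVM, random forest, logistic regression, KNN, Gaussian naive Bayes) are
evaluated under one fixed protocol; their measured performance is combined
with literature-coded usability criteria into a decision matrix; and
PROMETHEE II produces a complete ranking with a per-criterion decomposition
of every net flow. The classifiers themselves are scikit-learn estimators —
they are instruments here, not contributions; the package's own substance
is the fuzzy weighting, the Gaussian-preference outranking engine, the
matrix assembly, and the synthetic data model.

## Fuzzy criterion weights

Importances are elicited as labels on a five-level linguistic scale, each a
triangular fuzzy number on [0, 1]:

| label | (l, m, u) | Yager index |
|---|---|---|
| Very High | (0.75, 1, 1) | 0.9375 |
| High | (0.50, 0.75, 1) | 0.75 |
| Medium | (0.25, 0.50, 0.75) | 0.50 |
| Low | (0, 0.25, 0.50) | 0.25 |
| Very Low | (0, 0, 0.25) | 0.0625 |

Defuzzification uses the Yager F1 ranking index, the integral over
α ∈ [0, 1] of the α-cut midpoint, which for a triangular number has the
closed form (l + 2m + u)/4. The centroid index (l + m + u)/3 is provided as
a config-selectable alternative (`method="centroid"`); the two indices give
slightly different crisp values but identical weight *orderings* on this
scale. Crisp values are normalized by their sum, so the weight vector sums
to 1 (asserted to 1e−12) — the convention PROMETHEE needs for flows to stay
in [−1, 1]. All five labels are implemented even though the default
ten-criterion assignment uses only the top three levels.

## Decision matrix

Ten criteria in fixed order: accuracy, recall, precision, F1, ROC-AUC
(percent scale), log loss (raw negated values, direction minimize — the
only minimize criterion), then four qualitative codes in [0, 1]: number of
training samples needed (NOTS), impact of feature scaling (IOFS), impact of
hyperparameter tuning (IOHT, a YES/NO flag coded 1/0), tolerance to
irrelevant attributes (TTIA). The qualitative code values per family
(0.08 / 0.25 / 0.50 / 0.75 / 0.92) ship as a data file
(`data/qualitative_codes.json`); they are literature-derived constants, not
measured quantities, and the package deliberately does not attempt to infer
them from experiments. YES/NO is coded 1/0: any strictly monotone two-point
coding yields the same preference structure, so the transparent choice
wins. The percent scale of the metric columns is preserved (99.0, not
0.99); the auto-spread rule below makes the ranking invariant to any
per-column affine rescaling.

## PROMETHEE II engine

Deviations d_j(a, b) = g_j(a) − g_j(b) (sign-flipped for minimize
criteria) pass through the Gaussian preference function
P_j(d) = 1 − exp(−d²/2s_j²) for d > 0, else 0. Aggregation, flows and the
complete ranking follow the standard (n−1)-normalized definitions.
Unicriterion net flows φ_j(a) = (1/(n−1)) Σ_b [P_j(a,b) − P_j(b,a)] give
the decomposition Φ(a) = Σ_j w_j φ_j(a) (the identity behind the rainbow
diagram; re-asserted to 1e−10 at report-writing time). Only the rainbow
*numbers* are computed; no plot rendering is included.

Numerical choices:

* **Spreads.** The Gaussian parameter s_j defaults to `"auto"`: the
  population standard deviation (ddof = 0) of criterion j's column, with a
  fallback to half the column range if the deviation vanishes. A constant
  column carries no preference information at any spread; requesting an
  auto spread there with positive weight raises a configuration error
  rather than silently keeping an inert criterion. Explicit per-criterion
  spreads are accepted in the config and the spreads actually used are
  always logged at INFO, since they are the main free parameter of the
  method. Note that dominance results (a best-or-tied alternative has
  Φ⁻ = 0 and rank 1) hold for *any* positive spreads.
* **Ties.** `rank_complete` breaks net-flow ties alphabetically by
  alternative name — deterministic and order-independent.
* **Weights.** `compute_flows` validates Σw = 1 to 1e−8 and rejects
  negative weights; normalization is the caller's job (the fuzzy module and
  the criteria-config reader both normalize).
* **Preference bounds.** P is computed with `expm1`, so small deviations do
  not lose precision; mathematically P < 1, though float arithmetic
  saturates to 1.0 for deviations ≫ s.
* Partial (PROMETHEE I) preorders, other preference-function shapes, GAIA
  and sensitivity intervals are out of scope.

## Benchmarking protocol

Pipeline per fold: Tukey winsorizer → standard scaler → PCA → classifier,
wrapped in stratified k-fold CV (default 10 folds, shuffle, fixed seed).
Fitting all preprocessing inside the training folds is a deliberate
strictness choice: fitting fences/scales/components on the full data leaks
fold statistics and measurably shifts metrics on noisy data (guarded by a
regression test).

* **Winsorization.** An outlier is a value outside the Tukey fences
  Q1 − k·IQR / Q3 + k·IQR with k = 1.5 (configurable); it is replaced by
  the 25th/75th-percentile value, not the fence. Quartiles use linear
  interpolation. Constant columns pass through (IQR = 0 collapses the
  fences onto the constant).
* **PCA.** Retained variance defaults to 0.95; `variance_retained=1.0`
  keeps the full min(n−1, p) basis.
* **Metrics.** Accuracy, precision, recall, specificity and F1 come from
  the held-out confusion matrices; a metric with a zero denominator is
  reported as NaN (undefined, distinct from 0) with a warning. ROC-AUC is
  the trapezoidal-rule area over held-out scores; log loss uses the natural
  log with probabilities clipped at 1e−15 and is reported negated, so the
  decision-matrix column holds negative values and is minimized.
* **Aggregation.** Default `"folds"`: rate metrics are averaged over folds
  and F1 is then recomputed as the harmonic mean of the averaged precision
  and recall, keeping the reported triple internally consistent;
  `"pooled"` (summed confusion matrices, pooled scores) is available.
* **Grid search.** Exhaustive, selected by mean CV accuracy with a
  deterministic first-listed tie-break. Default grids: k ∈ 1..41 (KNN),
  C ∈ {0.1, 1, 10, 100} with RBF kernel (SVM), n_estimators ∈
  {5, 10, 50, 100} (random forest); logistic regression and naive Bayes
  stay at library defaults. Everything is seeded; the same seed gives
  bit-identical fold assignments and metrics.

## Synthetic data model

The generator emulates the *shape* of the Wisconsin diagnostic data so the
full pipeline is exercisable offline: 357 + 212 samples, 30 features, 10
informative. Class conditionals are multivariate Gaussians (real
cell-nucleus features are roughly unimodal per class); the first 6
informative features share compound-symmetry correlation 0.7, mimicking the
radius/perimeter/area redundancy; the remaining 20 columns are pure
standard-normal noise. The class-mean difference is drawn along a random
direction and scaled so its *Mahalanobis* distance equals
`class_separation` (default 4), making separations comparable across
correlation settings; the Bayes-optimal accuracy is then Φ(separation/2),
e.g. 0.977 at separation 4. Outliers are injected multiplicatively
(default: 2% of cells × 10), mimicking heavy-tailed measurement errors that
the winsorizer is designed to absorb.

What the generator does *not* emulate: skewed/log-normal marginals, the
mean/SE/worst triplet structure of the real feature set, label noise, and
ordinal BIRADS attributes. Consequently, passing tests demonstrate the
pipeline's correctness and the method's behavior under controlled signal,
not expected metric values on the real datasets — which is why the
published decision matrices are consumed directly as bundled inputs rather
than re-derived.

A note on attainable accuracy: near the 0.977 Bayes ceiling at separation
4, margin-based and well-specified models (SVM, logistic regression, naive
Bayes) land around 0.95–0.96 CV accuracy, while nonparametric families
(KNN, random forest) lose a few points to the 20 noise dimensions
(≈ 0.93 at the grid-best settings). This gap is intrinsic to the stated
data conditions — an independent no-preprocessing scikit-learn check
reproduces it — not an artifact of the pipeline.

## Test problem sizes

Generator-behavior tests (null-signal AUC, separation monotonicity) run at
n ≈ 200–250 with 5 folds and library-default hyperparameters — large
enough for stable fold averages of the quantities under test. The
end-to-end run uses the full 569 × 30 conditions with 10 folds and the
complete grids. Distributional checks on the generator (Mahalanobis
separation, block correlation) use n = 8000–10000 draws.
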