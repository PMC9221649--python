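# modelrank

Fuzzy-weighted PROMETHEE II ranking of classifier families for biomedical
screening model selection.

Picking a machine-learning model for a clinical screening task (the driving
application is benign/malignant breast-tumor classification) is rarely
decided by accuracy alone: decision-makers also care about how much training
data a model needs, whether it must be scaled or tuned, and how it copes with
irrelevant attributes. `modelrank` treats model selection as a multi-criteria
decision problem. It benchmarks five standard classifier families — SVM,
random forest, logistic regression, k-nearest neighbors and Gaussian naive
Bayes — under one fixed protocol, combines the measured metrics with coded
qualitative criteria into a ten-criterion decision matrix, and ranks the
models with the PROMETHEE II outranking method.

## Method

**Benchmarking protocol.** Tukey-fence winsorization (values beyond
Q1 − 1.5·IQR / Q3 + 1.5·IQR are replaced by the 25th/75th-percentile
values), standard scaling, PCA to 95% retained variance, stratified 10-fold
cross-validation, and an exhaustive hyperparameter grid search per family —
all preprocessing fitted on training folds only. Measured criteria:
accuracy, recall, precision, F1, ROC-AUC (as percentages) and negated log
loss (minimized on the raw negative values).

**Fuzzy criterion weights.** Each criterion's importance is a linguistic
label on a five-level scale represented by triangular fuzzy numbers
(l, m, u) on [0, 1]; e.g. Very High = (0.75, 1, 1). Labels are defuzzified
with the Yager index

    F(l, m, u) = (l + 2m + u) / 4,

the integral of α-cut midpoints, and normalized so Σⱼ wⱼ = 1. The default
assignment gives the six performance metrics Very High weight, the three
usability criteria (training samples needed, impact of feature scaling,
impact of hyperparameter tuning) High, and tolerance to irrelevant
attributes Medium.

**PROMETHEE II.** For alternatives a, b and criterion j with deviation
d = gⱼ(a) − gⱼ(b) (sign-flipped for minimize criteria), the Gaussian
preference function

    Pⱼ(d) = 1 − exp(−d² / 2sⱼ²)  for d > 0,  else 0

damps small deviations so rankings are not driven by rounding noise; the
spread sⱼ defaults to the population standard deviation of criterion j's
column. Aggregated preference indices π(a, b) = Σⱼ wⱼ Pⱼ(a, b) yield the
outranking flows

    Φ⁺(a) = 1/(n−1) Σ_b π(a, b),   Φ⁻(a) = 1/(n−1) Σ_b π(b, a),
    Φ(a) = Φ⁺(a) − Φ⁻(a),

and alternatives are ranked by descending net flow Φ. The unicriterion net
flows φⱼ(a) satisfy Φ(a) = Σⱼ wⱼ φⱼ(a); the weighted terms are the segments
of the "rainbow" contribution decomposition showing which criteria carry
each model's rank.

## Worked example

The package bundles the published ten-criterion decision matrix of the five
families benchmarked on the Wisconsin diagnostic breast cancer data
(`wisconsin_example()`; a BIRADS mammographic-mass counterpart is
`mammographic_example()`):

```python
from modelrank import compute_flows, rank_complete, wisconsin_example

flows = compute_flows(wisconsin_example())
print(rank_complete(flows))
```

prints

```
 rank         alternative  phi_plus  phi_minus  phi_net
    1                 SVM    0.7956     0.0000   0.7956
    2                 KNN    0.2722     0.2101   0.0621
    3       Random Forest    0.0746     0.3110  -0.2364
    4         Naive Bayes    0.0385     0.3421  -0.3036
    5 Logistic Regression    0.0289     0.3465  -0.3176
```

SVM's negative flow is exactly 0.0000: it is best-or-tied on every one of
the ten criteria, so no other model is ever preferred to it and dominance
forces Φ⁻(SVM) = 0 and rank 1 for *any* positive spreads and weights. The
remaining flows depend on the Gaussian spreads (here the auto
population-std rule). `flows.contributions()` decomposes each net flow by
criterion; for SVM the largest positive segments come from ROC-AUC, log
loss, precision and accuracy.

The `examples/` directory holds short narrative scripts — the worked
example above (`rank_published_benchmark.py`), the fuzzy weight derivation
(`fuzzy_criterion_weights.py`), and a full simulate → benchmark → rank run
on synthetic data (`simulate_bench_rank.py`). The same pipeline is exposed
as a CLI:

```
modelrank simulate --out data.csv --seed 7
modelrank bench --data data.csv --out-dir results/
modelrank rank --matrix results/decision_matrix.csv --out-dir results/
```

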