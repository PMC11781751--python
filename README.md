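# lbwdetect

Unsupervised, interpretable anomaly detection for low-birth-weight screening
from first-trimester cohort data.

Low birth weight (LBW, < 2500 g) and its nested severer forms — very low
(VLBW, < 1500 g) and extreme (ELBW, < 1000 g) — are rare outcomes: in a
typical cohort the three tiers affect roughly 11.6%, 1.3% and 0.5% of
pregnancies. At that imbalance, supervised classifiers need aggressive
re-sampling that distorts the decision boundary. `lbwdetect` instead treats
each tier as a **one-class anomaly-detection problem**: detectors are fitted
only on normal-weight pregnancies, and at test time every pregnancy receives
an anomaly score

    S(x) = φ(x),   higher = more anomalous,

from the detector's decision function φ. The package is aimed at
biostatisticians and ML researchers studying rare perinatal outcomes who
need a reproducible, inspectable pipeline rather than a black box.

## What's inside

- **`lbwdetect.synth`** — a synthetic cohort generator (latent-risk model
  with nested weight thresholds, mixed numeric/binary/categorical features,
  MCAR missingness) so the whole stack is testable without access to any
  private clinical registry.
- **`lbwdetect.preprocess`** — strict `<` weight stratification at
  2500/1500/1000 g, mean/mode imputation, Yes/No → 1/0 and full one-hot
  encoding, min-max scaling to [0, 1], and the normal-only train / mixed
  test split.
- **`lbwdetect.detectors`** — six natively implemented scorers (isolation
  forest with per-tree path lengths, HBOS, ECOD, kNN distance, Gaussian
  mixture, PCA reconstruction error) plus an adapter contract that wraps
  any external fit/score pair with a declared score orientation.
- **`lbwdetect.evaluate`** — 2×5-fold stratified cross-validation with
  both classes guaranteed in every test fold, Mann–Whitney AUCROC, average
  precision (AUCPR, chance level = prevalence), and one-way ANOVA F-tests
  across detectors' fold-level AUC values.
- **`lbwdetect.interpret`** — two per-instance attribution methods:
  mean-substitution score perturbation, ΔS_i = S_o − S_{m,i}, for any
  detector, and depth-based local importance for the isolation forest,
  I_i = mean_T |h(x,T) − h(x_i′,T)|; plus average-rank aggregation across
  outlier points.
- **`lbwdetect.cli`** — `lbwdetect synth | run | interpret`.

## Worked example

Generate an 800-pregnancy cohort with a strong injected signal (severity 2,
i.e. informative features shifted two standard deviations in anomalous
rows), evaluate an isolation forest on the LBW tier, and ask which features
drove the outlier scores:

```bash
lbwdetect synth --n 800 --prevalence 0.15,0.05,0.02 --severity 2 \
    --missing-rate 0.05 --seed 7 --out cohort.csv
# wrote 800 rows to cohort.csv
#   lbw: 112 positives (0.1400)
#   vlbw: 34 positives (0.0425)
#   elbw: 13 positives (0.0163)
```

```python
import numpy as np, pandas as pd
from lbwdetect import (ScorerSpec, Preprocessor, infer_schema, make_scorer,
                       make_folds, cross_validate, category_labels,
                       compute_baseline, perturb_attribution,
                       average_feature_ranks)

df = pd.read_csv("cohort.csv")
fm = Preprocessor(infer_schema(df)).fit(df).transform(df)
labels = category_labels(df["weight"].to_numpy())["lbw"]

plan = make_folds(labels, repeats=2, folds=5, seed=7)
report = cross_validate(fm, labels, ScorerSpec("iforest", seed=7), plan,
                        category="lbw")
print(report.summary())
#  category detector  auc_roc  auc_pr
#       lbw  iforest 0.860889 0.60436

normal = np.flatnonzero(labels == 0)
model = make_scorer(ScorerSpec("iforest", seed=7)).fit(fm.X[normal])
baseline = compute_baseline(fm, rows=normal)
attrs = [perturb_attribution(model, fm.X[i], baseline, fm.feature_groups())
         for i in np.flatnonzero(labels == 1)]
print(average_feature_ranks(attrs).head(6))
# cat_01    5.312500
# num_01    6.053571
# num_03    6.156250
# cat_03    6.767857
# bin_01    7.187500
# bin_02    7.419643
```

Reading the numbers: the detector separates LBW from normal pregnancies
with AUCROC ≈ 0.86 (0.5 is chance) and AUCPR ≈ 0.60 against a 0.14
prevalence baseline. The attribution table lists mean feature ranks across
all labeled outliers (lower = more influential); five of the six
best-ranked features are exactly the ones the generator injected the
anomaly signal into (`num_01`, `num_03`, `bin_01`, `bin_02`, `cat_01`).

A full multi-detector experiment, including the cross-model F-test and
attribution CSVs, runs from a YAML config via `lbwdetect run --config
exp.yaml`; `lbwdetect interpret` replays a fitted model bundle on new
instances.

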