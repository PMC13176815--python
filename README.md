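# pacv — participant-aware cross-validation benchmarking

`pacv` is a toolkit for validating classifiers on **repeated-measures
data**: datasets where each participant contributes several correlated
trials (hop tests, gait cycles, wearable-sensor sessions, repeated clinical
assessments). On such data, trial-wise cross-validation quietly places
trials of the same person on both sides of a split. A model can then score
well by recognising the *person* rather than the *class*, and reported
accuracy inflates — sometimes dramatically. The effective sample size of a
repeated-measures dataset is the number of participants, not the number of
trials.

The package is aimed at biomechanics / digital-health researchers who need
to choose (and defend) a validation design, and at methodologists who want
to quantify how much a given design leaks.

## What it implements

For a trial-level dataset `D = {(x_i, y_i, p_i, t_i)}` (features, binary
label, participant ID, within-participant trial index) the toolkit provides:

**Four validation designs**

| design | split unit | tuning |
|---|---|---|
| trial-wise stratified K-fold (k=10) | trial | fixed config |
| group K-fold (k=3) | participant | fixed config |
| leave-one-participant-out (LOPOCV) | participant | fixed config |
| nested: LOPO outer × group-3 inner | participant | inner grid search |

The nested design selects, per held-out participant, the hyperparameter
configuration θ\* maximising macro-F1 averaged over the inner group folds;
configurations within 0.5 percentage points of the best are treated as
indistinguishable and the lowest-capacity one wins. θ\* is refit on the full
outer-train set and evaluated once on the held-out participant — tuning
never touches outer-test data.

**Statistics**

- confusion-matrix metrics (accuracy, precision, recall, F1, MCC) with
  pooled and participant-averaged summaries;
- the train–test gap `Gap⁽ᶠ⁾ = Acc(train⁽ᶠ⁾) − Acc(test⁽ᶠ⁾)` per outer fold
  (participant-aware schemes only);
- validation bias `Δ = metric(strategy) − metric(participant-aware
  baseline)` per metric, and the mean absolute bias (MAB) over the five
  metrics;
- participant-level rank stability: within each participant the models are
  ranked by accuracy (rank 1 = best, ties averaged), then summarised as
  mean/SD/best/worst rank per model;
- computational efficiency: training time per fold (nested includes the
  inner search), inference latency per sample, serialized model size.

**Feature pipeline** — 13 time-series descriptors per signal (mean, SD,
variance, skewness, kurtosis, 10th/50th/90th percentiles, lag-1/2
autocorrelation, counts above/below the mean, absolute sum of changes; 48
signals → 624 features), a per-feature rank-sum screen with
Benjamini–Hochberg control, a single pooled gradient-boosting importance
ranking frozen to a top-10 set before any CV, per-fold z-scaling fit on
train splits only, and 101-point cubic-spline time normalization of raw
stance-phase signals.

**Synthetic cohort generator** — a random-effects model
`x_pt = y_p·β + u_p + ε_pt` with participant signatures
`u_p ~ N(0, σ_p² I)` and trial noise `ε_pt ~ N(0, σ_e² I)`, shaped like a
post-ACLR hop-test cohort (72 participants, participant-constant 36/36
labels, 5–10 trials each, optionally 48 raw waveforms per trial). The
intraclass correlation `ICC = σ_p²/(σ_p²+σ_e²)` dials the leakage severity,
so the inflation phenomenon is reproducible without any external data.

**Ten classifier families** behind one adapter contract — KNN, logistic
regression, LDA, QDA, AdaBoost, gradient boosting, extra trees, random
forest, and (when installed) XGBoost / LightGBM — plus a dependency-free
built-in L2 logistic-regression classifier, each with a small
capacity-ordered tuning grid.

## Worked example

```bash
pacv demo-leakage --seed 42
```

```
synthetic cohort: 72 participants, ICC=0.90, class effect delta=0.4
stratified 10-fold pooled accuracy: 0.996 (participant mean 0.995)
LOPOCV pooled accuracy:            0.645 (participant mean 0.640)
inflation delta (stratified - LOPO): +0.351
```

The same classifier, the same data: trial-wise splitting reports 0.996 while
honest participant-level evaluation yields 0.645. The `--null` variant sets
the class effect to zero, so there is *nothing real to learn* — yet
trial-wise CV still reports near-perfect accuracy:

```
synthetic cohort: 72 participants, ICC=0.90, class effect delta=0.0
stratified 10-fold pooled accuracy: 0.996 (participant mean 0.995)
LOPOCV pooled accuracy:            0.588 (participant mean 0.581)
inflation delta (stratified - LOPO): +0.409
```

LOPOCV sits at chance, as it should; the 0.996 under trial-wise CV is pure
identity leakage.

The full benchmark (every strategy × model, with report tables
`metrics.csv`, `gaps.csv`, `bias.csv`, `ranks.csv`, `efficiency.csv`,
per-trial predictions and a reproducibility manifest):

```bash
pacv benchmark --strategies stratified_kfold,group_kfold,lopo,nested \
               --models builtin_linear,knn --seed 42 --out run/
```

Library use mirrors the CLI:

```python
from pacv import GeneratorConfig, generate_feature_table, StrategySpec, run_strategy
from pacv.evaluation import pooled_overall

table = generate_feature_table(GeneratorConfig(seed=42))
folds = run_strategy(table, StrategySpec(name="lopo"), "knn")
print(pooled_overall(folds, "accuracy"))
```

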