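# Methods

## The problem being modelled

A repeated-measures classification dataset consists of trials nested in
participants, with the label constant within a participant (here: a binary
fear-of-reinjury style outcome). Trials from one person are correlated —
each individual has a stable movement signature — so the observations are
not i.i.d. and the effective sample size is close to the number of
participants. A validation split that ignores participant identity lets a
classifier match test trials to training trials from the same person and
read the label off that match. `pacv` exists to measure that failure mode
and to provide the participant-aware designs that avoid it.

## Validation designs

All four schemes partition the trial set into test folds exactly once.

- **Trial-wise stratified K-fold** (default k=10, shuffled with the run
  seed): per-class test counts differ by at most one across folds;
  participants may straddle folds. This is the leaky baseline, implemented
  via scikit-learn's `StratifiedKFold(shuffle=True)`.
- **Group K-fold** (default k=3): participants are atomic. Assignment is a
  deterministic greedy rule — participants sorted by trial count descending
  (ties by ID) go to the fold with the smallest running trial total (ties
  by fold id). This balances trial counts like standard group-K-fold
  implementations while being exactly reproducible without a seed. With
  71 participants contributing 5–10 trials each, the rule yields
  participant groups of 24/24/23, so the largest inner training split in
  the nested design holds 48 participants.
- **LOPOCV**: one fold per participant, ordered by ascending participant ID
  so per-participant outputs align across models.
- **Nested**: LOPO outer evaluation; within each outer-train set, a
  group-3 inner split of the remaining participants drives the grid search.
  The executed inner splits are recorded on each fold result so tests can
  audit the realised plan, not just the declared one.

Requesting a nested plan with fewer than `inner_k + 1` participants fails
loudly rather than silently shrinking the inner loop.

## Inner selection

Each grid configuration is trained on every inner-train split (feature
scaling refit per split) and scored on the corresponding inner-validation
split; scores are averaged over the three inner folds. The default score is
macro-F1 (mean of the two per-class F1 values, zero-denominator → 0), with
plain accuracy available via `inner_metric="accuracy"`. Among
configurations whose mean score is within 0.005 (0.5 percentage points) of
the maximum, the one with the lowest capacity index wins — at
indistinguishable skill the simpler model has lower variance. Grids are
ordered so index 0 is always the simplest configuration (most neighbors,
strongest regularization, shallowest trees). A configuration that fails to
fit on any inner fold is excluded with a warning; if all fail, the run
errors out rather than imputing scores.

## Metrics and aggregation

Confusion-matrix metrics treat class 1 as positive and use the conservative
zero-denominator conventions (precision/recall/F1 → 0; MCC → 0 when any
marginal is empty). These conventions are load-bearing: a held-out LOPO
participant is single-class, so the degenerate cases occur on every run,
not just at the margins. Accuracy is summarised both participant-averaged
(equal weight per individual; sample SD across participants) and pooled
(all test predictions concatenated, weighting participants by trial
count); the other four metrics are primarily reported pooled for the same
degeneracy reason. The train–test gap (train accuracy minus test accuracy
per outer fold, mean and sample SD across folds) is computed only for LOPO
and nested runs; it is refused for the trial-wise and group schemes where a
shared participant or tuning overlap makes it uninterpretable.

Dispersions (across participants, across folds) use the sample SD (n−1)
throughout.

## Bias, ranks, efficiency

Bias Δ is the strategy's metric minus the participant-aware baseline's
(default baseline LOPOCV, switchable to nested), computed by default on
pooled metrics; MAB is the mean of |Δ| over the five metrics. Rank
stability ranks the models within each participant by accuracy (rank 1 =
best, ties averaged — two tied top models each get 1.5) and summarises
mean/SD/best/worst across participants; tie-averaging preserves the row sum
n(n+1)/2. Efficiency records mean wall-clock training time per fold (the
nested figure includes the entire inner search), total prediction time over
total test samples in ms, and the pickled model size in MB (mean across
folds). Timing values are measured with a monotonic clock and are the only
non-deterministic outputs; tests compare them ordinally, never absolutely,
and the unrounded inference latency is reported alongside a
rounded-to-the-nearest-ms display column.

## Synthetic generator

Feature mode draws `x_pt = y_p·β + u_p + ε_pt` with `u_p ~ N(0, σ_p² I)`
once per participant and `ε_pt ~ N(0, σ_e² I)` per trial; β carries the
class effect δ on the first `n_informative` coordinates. Defaults mirror
the emulated cohort: 72 participants, 36/36 participant-constant labels,
trial counts i.i.d. uniform on {5..10} (an optional hook pins per-class
trial totals, e.g. 301/322, for study-shaped fixtures), 10 features,
δ=0.6, σ_p=σ_e=1 (ICC 0.5). Signal mode instead draws, per participant and
signal, coefficients of three sinusoids over the unit interval (class
offset on the first harmonic of informative signals, trial-level
coefficient noise), at raw lengths uniform on 80–160 — deliberately
un-normalized so the 101-point resampling step has real work to do.

The leakage demonstration uses σ_p=1.5, σ_e=0.5 (ICC 0.9) and δ=0.4 with a
nearest-neighbor classifier: a strong identity signature with a weak class
effect, the regime where trial-wise validation is most misleading. The
zero-effect variant (δ=0) bounds honest accuracy at chance, so anything a
trial-wise split reports above chance is leakage by construction.

Randomness uses one root `SeedSequence` spawned into disjoint substreams
(cohort structure, participant effects, trial noise, signal phases), so
changing the feature count never perturbs trial counts or labels.

What the generator does *not* emulate: real biomechanical waveform shapes,
inter-feature correlation structure, heteroscedastic participants, label
noise, class imbalance, or missing trials. Passing tests therefore show
that the validation machinery behaves correctly under the random-effects
mechanism — not that any particular accuracy level transfers to real
cohorts.

## Numerical choices

- **Time normalization** is piecewise-cubic natural-spline interpolation
  onto 101 equally spaced points of normalized time; a single global cubic
  polynomial cannot follow an 80–160-sample waveform. Endpoints are
  preserved exactly; inputs shorter than 4 samples are rejected.
- **Descriptors**: SD/variance are population moments (divide by n);
  skewness is the adjusted Fisher–Pearson coefficient; kurtosis is Fisher
  excess; percentiles interpolate linearly; autocorrelation at lag k is
  `Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)²`; counts above/below the mean are
  strict. Zero-variance signals map skewness, kurtosis and the
  autocorrelations to 0. These follow the dominant time-series
  feature-extraction conventions.
- **Univariate screen**: two-sided Mann–Whitney rank-sum per feature
  against the binary label (the standard choice for a real-valued feature
  vs a binary target), Benjamini–Hochberg at α=0.05; zero-variance features
  get p=1.
- **Importance ranking** fits one gradient-boosting ensemble (seed 42) on
  the pooled data and orders retained features by impurity importance, ties
  broken by name. The resulting top-k (k=10 by default) is frozen before
  any CV experiment — feature selection is deliberately outside the
  validation comparison.
- **Scaling**: per-feature train-split mean and population SD; zero-SD
  columns map to 0 on both train and test. Scaling is refit inside every
  training split of every scheme, including inner folds.
- **CSV round-tripping** writes floats with `repr` and reads with
  pandas' round-trip parser so write→read is exactly the identity.

## Design choices that were genuinely open

- Group-fold balancing could target participant counts or trial counts; we
  balance trial counts (matching common implementations) and verified that
  participant counts then differ by at most one under the 5–10 trials/
  participant regime.
- The inner selection metric is macro-F1 by default with an accuracy
  switch, reflecting that either is defensible for a balanced binary task.
- The built-in linear classifier exists so the full pipeline (including
  nested tuning) runs with zero optional dependencies; it is plain
  full-batch gradient descent on the L2-regularized logistic loss,
  deterministic by construction.

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run entirely on generated data:
the study-shaped 72-participant cohort (~540–620 trials, 10 features) for
structural and leakage checks, and 6–12-participant cohorts for exhaustive
nested-tuning and reporting checks. The leakage demonstration uses the
nearest-neighbor and built-in linear classifiers, which keep a full
strategy × model benchmark at these sizes in the tens of seconds.

## Known limitations

- Binary labels only; no multi-class, no missing data, no trial-level
  exclusion rules.
- No ROC/AUC or probability calibration, and no statistical tests on rank
  differences — the comparison stops at descriptive stability statistics.
- Fixed configurations default to the backing libraries' documented
  defaults, and tuning grids are small capacity-aware spans; both are
  overridable per run, and users reproducing a specific published setup
  should supply its exact grids via configuration.
- Wall-clock efficiency numbers are hardware-dependent by nature; only
  their ordinal relationships are meaningful.
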