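# Methods

This note documents the models, protocols and numerical choices behind
`rnnlr`, in the order data flows through the pipeline.

## Cohort schema

A cohort is a flat CSV, one row per clinical record, patient-level columns
repeated per row, empty cell = missing lab (never `0`; `NA`/`NaN` accepted
on read, never written).  Day offsets are whole days since surgery, 0-based
and half-open [0, 3): each patient has 1–3 records on distinct days 0/1/2.
The 18-analyte laboratory panel with clinically valid closed ranges
(albumin 0.19–5.5 g/dL … sodium 10–190 mEq/L) ships as
`rnnlr/data/analyte_panel.json`; age is validated on [0, 102] and the
prior-hospitalisation count (DGTM) on [0, 136].  Validation reports
violations as data — nothing is ever silently clipped on input.  The 17
Charlson comorbidity categories are boolean columns; the 7 operation
categories an integer code.  Outcome labels are `neither`/`AHE`/`HRS`
(class order fixed: neither=0, AHE=1, HRS=2).

## Synthetic cohort generator

The generator emulates the shape of the registry cohort this class of
model is built for, with a known ground truth so recovery is testable:

* **Latent severity.** Each patient draws a `latent_dim`-vector (default 2)
  severity trajectory evolving over the 3-day window by an AR(1) step with
  coefficient 0.8 (stationary N(0,1) margins) — the temporal dependence the
  recurrent model is meant to exploit.  The coefficient is a package
  default, not an empirical estimate.
* **Labs.** Analyte value = panel midpoint + loading·z(day) + Gaussian
  noise (sd = range/12), truncated to the panel range.  Truncation (not
  rejection) keeps the configured missingness and runtime.  Dimension 0 is
  hepatic/renal severity: strong loadings on total bilirubin, creatinine,
  BUN (and INR/lactate), negative on albumin.
* **Outcomes.** Multinomial-logistic on (mean severity, standardised age,
  the four hepatic/renal analytes), all coefficients scaled by the signal
  strength β (default 3.0, at which a held-out linear probe reaches
  one-vs-all AUC > 0.8; β = 0 severs the association entirely).
  Intercepts are calibrated by a fixed-point iteration so empirical class
  frequencies match the configured prevalence at any β.
* **Defaults** reproduce the published cohort shape: 6,545 patients,
  record-count distribution 3665/1951/929 over 1/2/3 records, prevalence
  41 AHE and 174 HRS.  (The source literature reports both 174 and 147 HRS
  patients, and minority shares of 0.6%/1.1% that do not match the raw
  counts; the defaults follow the raw counts and this note records the
  discrepancy rather than resolving it.)
* **Missingness** is MCAR at `missing_rate` (default 0.15, a package
  default — the original missingness mechanism is uncharacterised); an
  optional MNAR switch makes the missing probability increase with
  severity.
* **Annotations.** Complication onset day (AHE 6–17 d, mean 13; HRS 4–47 d,
  mean 14, via matched binomials) and length of stay (≈25 d for
  complication patients vs ≈17 d, sd 5) are metadata columns only — the
  model never consumes them.

What the generator does **not** emulate: the real cohort's joint
demographic distribution, informative lab-ordering patterns, coding noise
in comorbidities, or any survival structure.  Passing tests therefore
demonstrate method correctness and recoverability under a known mechanism,
not clinical performance on real data.

## Imputation

The primary imputer is a denoising autoencoder over per-record lab vectors:
records standardised per analyte on observed statistics, missing entries
initialised at the analyte mean (0 after standardisation), symmetric
architecture 18→32→16→32→18 with ReLU hidden layers, Adam (lr 1e-3,
200 epochs), reconstruction loss on **observed** entries only.  The
architecture is a package default chosen for small cohorts and CPU
training.  Analytes with no observed values fall back to the panel-range
midpoint with a warning.  Imputed values are clipped to panel ranges;
observed cells are never altered.  Mean and kNN imputers (k nearest
complete-case records, Euclidean distance on the standardised analytes
observed in the focal record) serve as protocol baselines.

**NRMSE.** The masked-holdout error is computed per analyte — RMSE over
held-out cells divided by that analyte's mean in the complete reference
data — and averaged unweighted across analytes with ≥1 holdout cell.  The
panel spans four orders of magnitude, which makes a single global
denominator uninterpretable; the global variant is available behind
`per_analyte=False`.  Analytes with zero reference mean are excluded with
a warning.  The imputer is always fitted on the training split only.

## Sequences

Min-max scaling to [0, 1] is fitted on the training cohort (labs plus age
and DGTM); test values may leave [0, 1] — intentional, no clipping.  The
zero pad then sits near the feature minima rather than at a mid-range
value.  Real records occupy the trailing slots in day order; padded slots
are exactly zero; `day_offset/3` is appended as a per-record feature so
within-window timing survives slot alignment.  Static features (sex,
scaled age/DGTM, 17 comorbidity flags, 7-way operation one-hot, 3
complication flags; S = 30) stay separate and enter at the classifier
head.  A `pad_mask` is carried; the default model consumes the raw
zero-padded slots, with a mask-aware recurrence (state updates skipped on
padded slots) behind `ModelConfig(mask_aware=True)`.

## Resampling

First-principles SMOTE (synthetic sample = xᵢ + u·(x_nn − xᵢ), u uniform,
x_nn among the k same-class nearest neighbours) followed by single-pass ENN
(remove any sample whose k-NN majority label disagrees with its own; vote
ties remove).  Defaults k_smote = 5, k_enn = 3, strategy "equalise
minorities to the majority" — the conventional configuration.  Resampling
operates on whole per-patient flattened trajectories (3 padded slots ⊕
statics) so every synthetic unit is a coherent patient, and is applied
after the 80/20 split, training side only — standard leakage prevention.

## Model and training

Architecture as in the README: 8 tanh Elman layers × 16 units over 3 time
steps, hidden state linearly projected to 64 values reshaped 8×8 (**D** —
this projection reconciles the 16-unit layer width with the 8×8 embedding),
global trainable 8×8 latent regulator **H** initialised N(0, 0.1²), head
input flatten(D) ⊕ flatten(D·H) ⊕ statics through dense 128→64→32→3 with
ReLU and dropout 0.2 at the recurrent/dense junction.

The **combined effect** of the embedding and the regulator is realised as
the matrix product D·H rather than by feeding H's entries to the head
directly: a globally shared constant input block is absorbed by the first
dense layer's bias and would make the H-ablation a comparison of two
identical-capacity models, whereas D·H lets H act as a learned linear
operator on the disease-progression embedding (and dies exactly when H is
frozen at zero, giving the ablation teeth).  Column j of D·H depends only
on H's column j, so attribution reports it as "hidden j".

Recurrent weight matrices are initialised orthogonally (QR of a Gaussian);
Glorot initialisation degrades signal propagation noticeably through the
8-layer tanh stack.  All parameters including H are trained jointly by
Adam at γ = 0.01 with coupled L2 weight decay λ = 0.005 and the
cost-weighted cross-entropy (`weighted_ce`; `expected_cost` mode minimises
the smooth expected-cost surrogate instead).  The learning rate follows a
cosine schedule annealing to exactly 0 on the final epoch (default 100
epochs, batch 256): the anneal realises the intended "converges to a
stable range" behaviour of H, whose per-epoch Frobenius delta is recorded;
`i_min` reports the first epoch below the tolerance (1e-4).  A constant-γ
schedule is available.  γ = 0 leaves every parameter exactly unchanged.
Ties at argmax resolve to the lowest class index (neither < AHE < HRS);
dropout is disabled at inference, making prediction deterministic.

## Evaluation

One-against-all per class: TP/FP/FN read off the confusion matrix,
0/0 → 0 with a warning; AUC uses the positive-class probability as the
ranking score (trapezoidal, equal to the normalised Mann–Whitney U
statistic, ties one half); PR curves at unique score thresholds with both
endpoints.  AUC/PR computations delegate to scikit-learn and are
cross-checked in the tests against O(n²) all-pairs and per-threshold
oracles.  Rendered tables round half-up to 2 decimals.  Repeated trials
differ only by seed; paired two-sided t-tests run on seed-matched
differences, with zero-variance difference vectors treated as exact ties.

## Attribution

A model-agnostic permutation-sampling Shapley estimator replaces
backend-specific deep attribution: for random feature orderings, features
switch from a baseline (dataset means) to the instance value and marginal
score changes are averaged; the telescoping sum makes efficiency exact per
permutation, additive functions exact for any sampling, and dead inputs
exactly zero.  It is applied at two layers: the classifier-head input
(64 embedding units "RNN unit j" ⊕ 8 latent-regulator column blocks
"hidden j") and the raw input (each analyte as a block over its 3 slots,
plus each static feature) through the full network.  The score is the
predicted probability mass on the two complication phenotypes.  Defaults
(test split, mean baseline, 20 permutations, ≤50 instances) are package
choices; the per-feature report is the mean absolute attribution, sorted
descending.

## Pipeline

Stage order: load/simulate → validate → stratified 80/20 split → fit
imputer on train, impute both → fit scaler on train, build sequences →
SMOTEENN on train only → train → evaluate on the untouched test split.
The split is stratified by outcome because with rare phenotypes an
unstratified split can yield empty test classes.  One global seed fans out
to per-stage seeds via `numpy.random.SeedSequence(seed, spawn_key=(stage,))`;
every artifact carries the config hash and seed, and identical config+seed
reproduce reports byte-for-byte.

## Validation study conditions

The stochastic self-checks (`rnnlr.protocols`) run under fixed conditions
chosen for estimator stability, not per-run:

* **Prevalence (0.70, 0.12, 0.18)** for the null/signal/ablation studies.
  At the emulated raw prevalence (0.6%/2.7%) a 20% test split of a
  desk-scale cohort contains ~2 positive cases and a one-vs-all AUC
  estimate has a standard error near 0.2, so any null band would reflect
  estimator noise rather than model behaviour.
* **Null control:** β = 0, n = 2,000, 30 epochs, 5 seeds; per-class mean
  AUC must sit in [0.45, 0.55].
* **Signal recovery:** β = 3, n = 4,000, 60 epochs, 5 seeds, compared to
  a baseline retrained on permuted training labels with identical
  features and budget.
* **Regulator ablation:** paired runs (H trainable vs frozen at zero) on
  the same cohorts and seeds, n = 2,000, 60 epochs, 5 seeds; reported as a
  directional mean difference.  Sixty epochs because comparisons between
  undertrained models are dominated by optimisation noise.
* **Imputation benchmark:** ordering check (autoencoder vs mean imputer,
  paired over 10 seeds, one-sided sign test) on n = 800 cohorts at 20%
  masking; monotonicity check (30% vs 20% masking for the mean imputer)
  on n = 150 cohorts with *nested* masks — the 20% holdout is a random
  subset of the 30% holdout — a variance-reduced pairing of the same
  protocol, since with independent masks the tiny true effect is swamped
  by holdout sampling noise.
* Smaller epoch budgets than the 100-epoch default are used throughout
  these studies; they are package choices recorded here.

## Known limitations

* The deep 8-layer Elman stack is hard to optimise; its held-out AUC on
  synthetic cohorts (~0.6–0.7) sits well below a linear probe on the same
  features (~0.9).  The architecture is kept as specified rather than
  tuned past it; shallower stacks train markedly better.
* With phenotype cost 200 the thresholded predictions are deliberately
  alarm-biased (near-zero `neither` precision on balanced-ish synthetic
  cohorts); the AUC columns and the `min_expected_cost` rule are the
  intended read-outs.
* SMOTE on flattened trajectories can interpolate between patients with
  different record counts, producing partially padded synthetic slots; a
  slot counts as real when any feature is nonzero.
* Byte-identical reproducibility is guaranteed on a fixed platform/BLAS;
  across platforms, floating-point reduction order may differ.
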