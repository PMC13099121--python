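# Methods

## Overview

`gaoof` evaluates a genetic-algorithm (GA) derived composite health-risk
score under a nested out-of-fold (OOF) validation framework on annual
health-checkup cohorts. The pipeline has six stages — synthetic cohort
generation, threshold grading and OR-rule labelling, fold-internal
preprocessing, GA weight optimization, Platt calibration, and bootstrap
uncertainty — each implemented as an importable module with an explicit
contract. This note records the statistical model, the defaults and why,
and the design choices made where the design was genuinely open.

## Outcome construction

Each of five clinical domains (glucose metabolism, blood pressure, lipids,
liver enzymes, anthropometry) grades its contributing indicators through
contiguous threshold intervals into A (no abnormality), B (mild
abnormality), C (follow-up) or D (referral). The domain grade is the
**worst** grade among its indicators; an institutional system might instead
use a designated primary indicator, but worst-case aggregation is the
conservative screening convention and the only one that makes the domain
grade monotone in every indicator. A domain whose contributing indicators
are all missing defaults to grade A with a logged flag rather than dropping
the participant: the OR rule means outcome ascertainment never depends on a
single domain, and dropping would distort prevalence. The composite label
is `1` iff any domain grade is B or higher; grade-E participants (already
under treatment) are excluded before labelling.

The shipped grading rule set is a **synthetic fixture**: round-number
thresholds loosely modeled on Japanese screening conventions (e.g. SBP
130/140/160, fasting glucose 100/110/126, sex-specific waist 85/90 vs
90/95). It is explicitly non-authoritative and fully replaceable via JSON.
Interval semantics: a value equal to a breakpoint falls in the upper
interval, so 130 mmHg is already grade B.

## Synthetic cohort generator

The generator is first-class, tested code: it is the only way to exercise
the pipeline with *known* ground truth.

* **Continuous indicators** are drawn from a 13-dimensional Gaussian with a
  three-factor (metabolic / lipid / hepatic) correlation structure — PSD by
  construction — then affinely mapped to clinical-looking units. Grading
  thresholds are defined on the mapped scale, which decouples correlation
  structure from threshold placement.
* **Lifestyle items** are independent Bernoulli with marginals between 0.15
  and 0.45.
* **Outcome (generative path)**: a latent linear predictor
  `eta = w_trueᵀ x_std + c` with the intercept `c` found by bisection so the
  mean of `sigmoid(eta)` equals the target prevalence (default 0.375);
  `y ~ Bernoulli(sigmoid(eta))`. The default true weights form a moderately
  discriminative metabolic-risk pattern whose Bayes-optimal AUC is ≈ 0.81 —
  the regime routine screening scores operate in. `oracle_auc` estimates
  that ceiling by Monte-Carlo concordance of `eta` against `y`.
* **Outcome (grading path)**: applying the fixture rules to the generated
  indicators yields an OR-rule prevalence of ≈ 0.37; the clinical scale
  locations were set jointly with the fixture thresholds (each indicator
  crosses its B threshold for roughly the top 5% of its latent scale) to
  land in that regime.
* **Missingness**: every continuous indicator except HbA1c is masked MCAR
  at rate 0.015 (default; "low, under 2%"). HbA1c is masked **structurally**:
  the fraction (default 0.30, configurable — the real rate is not public)
  of participants with the lowest fasting glucose form the low-risk
  screening stratum the program does not test. This is MNAR-by-policy,
  deterministic given the covariate, and detectably associated with the
  stratum indicator. Outcome labels are never masked.
* **Determinism**: one `numpy` generator seeded from the config; the
  missingness stream is seeded independently (`[seed, 7919]`) so generation
  and masking are separately reproducible.

What the generator does **not** emulate: real joint biomarker
distributions, age structure, within-person correlation across years,
informative grade-E assignment, or missingness in lifestyle items. Passing
tests therefore demonstrate the *framework's* correctness (no leakage,
correct metrics, calibrated uncertainty), not clinical performance on any
real population.

## Preprocessing

Within each training fold, continuous features are median-imputed (median
of observed training values; even counts use the mean of the two central
order statistics) and standardized. The mean/SD are computed **after**
imputation by default, so the training matrix the GA sees has exactly zero
mean and unit SD; an `observed`-moments variant exists behind a switch
because the original convention is ambiguous. Binary lifestyle items are
mode-imputed (ties toward 0) — imputation is only specified for continuous
variables, but the GA needs a complete matrix. Parameters are frozen and
applied unchanged to the held-out fold; a feature fully missing or constant
in a training fold raises an error naming the feature and fold.

## GA scoring

The composite is a plain linear form `s = wᵀx` with no intercept (absorbed
by calibration downstream). The functional form is a package choice — the
simplest consistent with "composite score from standardized features" and
with univariate logistic calibration.

Fitness of a weight vector is the mean held-out midrank AUC over
`inner_k = 5` shuffled stratified folds (deterministic per seed). AUC is
invariant under positive scaling of `w`, so no normalization is needed.

The GA is generational with defaults: population 60, 40 generations,
uniform initialization in [−1, 1], tournament size 3, arithmetic blend
crossover with probability 0.7 (per-gene convex combination with uniform
coefficient), per-gene Gaussian mutation (probability 0.2, σ = 0.1), and
elitism 1. These operator choices and sizes are package defaults — all
exposed in `GAConfig` — selected for robust convergence on 20–21 features
within seconds; the exact original settings are not public. The best
individual **ever evaluated** is returned, so best-ever fitness is
non-decreasing (asserted from the evolution log). The whole population is
scored with one matrix product per generation; all stochastic components
flow through a single seeded generator, making runs bit-reproducible. No
regularization or sparsity pressure is applied; none is described for this
class of score.

## Calibration

Platt scaling fits `p = sigmoid(a + b s)` by Newton iteration with a ridge
penalty of 1e-6 on both coefficients (GA-optimized scores can separate
small folds; the ridge keeps coefficients finite), convergence at gradient
max-norm < 1e-8, at most 100 iterations (non-convergence is flagged and the
best iterate kept). The score is standardized internally for Newton
stability and the coefficients back-transformed. If the GA returns an
inverted score the fitted slope is negative; the model is kept as-is with a
warning — probabilities remain correct. The linear predictor is clipped at
±36 so probabilities stay strictly inside (0, 1).

An optional post-hoc Bayesian layer multiplies the odds by a prior odds
ratio (`odds' = r · p/(1−p)`). It is a transparent reporting device, off by
default, monotone (so AUC-invariant), and excluded from all metrics.

## OOF orchestration

Outer loop: stratified 5-fold with shuffling (K = 5 is the package default;
the loop count is configurable). Within each outer fold the full chain —
preprocessing fit, GA evolution, Platt fit — is re-run on the training
subset only; the held-out fold is only ever transformed and predicted. The
GA is re-evolved per outer fold because that is the only reading of
fold-wise training that admits no leakage; a non-nested variant
(`run_oof_leaky`: global preprocessing, one GA on the full matrix) is kept
exclusively as a negative control, and the test suite demonstrates that it
inflates OOF AUC on null-signal cohorts while the nested pipeline stays at
chance. Under the HbA1c ON condition, structurally missing HbA1c values are
median-imputed within each training fold like any other continuous
variable.

Metrics: midrank Mann–Whitney AUC (ties count 0.5) and the Brier score,
both computed only from the aggregated OOF probabilities; calibration is
summarized as equal-width bin tables (count, mean predicted, observed
fraction) rather than plots.

## Bootstrap uncertainty and the ON/OFF analysis

95% CIs are empirical 2.5/97.5 percentiles over 2000 participant-level
resamples (with replacement, unstratified) of the **already generated**
(probability, label) pairs — models are never refit, preserving the
original cross-validated predictions. Single-class resamples (AUC
undefined) are redrawn with logging so the replicate count stays exact; if
more than 1% of initial draws are single-class the routine refuses and
advises a larger cohort.

The HbA1c ON/OFF sensitivity analysis reruns the entire pipeline twice with
predictor sets differing only by HbA1c, on an identical fold plan (audited
by hash equality). ON−OFF deltas use **paired** resampling — the same
participant draw applied to both aligned OOF vectors — which cannot be wider
than the unpaired interval under positive correlation; the pairing choice
is the package's, since no interval construction for the delta is
prescribed. Both the per-year deltas and their median across years are
reported, the median being the headline robustness summary.

## Reproducibility

One master seed fans out via `numpy.random.SeedSequence(master).spawn()` to
stage seeds (cohort, folds, bootstrap), each reduced mod 2³¹. Every numeric
output embeds the master seed and a SHA-256 hash of the canonical run
config. Two runs of the same config produce byte-identical metric files.

## Problem sizes used in the shipped analyses

The analysis drivers and the acceptance script use three annual cohorts of
n = 3744, 5153 and 5352 with the default GA (population 60, 40
generations) and 2000 bootstrap replicates. The validity checks use the
sizes at which their statistical claims are sharp: 50 null-signal cohorts
of n = 2000 with a reduced GA (population 16, 8 generations — leakage
detection does not require a strong optimizer), signal recovery at n = 5000
with population 40 / 25 generations, and 500 replicate cohorts of n = 1000
with 500 resamples for bootstrap coverage.

## Known limitations

* The fixture grading thresholds are illustrative, not institutional
  criteria; absolute AUC/Brier values on synthetic cohorts (≈ 0.88 / 0.13)
  characterize the synthetic task, not any real screening program.
* The grading-path outcome is a deterministic function of the predictors,
  so discrimination measures reconstruction of the screening rule set, not
  prognosis — mirroring the operational character of such labels.
* Percentile bootstrap only; no BCa or studentized intervals.
* No multiple imputation; median/mode imputation is the specified
  convention.
* The GA optimizes inner-CV AUC only; no multi-objective or sparsity
  variants.
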