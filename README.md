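# gaoof — GA composite health-risk scoring with leakage-safe out-of-fold validation

`gaoof` implements a complete, reproducible analysis pipeline for
**genetic-algorithm (GA) derived composite health-risk scores** of the kind
used in annual health-checkup (Ningen Dock style) screening programs, with a
strict **out-of-fold (OOF) validation framework** that keeps preprocessing,
optimization and evaluation separated so performance estimates are not
inflated by information leakage.

It is written for biostatisticians and epidemiologists who want to evaluate
data-driven risk scores on screening data — and, just as importantly, to
*audit* such evaluations: the package ships a deliberately broken
(non-nested) variant whose inflated results on null-signal data demonstrate
exactly what the nested design prevents.

## The model

Participants carry 13 routine clinical indicators (BMI, waist circumference,
SBP, DBP, fasting glucose, HbA1c, TG, HDL-C, LDL-C, AST, ALT, γ-GT, uric
acid) and 8 binary lifestyle items. Each clinical domain (glucose
metabolism, blood pressure, lipids, liver, anthropometry) is graded A–D by
threshold rules (worst indicator wins; waist thresholds are sex-specific);
grade-E participants (already under treatment) are excluded, and the
composite outcome is the **OR rule**:

```
y = 1  iff  any domain grade ≥ B
```

The risk score is a linear composite of standardized features,
`s = wᵀx`, whose weights `w` are evolved by a generational GA (tournament
selection, blend crossover, Gaussian mutation, elitism) maximizing the mean
held-out AUC over stratified inner K-fold splits. Scores become calibrated
probabilities via Platt scaling, `p = σ(a + b·s)`.

Everything that learns from data is nested inside each outer fold:

* median imputation and standardization are **fit on the training fold only**,
* the GA is **re-evolved from scratch** per outer training fold,
* Platt calibration is fit on training-fold scores only,

so each participant's OOF probability comes from a model that never saw
them. Discrimination (midrank AUC) and overall accuracy (Brier score) are
computed from the aggregated OOF probabilities, with 95% percentile
bootstrap CIs from 2000 participant-level resamples that recompute the
metrics **without refitting** anything. A prespecified **HbA1c ON/OFF
sensitivity analysis** reruns the entire pipeline with and without HbA1c
(which is structurally missing for the screening stratum the program does
not test) on an identical fold plan, with paired bootstrap CIs for the
ON−OFF differences.

Because real institutional checkup data are not publicly available, the
package includes a first-class synthetic cohort generator with *known*
generative structure (true effect weights, target prevalence, MCAR plus
policy-driven MNAR missingness), which makes every claim above testable:
the generative model's Bayes-optimal AUC is a computable ceiling, and
null-signal cohorts are a leakage detector.

## Worked example

```python
from gaoof import (SyntheticConfig, generate_cohort, inject_missingness,
                   default_rules, assign_grades, binarize_or_rule,
                   GAConfig, run_oof, percentile_bootstrap)

cfg = SyntheticConfig(n_participants=3744, year=2021, seed=2021)
cohort = inject_missingness(generate_cohort(cfg), cfg)
labels = binarize_or_rule(assign_grades(cohort, default_rules()))
print(labels.n, round(labels.prevalence, 3))      # 3674 0.363

oof = run_oof(cohort, labels, GAConfig(), outer_k=5, seed=42)
print(round(oof.auc(), 4), round(oof.brier(), 4)) # 0.8803 0.1307

est = percentile_bootstrap(oof, "auc", n_boot=2000, seed=0)
```

`labels.prevalence` is the OR-rule outcome prevalence after grade-E
exclusion (≈0.37 under the default generator). `oof.auc()` is the
probability that a random outcome-positive participant receives a higher
OOF probability than a random negative; `oof.brier()` is the mean squared
error of the OOF probabilities (0.25 would be an uninformative constant
0.5). The bootstrap estimate carries `point`, `ci_lower`, `ci_upper`.

## Analysis scripts

The study-style analysis lives in numbered drivers (run in order from the
repository root; outputs under `results/`):

```bash
python analysis/01_simulate_cohorts.py    # three annual cohorts (n=3744/5153/5352)
python analysis/02_grade_outcomes.py      # A–D grading + OR-rule prevalence
python analysis/03_run_oof.py             # per-year OOF AUC/Brier with bootstrap CIs
python analysis/04_hba1c_sensitivity.py   # HbA1c ON/OFF deltas, paired bootstrap
```

A typical run prints stable year-over-year discrimination (OOF AUC ≈ 0.87–0.88,
Brier ≈ 0.13) and a small positive median ON−OFF ΔAUC (≈ +0.005): excluding
HbA1c barely moves performance because the OR-rule outcome and the
correlated glucose indicator carry most of the signal.

There is also a config-driven CLI (`gaoof simulate|run|sensitivity|report`,
plus the standalone `synth-cohort`) for running the same pipeline from YAML.

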