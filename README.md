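# ckdphen

Computable phenotyping of **advanced chronic kidney disease (CKD)** from
longitudinal hospital records, built for healthcare-integrated biobanking
(HIB): deciding *at admission*, from the limited information then
available, whether a patient's surplus routine samples are worth banking
for a CKD cohort.

Real inpatient records of this kind are restricted by hospital law, so the
package ships a synthetic EHR generator with known ground truth; every
pipeline stage — cohort construction, renal feature extraction,
classification, validation — is exercised end to end against it.

## What it implements

**Renal physiology.** eGFR via the 2009 CKD-EPI creatinine equation (no
race factor),

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.209) · 0.993^age · 1.018[female]

with κ = 0.7/0.9 and α = −0.329/−0.411 (female/male), plus its closed-form
inverse (used by the generator to place patients at exact target eGFR).
Creatinine-based KDIGO acute kidney injury detection (≥ 0.3 mg/dL rise
within 48 h, or ≥ 1.5× the 7-day rolling-minimum baseline) and a
*reverted-AKI* flag (creatinine falling below 66 % of its 7-day maximum —
transient, not chronic, injury).

**Predictor profiles.** Three nested feature sets per patient:
`admissionHIB` (age, sex, admission eGFR), `historyHIB` (+ mean eGFR over
previous stays since a configurable history start), and the full
15-variable retrospective `historyCKD` profile (index-stay summaries,
AKI flags, history ratios, below-60 index classifier).

**Classifiers.** Rule-based (index-stay eGFR < 60, ICD-10 N18 prefixes,
discharge-summary flag) and trainable: a logistic Model/Results pair
(`CkdLogit` → `CkdLogitResults` with coefficients, standard errors,
`summary()`, JSON serialization) with decision cutoffs calibrated by the
Youden index on training data, and a random-forest contract on the
`historyCKD` profile that acts as a **silver-standard labeler** for large
cohorts where manual chart review (the gold standard) is infeasible.

**Evaluation.** Sensitivity/specificity/PPV/NPV/F1/accuracy with Wilson
confidence intervals, ROC (trapezoid AUROC + DeLong CI), precision-recall
(step-wise AUPRC + stratified bootstrap CI), Cohen's kappa, and a
reconstruction bridge turning printed sensitivity/specificity plus class
sizes back into integer confusion matrices to audit published metric
grids.

## Worked example

```python
from ckdphen import ExperimentConfig, run_full_study

cfg = ExperimentConfig()            # two-cohort study design
cfg.development.n_patients = 400    # high-prevalence training cohort (48 %)
cfg.validation.n_patients = 500     # low-prevalence validation cohort (12 %)
cfg.evaluation.bootstrap_reps = 200
report = run_full_study(cfg, "demo_run")
```

Printing the headline numbers of that run:

```
development test F1: {'admissionHIB': 0.968, 'historyHIB': 1.0}
validation gold-standard F1: {'admissionHIB': 0.927, 'historyHIB': 0.934}
validation silver-standard F1: {'admissionHIB': 0.943, 'historyHIB': 0.951}
AUROC (gold): {'admissionHIB': 0.994, 'historyHIB': 0.998}
gold vs silver agreement: {'n_overlap': 496, 'accuracy': 0.995968, 'kappa': 0.980763}
silver prevalence: 0.118952  age-CKD r: 0.28
```

Reading this: both admission-time classifiers, trained on the
high-prevalence development cohort with cutoffs chosen on the training
split only, transfer to an independent low-prevalence cohort (F1 ≈ 0.93
against ground truth). Labeling that cohort with the `historyCKD` forest
instead of ground truth (the silver standard) shifts F1 by under 0.02 and
agrees with truth at κ ≈ 0.98 — on synthetic data the silver-standard
shortcut is nearly free. `demo_run/` holds the full `report.json`, model
manifests, ROC/PR curve CSVs and a structured stage log.

The same study is available from the shell:

```bash
ckdphen report --config configs/demo.yaml --out demo_run --seed 7
```

with further subcommands `simulate`, `build-cohort`, `features`, `train`,
`predict`, `silver-standard`, and `evaluate` for running stages
individually on NDJSON/CSV record bundles.

## Layout

| module | contents |
|---|---|
| `ckdphen.egfr` | CKD-EPI 2009 equation and closed-form inverse |
| `ckdphen.synthetic` | synthetic cohort generator, NDJSON/CSV serialization |
| `ckdphen.cohort` | flattening, stay linkage, inclusion/exclusion criteria |
| `ckdphen.features` | AKI detectors, stay summaries, the three profiles |
| `ckdphen.models` | rule classifiers, `CkdLogit`, Youden cutoffs, forest labeler |
| `ckdphen.metrics` | confusion metrics, CIs, ROC/PR, kappa, grid reconstruction |
| `ckdphen.pipeline` | two-cohort study orchestration, characterization, reports |
| `ckdphen.cli` | `ckdphen` command-line entry point |

Design notes, modeling assumptions and known limitations are in
[`docs/methods.md`](docs/methods.md).
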