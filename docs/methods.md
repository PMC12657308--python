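# Methods

## The phenotyping problem

Healthcare-integrated biobanking must decide, shortly after a patient is
admitted, whether their surplus routine samples belong in a disease-specific
cohort. For advanced chronic kidney disease the decision has to be made from
what a hospital information system knows at admission: age, sex, and the
first serum creatinine — optionally enriched with laboratory history from
earlier stays at the same institution. This package implements that decision
problem as a supervised classification task, together with the
validation machinery needed to trust it: rule-based baselines, a
retrospective full-information classifier that can stamp out large
"silver-standard" validation cohorts, and agreement analysis between silver
labels and ground truth.

"Advanced CKD" is operationalized throughout as eGFR below
60 mL/min/1.73 m², computed with the 2009 CKD-EPI creatinine equation
without the race factor (current European laboratory-medicine practice).
No staging beyond the 60 threshold, no cystatin-C or 2021 equation
variants, and no urine-output criteria are implemented.

## Renal feature definitions

- **eGFR at admission** — CKD-EPI applied to the earliest non-missing
  creatinine of the index stay, with no time cap; ties in timestamps break
  by stable input order. Creatinine is accepted in mg/dL; µmol/L inputs
  are divided by 88.4 at ingestion.
- **KDIGO AKI (creatinine criteria)** — true iff some observation rises
  ≥ 0.3 mg/dL above an earlier value within 48 h, or reaches ≥ 1.5× its
  baseline within 7 days. The baseline is the *minimum value in the 7 days
  preceding the candidate elevation* (rolling-minimum convention — one of
  several operationalizations in use; chosen because it needs no
  out-of-stay data).
- **Reverted AKI** — true iff some value falls below 66 % of the maximum
  over the preceding 7 days. A pure ratio rule: invariant to rescaling the
  series, unlike the absolute-rise arm of the KDIGO flag.
- **History summaries** — mean eGFR over all pre-index measurements since
  the history start (default 2011-01-01), plus three ratios: stays with
  measurements / all previous stays; measurements / stays with
  measurements; below-60 measurements / stays with measurements.
  **Zero-denominator convention:** all ratios are 0 when undefined, and
  the history mean falls back to the admission eGFR with an explicit
  `history_missing` indicator. The fallback keeps admission information
  dominant for patients never seen before instead of dropping them.
- Thresholds are strict (`< 60`, `< 0.66·max`), values are carried at full
  precision, and nothing is rounded before thresholding.

The three predictor profiles are nested: `admissionHIB` (age, sex,
admission eGFR — 3 features), `historyHIB` (+ history mean and its missing
indicator — 5), `historyCKD` (the full 15-variable retrospective set,
computable only at discharge). The missing-history indicator is part of
`historyHIB` only; in `historyCKD` absent history is already encoded by
the ratios being 0.

## Classifiers

The admission-time classifiers are unpenalized maximum-likelihood logistic
regressions (2–5 predictors; with so few variables logistic regression is
robust, auditable, and easy to embed in a hospital information system).
Quasi-separation — common when the synthetic classes are cleanly separated
in eGFR — is detected via non-convergence, exploding coefficients or
non-finite standard errors, and triggers an L2-regularized fallback that
is flagged on the results object; its standard errors are reported as NaN
rather than pretended valid. Zero-variance columns are dropped with a
warning.

Decision cutoffs are calibrated by maximizing the Youden index
(sensitivity + specificity − 1) on *training* scores only. Candidate
thresholds are the midpoints between consecutive distinct scores plus the
two extremes; ties resolve to the lowest threshold, and a score exactly at
the cutoff classifies positive. The cutoffs published for the original
admission-time classifiers (0.478 admission-only, 0.586 history-aware) are
shipped as annotated constants for workflow parity, but every executable
model here is refit and recalibrated — the original coefficients were
never published and their training data are restricted.

The silver-standard labeler is a random forest on the `historyCKD`
profile (default 300 trees, fixed seed, scikit-learn implementation).
Forest hyperparameters are deliberately left near library defaults; on
the synthetic task the profile is so informative that tuning is moot.

Rule-based baselines: index-stay eGFR rule (default `max_lt`: *all*
index-stay values below 60, equivalent to max < 60; `any_lt` also
available since published wordings are ambiguous), ICD-10 prefix rule
(default code set N18.3/N18.4/N18.5/N18.9 targeting advanced CKD —
configurable, as no canonical set exists), and a pass-through of the
binary discharge-summary CKD mention (missing flags are negative, logged).

## Evaluation

All six confusion-matrix metrics carry Wilson score intervals
(Clopper–Pearson optional); each metric is treated as a binomial
proportion on its own numerator/denominator, F1 via its 2·TP /
(2·TP + FP + FN) representation. Zero-denominator metrics are flagged
undefined, never coerced to 0 — this protects degenerate all-negative
cohorts. AUROC is the trapezoid area (provably the Mann–Whitney
probability of correct ranking, ties counted ½) with a DeLong interval;
AUPRC is the step-wise average precision — linear PR interpolation is
biased and is not used — with a stratified bootstrap interval (default
2000 draws, seeded). Rounding to 3 decimals happens only when rendering
reports.

`reconstruct_matrix_from_rates` inverts printed sensitivity/specificity
and class sizes into an integer confusion matrix (rounding TP and TN,
subtracting for the rest). Recomputing the metric set from the
reconstruction audits a published grid cell by cell; the shipped tests do
this for a three-classifier grid on a 29/133 review cohort and reproduce
every printed value to 3 decimals.

## The synthetic cohort generator

The generator emulates the population structure these phenotyping
studies describe, with every quantity controllable and ground truth known:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 1000 | cohort size |
| `ckd_prevalence` | 0.12 | validation-style prevalence (development cohorts use 0.48) |
| `age_mean` / `age_sd` | 60 / 14 years | adult inpatient age profile (clipped ≥ 18) |
| `age_ckd_effect` | 0.10 /year | log-odds of CKD per year of age |
| `target_egfr_ckd_range` | 15–50 | baseline eGFR of CKD patients (below 60 by construction) |
| `target_egfr_nonckd_range` | 65–110 | baseline eGFR of non-CKD patients |
| `stays_per_patient_rate` | 2.0 | Poisson mean of previous stays over a 7-year history |
| `labs_per_stay_rate` | 4.0 | mean creatinine count per stay (≥ 1 always) |
| `aki_rate_ckd` / `aki_rate_nonckd` | 0.30 / 0.08 | per-stay transient-AKI probability |
| `aki_peak_multiplier` | 2.5 | creatinine fold-rise at the AKI peak (2 d rise, 3 d recovery) |
| `creatinine_noise_cv` | 0.12 | multiplicative lognormal measurement/biological noise |
| `icd_sensitivity` / `icd_specificity` | 0.931 / 0.872 | administrative CKD coding quality |
| `summary_sensitivity` / `summary_specificity` | 0.862 / 0.684 | discharge-summary mention quality |

Mechanics and the reasoning behind them:

- **Creatinine from inverted CKD-EPI.** Each patient gets a baseline eGFR
  drawn uniformly from their class range; the baseline creatinine is the
  closed-form CKD-EPI inverse at that target. This guarantees controllable
  class separation in eGFR space and makes noiseless configurations exact
  oracles (every derived eGFR equals the target).
- **AKI as a piecewise-linear multiplier** (rise to peak, linear
  recovery), so KDIGO-positive and reverted-AKI-positive patterns are
  produced deterministically when sampling is dense.
- **Lognormal noise** (mean-corrected, CV-parameterized) keeps values
  positive — multiplicative error is the physiological regime for
  creatinine.
- **Age→CKD link.** CKD status is Bernoulli with logit
  `b0 + effect·(age − age_mean)`; `b0` is solved numerically per cohort so
  empirical prevalence hits the target regardless of the effect. The
  default effect 0.10/year was calibrated once against the
  point-biserial age–CKD correlations reported for real validation
  cohorts (r ≈ 0.37–0.43 at ~10–18 % prevalence): integrating the link
  over the age distribution gives r = 0.367 at 12 % prevalence. The
  correlation is prevalence-dependent (≈ 0.5 at 48 %), which is why the
  test asserts the band at validation prevalence.
- **Imperfect coding.** ICD-10 CKD codes and discharge-summary flags are
  emitted per patient with the configured sensitivity/specificity,
  independent across patients given truth; defaults mirror the error
  rates observed for these sources in routine data. Comorbidity codes
  (cardiovascular, diabetes, liver, malignancy) are emitted with
  CKD-dependent rates so cohort characterization tables have realistic
  content.
- **Determinism.** Every patient owns a random stream seeded from
  `(seed, patient_index)`; identical configurations produce byte-identical
  NDJSON, independent of generation order.
- A configurable fraction of single-stay patients is routed through the
  emergency department, and stay lengths are uniform 3–14 days, so the
  emergency-discharge and minimum-stay exclusion rules are exercised only
  when a configuration makes them bite.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: admission eGFR is conditionally independent of
everything else given the baseline and AKI state (no comorbidity→lab
coupling, no medication effects, no assay drift across years); CKD is a
static trait rather than a progressing one; coding errors are independent
across patients and sources; there is no free text, no urine output, no
inter-hospital fragmentation. Classifier performance on this simulator is
an upper bound, not a forecast: the useful results are the *relative* and
*structural* ones (history helps when admission values are noisy; silver
standards track truth when the labeler is strong), not the absolute F1
levels.

## Cohort construction conventions

Stays are half-open intervals `[admission, discharge)`; the minimum-stay
rule is `discharge − admission ≥ 72 h`; "adult" is strictly `age > 18` at
index admission (fractional years from birth date). The index stay is the
first stay admitted inside the evaluation window (a longest-stay policy is
available, since multiple in-window stays can reasonably be resolved
either way); history stays are those discharged before the index admission
and admitted on/after the history start. Exclusion rules run in a fixed
order — age → minimum stay → emergency discharge → missing eGFR — and the
log records exactly one (first-failing) rule per excluded patient, so
screening-flow counts always partition the cohort. The gold profile
applies all four rules; the silver profile only age and missing eGFR.
Consent is modeled as an upstream filter (the generator only emits
consented patients); consent infrastructure itself is out of scope.

## Study designs shipped with the package

Problem sizes were chosen so the full suite and the acceptance script
each complete in minutes on a single core while keeping Monte-Carlo
bounds meaningful.

- **Two-cohort study** (`run_full_study`): development cohort at 48 %
  prevalence (default n = 785) for fitting and cutoff calibration
  (80/20 split, unstratified by default — split size is
  `floor(0.8·n)`), validation cohort at 12 % (default n = 1075)
  evaluated against both truth ("gold") and forest-derived silver labels.
- **History-benefit experiment** (`history_benefit_trial`): development
  cohorts (n = 600) with measurement CV 0.35 and eGFR ranges 20–55 vs
  62–105. The single admission eGFR is then an unreliable classifier
  input while the history mean (≈ 8 pre-index measurements) averages the
  noise away; held-out F1 of the history-aware model exceeds the
  admission-only model in ≈ 95 % of seeds (observed means ≈ 0.93 vs
  ≈ 0.86), reproducing the qualitative ordering reported for real
  cohorts without claiming their exact values.
- **Silver-fidelity experiment** (`silver_fidelity_trial`): per seed, a
  forest labeler trained on a development cohort (n = 600) labels an
  independent validation cohort (n = 600, 12 %); with labeler held-out
  F1 ≥ 0.9 the median absolute gap between silver-referenced and
  truth-referenced F1 of the admission-time classifiers stays below 0.01
  and gold-vs-silver kappa above 0.95 at the default noise level.

## Known limitations

- The original studies' fitted coefficients, forest internals, and
  patient-level data are restricted; their absolute headline metrics are
  therefore not reproduction targets anywhere in this package. What is
  reproduced exactly is their published rule-based metric grid (an
  arithmetic consequence of printed rates and class sizes) and their
  qualitative findings under simulation.
- Published wording leaves several operational details open; this package
  fixes them explicitly (KDIGO baseline convention, eGFR-rule
  aggregation, first-in-window index policy, within-index-stay admission
  observation selection, history-mean-in-eGFR rather than creatinine) and
  keeps each behind a documented switch where both readings are
  defensible.
- Confidence-interval methods for the published forest plots were never
  named; Wilson/DeLong/bootstrap are standard, reproducible choices, but
  interval *widths* are not comparable to the published figures.
- Cohort matching by comorbidity profile (used to assemble one of the
  original review cohorts) is not implemented; no algorithmic description
  exists.
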