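# Demo experiment: small two-cohort CKD phenotyping study.
# Development cohort (high prevalence) trains the classifiers; the
# validation cohort (low prevalence) is labeled by the historyCKD forest
# to form the silver standard.
development:
  n_patients: 300
  ckd_prevalence: 0.48
  seed: 101
validation:
  n_patients: 400
  ckd_prevalence: 0.12
  seed: 202
cohort:
  profile: gold
  window: ["2018-01-01", "2020-04-30"]
  history_start: "2011-01-01"
model:
  profiles: [admissionHIB, historyHIB]
  split_fraction: 0.8
  seed: 7
  forest_trees: 150
evaluation:
  ci_method: wilson
  bootstrap_reps: 200
output_dir: demo_run
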