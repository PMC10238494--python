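# Demo pipeline configuration: small enough to run in about a second,
# large enough to populate every stage of the candidate funnel.
seed: 7
n_proteins: 120
n_cohort_peptides: 150
n_differential: 15
planted_fc: 1.5
cv_biological: 0.2
cv_technical: 0.1
discovery:
  fc_threshold: 1.2
  alpha: 0.05
screening:
  snr_threshold: 3.0
  snr_high: 10.0
  rt_tolerance_min: 0.2
  ratio_threshold: 0.95
cohorts:
  discovery_cases: 50
  discovery_controls: 50
  validation_cases: 96
  validation_controls: 95
evaluation:
  train_fraction: 0.7
  random_states: [1, 2, 3, 4, 5]
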