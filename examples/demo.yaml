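# Demo pipeline configuration: small synthetic cohort, all stages.
seed: 20230419
output_dir: out
synthetic:
  n_lean: 20
  n_overweight: 20
  n_obese: 20
  n_paired: 12
stages:
  qpcr: true
  metrics: true
  stats: true
  correlations: true
  anni: true
anni:
  hidden_units: 3
  mc_resamples: 10
log_level: INFO
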