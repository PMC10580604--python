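# Example configuration for `histoarea-surv run --config examples/run.yaml`
output_dir: scratch/yaml_run
cohort:
  n_patients: 40
  map_rows: 40
  map_cols: 40
  hazard_betas: [1.5, 0, 0, 0, 0]
  hazard_texture_scale: 25.0
  censor_rate: 0.3
  seed: 5
deep:
  epochs: 8
model_names: [lasso_cox, ridge_cox, en_cox, ssvm, rsf, gbrt]
k_folds: 5
cutoff_permutations: 200
seed: 9
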