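# Example run config for `neuroprog run-study --config run.yaml`.
# Omitted keys keep their defaults (full desk-scale study: n=332, 32^3 grids,
# 10 folds, B=2000, CNN 12 epochs).
generator:
  n_subjects: 332
  frac_early_ad: 0.328
  grid_shape: [32, 32, 32]
  seed: 0
models: [clinical, hippocampus, freesurfer, deep]
tasks: [progression, slope]
k_folds: 10
split_seed: 101
fold_seed: 202
eval_seed: 303
deep_epochs: 12
occlusion_block: 4
occlusion_per_class: 5
out_dir: study_out
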