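# Example configuration for `hippoaxis run --config examples/run.yaml`.
# A reduced synthetic cohort so the full pipeline finishes in ~1 minute;
# remove the cohort block to run the full 16+68 study design.
cohort:
  n_sham: 8
  n_tbi: 14
  voxel_dims: [0.3, 0.3, 0.5]
  store_truth: false
spacing: 1.0
axis_mode: "true"      # "skeleton" re-estimates each animal's axis from its mask
model_positions: [3.0, 9.0]
inner: kfold
n_inner: 5
n_lambda: 30
lambda_min_ratio: 0.01
n_boot: 1000
seed: 7
outdir: scratch/run_demo
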