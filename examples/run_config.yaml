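# Full-pipeline run on the default synthetic scene.
# For real rasters, replace `scene` with `ndvi_path` + `climate_paths`
# (multipage TIFF stacks written by grasstrend.write_stack) and optionally
# `mask_path` / `mask_buffer` for road/river exclusion.
output_dir: scratch/demo_run
seed: 7
alpha: 0.05
window: 3
slope_mode: ols
rf_trees: 500
rf_max_rows: 3000
hot_permutations: 199
scene:
  n_rows: 40
  n_cols: 40
  n_years: 20
  seed: 7
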