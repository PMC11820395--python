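# Full pipeline run from one config:
#   sebumetrics run --config examples/06_full_pipeline.yaml
# Simulates the default cohort, builds and normalizes the feature matrix,
# then runs one classification and one PCA analysis. Outputs land in a fresh
# runs/run-NNN directory with a manifest of SHA-256 digests.
seed: 0
out_dir: runs
simulate:
  kind: cohort
  n_donors: 30
  n_lipid_peaks: 500
binning:
  mz_min: 250.0
  mz_max: 1300.0
  bin_width: 0.01
  rt_min: 0.8
  rt_max: 1.0
normalize:
  min_nonzero_fraction: 0.01
  epsilon: 1.0e-10
  n_keep: 400          # ~80% of the ~500 bins that survive the 1% filter
  batch_mode: column:batch
analyses:
  - type: classify
    task: region
    regions: [neck, forehead]
    n_keep: 400
  - type: pca
    group_by: region
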