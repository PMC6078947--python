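# Reduced-scale end-to-end run: `compdrop run --config examples/pipeline_config.yaml --out runs/demo`
# All keys are RunConfig fields; `simulate` holds SimulationConfig overrides.
seed: 5
simulate:
  n_subjects: 5
  n_channels: 12
  sampling_rate: 128.0
  epoch_span: [-100.0, 700.0]
  n_categories: 5
  n_exemplars_per_category: 4
  n_items_s2: 24
  signal_window: [80.0, 400.0]
  effect_size: 2.0
feature_type: voltage   # or: theta
step_ms: 40.0
localizer_n_perm: 25    # within-subject permutations per timepoint
cluster_n_perm: 150     # label permutations for the cluster null
n_boot: 10              # subject bootstrap draws
boot_n_perm: 100
behavior_n_perm: 50
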