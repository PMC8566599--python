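alpha: 0.05
clip_z: 6.0
covariates_path: null
excluded_classes:
- cerebellar
hub_top_fraction: 0.2
include_iq_analysis: true
min_size_voxels: 57
modularity_policy: preserve
modularity_restarts: 20
node_table: null
output_dir: demo_out
seed: 7
simulate: true
simulation:
  effect_delta: 0.3
  n_hubs: 3
timeseries_dir: null
weight_policy: absolute
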