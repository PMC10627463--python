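# Reduced-scale demonstration study: synthetic landscape, three dispersal
# distances, five boosted-tree replicates per network.
seed: 1
output_dir: demo_out
brt:
  learning_rate: 0.1
  tree_complexity: 3
  n_folds: 5
  step_size: 25
  max_trees: 100
  patience: 3
  n_replicates: 5
sweep:
  species: [focal]
  fixed_distances: [300.0, 4000.0, 10000.0]
  intensity_threshold: 2
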