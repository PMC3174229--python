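# Example configuration for `pathrise run --config pipeline.example.yaml`.
# Omit `synthetic` and set `input` to a CSV path to analyse your own flora.
input: synthetic
seed: 1
stages: [dynamics, contingency, range]
output_dir: pathrise_out
synthetic:
  n_species: 1007
tree_config:
  min_node_size: 25
  n_cv_repeats: 10
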