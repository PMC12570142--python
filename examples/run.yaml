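# End-to-end pipeline configuration for `smilesclm run examples/run.yaml`.
# Desk-scale settings: a 500-molecule synthetic corpus, 30 training epochs.
# Unknown keys anywhere in this file are rejected with an error naming them.

seed: 1
workdir: run-out

fixture:                 # omit this block and set `input: path.smi` to use your own corpus
  n_molecules: 500
  heteroatom_set: [C]
  ring_fraction: 0.0
  max_heavy_atoms: 16

curation:
  length_trim: [0.05, 0.05]

training:
  batch_size: 8
  warmup_steps: 2000
  max_epochs: 30
  early_stop_patience: 30

generation:
  n_samples: 1000
  temperature: 1.0

split:
  holdout_fraction: 0.2
  threshold: 0.6
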