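dataset: examples/demo.csv
dataset_id: demo-population
schema:
  fitness: fitness
  identifier: id
  standard_prefix: trait_
  volatile_prefix: vol_
model:
  rank: 1
  n_chains: 2
  n_warmup: 1000
  n_samples: 1000
  seed: 1
fit_multiple_regression: true
cv:
  n_folds: 5
  cv_seed: 1
out: examples/demo_fit
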