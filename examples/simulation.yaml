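# One synthetic population-year: 150 plants, 3 morphological traits,
# 12 correlated volatile emission rates, a true scent-axis gradient of 0.25
# (variance-scaled) and Gaussian noise on relative fitness.
n: 150
n_standard: 3
n_volatiles: 12
true_axis_gradient: 0.25
residual_sd: 0.3
seed: 42
dataset_id: demo-population
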