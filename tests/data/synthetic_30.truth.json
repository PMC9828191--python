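{
 "true_weights": [
  0.16769553253574826,
  0.3986921140467846,
  0.1603453593436953,
  -0.6323600759225024,
  0.43932603887058064,
  0.2166042988707274,
  -0.26055780564654846,
  0.28198891091379247
 ],
 "true_axis_gradient": 0.3,
 "realized_axis_gradient": 0.2848168028967639,
 "realized_standard_gradients": [
  0.0,
  0.0,
  0.0
 ],
 "true_standard_gradients": [
  0.0,
  0.0,
  0.0
 ],
 "residual_sd": 0.3,
 "fitness_model": "gaussian",
 "seed": 1,
 "n": 30,
 "n_standard": 3,
 "n_volatiles": 8
}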