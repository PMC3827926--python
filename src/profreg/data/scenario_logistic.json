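{
  "version": 1,
  "description": "Benchmark scenario: ten Bernoulli(0.5) binary covariates, outcome from a logistic model with main effects and two pairwise interactions. Coefficients are package surrogates.",
  "intercept": -1.0,
  "main_effects": [0.7, -0.7, 0.5, 0.5, -0.5, 0.3, 0.0, 0.0, 0.0, 0.0],
  "interactions": [[0, 1, 1.0], [2, 3, -1.0]]
}
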