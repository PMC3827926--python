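{
  "version": 1,
  "description": "Benchmark scenario: three contrasting covariate clusters over ten binary covariates with cluster-specific disease risks. Parameters are package surrogates.",
  "weights": [0.4, 0.3, 0.3],
  "theta": [-1.5, 0.0, 1.5],
  "modal_patterns": [
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
    [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  ],
  "modal_probability": 0.9
}
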