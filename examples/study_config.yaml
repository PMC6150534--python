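# Scaled-down end-to-end study configuration for `netcog run`.
# Omitted keys fall back to the full-scale defaults in netcog.pipeline.
seed: 1
simulate: default          # or a path to a simulation-config YAML
measures: [thickness, area]
abilities: [executive_function, episodic_memory]
networks: [1, 2, 3, 4, 5, 6, 7, whole]
cv:
  k: 5
  iterations: 10
  alphas: [0.05, 0.01, 0.001, 0.0005, 0.0001]
bootstrap:
  B: 200
vertexwise:
  B: 200
  n_perm: 500
  thresholds: [1.96, 2.58, 3.3, 3.9]
  sign: positive
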