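# Homogeneous reciprocal correlations eta = 1 push a sub-threshold network
# (J_E = 1.9) into bistability via the covariance feedback term.
experiment: dynamics
population: {N_E: 1200, N_I: 300}
stats:
  flavor: gaussian
  J_E: 1.9
  J_I: 0.6
  g: [[0.8, 0.4], [0.16, 0.64]]
  eta: [[1.0, 1.0], [1.0, 1.0]]
seeds: [0, 1, 2]
theta: 1.5
dt: 0.05
T: 200.0
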