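# Cell-type-dependent reciprocal correlations eta_EE = eta_EI = -eta_II,
# homogeneous variance g = 0.3; generates complex-conjugate outliers.
experiment: spectrum
population: {N_E: 1200, N_I: 300}
stats:
  flavor: gaussian
  J_E: 2.0
  J_I: 1.3
  g: [[0.3, 0.3], [0.3, 0.3]]
  eta: [[0.8, 0.8], [0.8, -0.8]]
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29]
theta: 1.5
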