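# Dense Gaussian network with homogeneous reciprocal correlations eta = 1,
# homogeneous variance g = 0.3, excitation-dominated means.
experiment: spectrum
population: {N_E: 1200, N_I: 300}
stats:
  flavor: gaussian
  J_E: 2.0
  J_I: 1.2
  g: [[0.3, 0.3], [0.3, 0.3]]
  eta: [[1.0, 1.0], [1.0, 1.0]]
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29]
theta: 1.5
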