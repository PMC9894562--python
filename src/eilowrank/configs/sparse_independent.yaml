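# Sparse Bernoulli network, independent edges (rho = c), E/I weight ratio
# A_E/|A_I| = 0.33.
experiment: spectrum
population: {N_E: 800, N_I: 200}
stats:
  flavor: sparse
  c: 0.3
  A_E: 0.025
  A_I: -0.0757575757575758
  rho: [[0.3, 0.3], [0.3, 0.3]]
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29]
theta: 1.5
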