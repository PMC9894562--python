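# Sparse network with reciprocal motifs: rho_EE = rho_EI = 1, rho_II = 0
# gives eta_EE = 1.0, eta_EI = -1.0, eta_II = -0.43 at c = 0.3.
experiment: spectrum
population: {N_E: 800, N_I: 200}
stats:
  flavor: sparse
  c: 0.3
  A_E: 0.023
  A_I: -0.0766666666666667
  rho: [[1.0, 1.0], [1.0, 0.0]]
seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29]
theta: 1.5
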