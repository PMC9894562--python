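# Homogeneous negative (anti-symmetric) reciprocity suppresses bistability
# in an otherwise bistable excitation-dominated network (J_E = 2.2).
experiment: dynamics
population: {N_E: 1200, N_I: 300}
stats:
  flavor: gaussian
  J_E: 2.2
  J_I: 0.6
  g: [[0.8, 0.4], [0.16, 0.64]]
  eta: [[-1.0, -1.0], [-1.0, -1.0]]
seeds: [0, 1, 2]
theta: 1.5
dt: 0.05
T: 200.0
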