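# SEIR epidemic fractions with the infected compartment observed;
# alternative observable sets: [E, I], [I, R], [S, E, I, R].
model: seir
theta: [0.6, 0.2, 0.15]
observables: [I]
t_grid: {start: 0.0, stop: 100.0, num: 26}
noise_sigma: auto
seed: 0
eps_eig: 1.0e-6
lambda: 1.0
alpha: 0.05
design:
  initial_times: [4.0]
  grid: {start: 0.0, stop: 100.0, num: 201}
  m_max: 30
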