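# Michaelis-Menten mass-action kinetics; substrate and product observed
# (set observables to [P] for the product-only readout).
model: mm
theta: [1.0, 0.5, 0.3]
observables: [S, P]
t_grid: {start: 0.0, stop: 40.0, num: 25}
noise_sigma: auto
seed: 0
eps_eig: 1.0e-6
lambda: 1.0
alpha: 0.05
design:
  initial_times: [1.0]
  grid: {start: 0.0, stop: 40.0, num: 201}
  m_max: 30
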