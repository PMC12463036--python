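# Lotka-Volterra predator-prey, both populations observed at 25 times
# over one-and-a-bit oscillation periods; noise is 5% of each
# trajectory's range.
model: lv
theta: [0.55, 0.028, 0.024, 0.84]
observables: [prey, predator]
t_grid: {start: 0.0, stop: 20.0, num: 25}
noise_sigma: auto
seed: 0
eps_eig: 1.0e-6
lambda: 1.0
alpha: 0.05
design:
  initial_times: [0.0]
  grid: {start: 0.0, stop: 20.0, num: 201}
  m_max: 30
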