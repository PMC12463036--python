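# Cubic benchmark: data at the roots of the cubic basis term, so the
# third coefficient is invisible to the data by construction.
model: polynomial
theta: [1.0, 1.0, 1.0]
t_grid: [1.0, 2.0, 3.0]
noise_sigma: 0.0
seed: 0
eps_eig: 1.0e-4
lambda: 1.0
alpha: 0.05
design:
  initial_times: [1.0, 2.0, 3.0]
  grid: {start: 0.0, stop: 4.0, num: 17}
  m_max: 20
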