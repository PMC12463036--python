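# Saturating-ligand assay: nine concentrations on the saturating arm
# x in [2, 4] (>= 94% of Vmax at the reference parameters), emulating
# dose-response data collected far above the half-saturation point.
model: hill
theta: [2.0, 1.0, 4.0]
t_grid: {start: 2.0, stop: 4.0, num: 9}
noise_sigma: 0.0
seed: 0
eps_eig: 1.0e-4
lambda: 1.0
alpha: 0.05
design:
  initial_times: [0.25]
  grid: {start: 0.0, stop: 4.0, num: 201}
  m_max: 30
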