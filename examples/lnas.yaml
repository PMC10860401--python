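# Sugar-beet growth model with synthetic weather: pairwise and full-subset
# collinearity of the 8 parameters under daily observation of green leaf
# biomass and yield from day 25 to 150.
model:
  name: lnas
  constants: {k_B: 0.7, T_b: 0.0, tau_sen: 450.0, seed_mass: 0.3}
  weather: {n_days: 151, seed: 5}
protocol:
  times: {start: 25, stop: 150, step: 1}
  observed: [Qg, Qr]
  noise:
    Qg: {kind: absolute, value: 0.1}
    Qr: {kind: absolute, value: 0.1}
seed: 2
output_dir: lnas_out
analyses:
  simulate: {}
  dataset: {}
  collinearity:
    min_size: 2
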