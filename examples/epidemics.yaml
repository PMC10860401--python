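# Full identifiability work-up of the plant epidemics model: collinearity
# table, risk indices with 95% profile-likelihood intervals, and recovery
# errors.  Run with:  pracident run --config examples/epidemics.yaml
model:
  name: epidemics
  initial_state: [0.0, 0.0, 0.0]
  removal_in_I: true
protocol:
  times: {start: 2, stop: 12, step: 2}
  observed: [I, N]
  noise:
    I: {kind: relative, value: 0.015}
    N: {kind: relative, value: 0.015}
seed: 1
output_dir: epidemics_out
analyses:
  simulate: {}
  dataset: {}
  collinearity:
    min_size: 2
    mean: {n_samples: 50}
  profile:
    parameters: [kappa, mu, d]
  risk:
    alpha: 0.95
  are:
    n_replicates: 100
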