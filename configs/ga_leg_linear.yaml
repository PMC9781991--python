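# Lower-limb database, GA selection, linear kernel.
database:
  n_subjects: 8
  movement_names: [AP, AT, LP, LT, PD, PI, RR]
  n_reps: 20
  n_channels: 4
  fs: 1000.0
  duration: 7.0
  rest_lead: 1.0
  seed: 0
  rest_name: RR
trim: {start_s: 1.0, end_s: 1.97}
prescreen: {enabled: true, alpha: 0.05}
selector:
  method: ga
  pop_size: 100
  mutation_rate: 0.02
  max_iterations: 100
  seed: 0
svm: {kernel: linear, C: 1.0, standardize: true}
cv: {k: 10, seed: 0}
split: {selection_fraction: 0.7, train_fraction: 0.7, seed: 0}
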