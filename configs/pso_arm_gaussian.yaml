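# Upper-limb database, binary-PSO selection, Gaussian kernel, long run.
database:
  n_subjects: 8
  movement_names: [FB, EB, FD, ED, RR]
  n_reps: 20
  n_channels: 4
  fs: 1500.0
  duration: 8.0
  rest_lead: 2.0
  seed: 0
  rest_name: RR
trim: {start_s: 2.0, end_s: 0.0}
prescreen: {enabled: false, alpha: 0.05}
selector:
  method: pso
  n_particles: 10
  w: 0.9
  c1: 2.0
  c2: 2.0
  max_iterations: 200
  seed: 0
svm: {kernel: gaussian, C: 1.0, gamma: scale, standardize: true}
cv: {k: 10, seed: 0}
split: {selection_fraction: 0.7, train_fraction: 0.25, seed: 0}
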