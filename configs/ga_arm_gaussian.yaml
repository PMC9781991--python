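# Upper-limb database, GA selection, Gaussian kernel.
# 8 subjects x 5 movements x 20 repetitions, 1.5 kHz, 8 s (2 s rest lead).
# No prescreen: all 26 predictors x 4 channels = 104 genes enter selection.
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
trim: {start_s: 2.0, end_s: 0.0}    # 6 s movement segment
prescreen: {enabled: false, alpha: 0.05}
selector:
  method: ga
  pop_size: 100
  mutation_rate: 0.02
  max_iterations: 100
  seed: 0
svm: {kernel: gaussian, C: 1.0, gamma: scale, standardize: true}
cv: {k: 10, seed: 0}
split: {selection_fraction: 0.7, train_fraction: 0.25, seed: 0}
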