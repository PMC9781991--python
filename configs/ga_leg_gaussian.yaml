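# Lower-limb database, GA selection, Gaussian kernel.
# 8 subjects x 7 movements x 20 repetitions, 1 kHz, 7 s (1 s rest lead).
# ANOVA prescreen reduces 26x4 = 104 columns to 80 genes before selection.
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
trim: {start_s: 1.0, end_s: 1.97}   # 4030-sample movement segment -> 64 windows
prescreen: {enabled: true, alpha: 0.05}
selector:
  method: ga
  pop_size: 100
  mutation_rate: 0.02
  max_iterations: 200
  seed: 0
svm: {kernel: gaussian, C: 1.0, gamma: scale, standardize: true}
cv: {k: 10, seed: 0}
split: {selection_fraction: 0.7, train_fraction: 0.7, seed: 0}
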