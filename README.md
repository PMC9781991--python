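# emgselect

Wrapper feature selection for surface-EMG movement classification.

Myoelectric pattern recognition classifies limb movements from multi-channel
surface electromyograms. A standard pipeline — band-pass filtering,
overlapping-window segmentation, time-domain (TD) feature extraction, and a
kernel classifier — produces a feature space of *channels × predictors* that
is highly redundant: with 26 TD predictors on 4 channels there are 104
candidate features, most of which add cost without adding discrimination.
`emgselect` implements *wrapper* feature selection over that space: a binary
genetic algorithm (GA) and a binary particle swarm optimizer (BPSO) search
over feature masks, scoring each mask by the 10-fold cross-validated mean
error of a one-vs-all soft-margin SVM trained on the masked features.

For maintainers of myoelectric-control experiments the package provides, as
composable library modules and a CLI:

- **`synth`** — seeded synthetic EMG databases (subjects × movements ×
  repetitions) of band-limited amplitude-modulated noise, so every stage is
  testable without human-subject data;
- **`preprocess`** — causal 4th-order Butterworth band-pass (10–500 Hz) and
  overlapping windows (250 ms length / 190 ms overlap by default; window
  count `⌊(N−W)/S⌋+1`);
- **`features`** — the 26 classical TD predictors (MAV, RMS, WL, ZC, SSC,
  WAMP, MYOP, IEMG, SSI, LOG, kurtosis, skewness, sample entropy, Higuchi
  fractal dimension, …) assembled into labelled channel-major matrices;
- **`prescreen`** — per-feature one-way ANOVA across movement classes,
  dropping predictors whose class means are indistinguishable (α = 0.05);
- **`classify`** — one-vs-all SVM (linear or Gaussian kernel) with z-score
  standardization and seeded stratified k-fold cross-validation;
- **`ga` / `pso`** — the two selectors: a simple GA (roulette-wheel
  selection, two-point crossover, uniform mutation, elitism of 1) and a
  sigmoid-transfer BPSO (`v ← w·v + c1·r1·(pbest−X) + c2·r2·(gbest−X)`,
  bit = 1 iff `S(v) > r3`), both minimizing the same cached CV-error
  fitness;
- **`evaluate`** — per-class TP/TN/FP/FN with accuracy, sensitivity,
  specificity and the composite *efficiency* = (accuracy + sensitivity +
  specificity)/3, macro averages, and a leave-one-feature-out sensitivity
  analysis (Δ = Y2 − Y1, percentage change 100·Δ/Y1).

## Worked example

Select features on whole-signal TD features of a synthetic 4-subject,
7-movement database, then classify the overlapping windows with the
selected mask:

```python
from emgselect import (DatabaseSpec, GaConfig, SvmSpec, WindowSpec, bandpass,
                       extract_matrix, generate_database, run_ga, segment,
                       select_columns, train_ova)
from emgselect.evaluate import evaluate, macro_average
from emgselect.features import default_predictors
from emgselect.pipeline import grouped_split

spec = DatabaseSpec(n_subjects=4,
                    movement_names=("AP", "AT", "LP", "LT", "PD", "PI", "RR"),
                    n_reps=10, n_channels=4, fs=1000.0, duration=3.0,
                    rest_lead=0.5, seed=0)
db = [bandpass(r) for r in generate_database(spec)]
preds = default_predictors(["MAV", "RMS", "WL", "ZC", "SSC", "LOG", "IEMG", "STD"])
signals = extract_matrix(db, preds, list(spec.movement_names))
windows = extract_matrix([segment(r, WindowSpec(), trim_start_s=0.5) for r in db],
                         preds, list(spec.movement_names))
print(f"signal matrix {signals.shape}, window matrix {windows.shape}")

run = run_ga(signals, SvmSpec(),
             GaConfig(n_genes=signals.shape[1], pop_size=20, mutation_rate=0.02,
                      max_iterations=10, seed=0, cv_k=5, cv_seed=0))
print(f"GA best CV error {run.best_fitness:.4f} with {run.best_mask.sum()} of "
      f"{signals.shape[1]} features")

masked = select_columns(windows, run.best_mask)
train_rows, valid_rows = grouped_split(masked, 0.25, seed=1)
model = train_ova(masked.select_rows(train_rows), SvmSpec())
report = evaluate(model, masked.select_rows(valid_rows))
print({k: round(100 * v, 2) for k, v in macro_average(report).items()})
```

prints

```
signal matrix (280, 32), window matrix (10640, 32)
GA best CV error 0.1964 with 19 of 32 features
{'accuracy': 91.65, 'sensitivity': 70.76, 'specificity': 95.13, 'efficiency': 85.85}
```

The GA kept 19 of 32 channel×predictor columns at a cross-validated error
of 19.6% on whole signals; classifying held-out windows with that mask gives
the per-class report whose macro averages are shown (percent). Movements
sharing activation channels (AP/AT vs PD/PI here) confuse each other, which
depresses sensitivity — the same failure mode seen on real recordings when
distinct movements recruit overlapping muscle groups.

The same pipeline runs from the shell:

```sh
emgselect run --config configs/ga_leg_gaussian.yaml --out scratch/leg_run
```

with canonical configurations for the GA/PSO experiments under `configs/`,
and each stage (`synth`, `features`, `prescreen`, `select`, `train`,
`evaluate`, `sensitivity`, `report`) also available as a standalone
subcommand over saved CSV artifacts.

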