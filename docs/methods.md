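# Methods

## Problem and model

The package targets movement classification from multi-channel surface EMG.
A recording is a short trial (seconds) of one movement by one subject,
sampled at 1–1.5 kHz on 4 bipolar channels. Classification operates on
time-domain (TD) features of overlapping analysis windows; the package's
core contribution is *wrapper* feature selection over the channel×predictor
feature space, scored by the downstream classifier itself.

The classifier is a one-against-all soft-margin SVM: one binary machine per
movement class, each solving

    min ½‖ω‖² + C Σᵢ ζᵢ   s.t.  yᵢ(ω·φ(xᵢ) + b) ≥ 1 − ζᵢ,

with a linear or Gaussian (RBF) kernel; prediction takes the class with the
largest decision value, ties broken toward the lowest class index. The
selection fitness of a binary feature mask is the mean misclassification
fraction over k = 10 stratified cross-validation folds of this classifier
trained on the masked matrix. Both search strategies minimize exactly this
fitness on exactly the same folds, so their trajectories are comparable and
a mask's fitness is cacheable.

## Search strategies

**Genetic algorithm.** Simple generational GA over bit-strings (1 = keep
column): roulette-wheel parent selection, two-point crossover (applied with
probability 1 by default), uniform per-gene mutation, elitism of one.
Roulette selection needs non-negative weights that favour low error, so
fitness f is transformed to weight (max f − f) + ε with ε = 1e−6. The
all-zero mask is unclassifiable and receives fitness 1.0 without invoking
the SVM. Elitism makes the best-so-far error non-increasing, which the
tests assert.

**Binary PSO.** Velocities update as
v ← w·v + c1·r1·(pbest − X) + c2·r2·(gbest − X) with per-dimension uniform
r1, r2, clamped to ±6 (the sigmoid is within 0.25% of saturation there);
positions are redrawn per dimension as 1 iff S(v) = 1/(1+e^{−v}) exceeds a
fresh uniform r3. Positions initialize Bernoulli(0.5), velocities zero.
Defaults w = 0.9, c1 = c2 = 2, 10 particles.

Replacement scheme, crossover probability and BPSO initialization are
conventions of the respective literatures; they are exposed in the configs
rather than hard-coded.

## Preprocessing

Filtering is a causal single-pass Butterworth band-pass, 10–500 Hz, of
overall transfer-function order 4 (the low-pass prototype order is halved,
since a band-pass doubles it). At fs = 1 kHz the 500 Hz edge sits exactly
at Nyquist and is clipped to 0.99·fs/2 with a warning — the band edge is
then 495 Hz, which is immaterial for TD features. A forward-backward pass
would square the magnitude response and double the realized order, so it is
deliberately not used.

Windows are 250 ms with 190 ms overlap (step 60 ms); durations convert to
samples by round(ms·fs/1000), trailing samples that do not fill a window
are discarded, and the window count is ⌊(N−W)/S⌋+1. A configurable
start/end trim selects the movement-only portion before windowing. The
canonical lower-limb trim (start 1.0 s, end 1.97 s of a 7 s trial) leaves a
4030-sample segment and hence exactly 64 windows; for the 8 s upper-limb
layout the 2 s rest lead is trimmed and the count follows the formula (no
trim reproduces a round number there — the window count is config-driven,
never hard-coded).

## Time-domain predictors

All 26 predictors are documented with closed forms in `features.py`.
Thresholded counters (ZC, SSC at 0; WAMP, MYOP at 0.02 in unit-scaled
amplitudes) and estimator constants are per-predictor parameters. Two
predictors are estimators with genuinely open conventions and are
implemented as the most common choices: SE as sample entropy (m = 2,
r = 0.2·STD, degenerate counts capped to keep the value finite) and FC as
the Higuchi fractal dimension (k_max = 8). MAVSLP reduces the vector of
consecutive segment-MAV differences (3 equal segments) to its mean so that
every predictor occupies exactly one column per channel. AAV is the
per-sample mean of absolute first differences — distinct from AAC, which
normalizes by N−1. VAR follows the EMG convention Σx²/(N−1) (zero-mean
assumption); STD is the sample standard deviation about the mean.
Amplitude-scaling laws (linear for MAV/RMS/STD/IEMG/WL/AAC/DASDV/MAD,
invariance for ZC/SSC/K/SK/SE/FC) are property-tested.

Features are computed vectorised over all windows at once (a few array
passes per predictor), which keeps the full-scale windowed matrix —
71,680 rows × 80 columns — under a minute on one core. Whether features
should be computed on normalized or raw amplitudes is not settled in the
field; the package computes them on raw (filtered) amplitudes and leaves
normalization to the classifier's z-scoring.

## ANOVA prescreen

Each (channel, predictor) column gets a one-way ANOVA across movement
classes. Elimination is at whole-predictor granularity — the benchmark
removed 6 predictors = 24 columns across 4 channels — but the per-channel
aggregation rule is not recoverable from the source material, so the
package eliminates a predictor when its *median* p across channels exceeds
α = 0.05. The prescreen is optional per database (the benchmark applied it
to the lower-limb data only). Under permuted labels p is uniform, so a
null column is retained with probability ≈ α; the tests check that rate.

## Classifier settings

C = 1 and the `scale` heuristic γ = 1/(n_features·Var(X)) are the widely
used defaults; the benchmark reports neither. Features are z-scored with
training-fold statistics (TD features span orders of magnitude — SSI vs
ZC — and kernel machines are scale-sensitive). Folding is stratified with
an explicit seed; every stochastic entry point in the package (generator,
CV, GA, PSO, splits) takes its own seed and fixed seeds reproduce results
bit-for-bit, including byte-identical pipeline artifacts.

## Synthetic databases

The generator emulates the *structure* of the benchmark's two private
databases (Table layout: 8 subjects × 7 movements × 20 repetitions at
1 kHz/7 s, and 8 × 5 × 20 at 1.5 kHz/8 s): per trial, Gaussian white noise
band-passed to 10–500 Hz and multiplied by a trapezoidal activation
envelope (0.25 s ramps) that is baseline (5% of unit amplitude) during the
initial rest lead and for the rest class throughout. Each non-rest class
drives a primary channel at 1.5× and a secondary at 0.7× with 0.2×
elsewhere, giving every movement a distinct cross-channel amplitude
signature; a per-subject log-normal gain (σ = 0.1) makes cross-subject
pooling non-trivial. Amplitudes are unit-scaled because the source material
never characterizes physical units or dynamic range.

What this emulates well: amplitude contrasts that TD features respond to,
class overlap when movements share channels, subject-level gain variation,
realistic matrix geometry. What it does not: motor-unit physiology,
electrode placement and crosstalk, non-stationarity within a contraction,
measurement noise spectra. Passing tests therefore demonstrate the
*machinery* (segmentation arithmetic, feature formulas, selection dynamics,
metric identities) — not expected accuracy on real muscle signals, and the
headline accuracies of the original human-subject experiments are not
reproducible from synthetic data.

## Evaluation

Per class, one-vs-rest counts give accuracy, sensitivity and specificity,
and the composite efficiency = (accuracy + sensitivity + specificity)/3.
Macro averages are unweighted means over classes; undefined metrics (empty
denominators) propagate as NaN, are excluded from macro averages and
warned about — never silently zeroed. Percentages are reported to 2
decimals, matching the bundled reference tables. Those tables reproduce a
published benchmark's printed per-class values; one of its quoted summary
figures (the PSO training-stage accuracy mean) is inconsistent with its own
table by nearly two points, which the test suite documents as an exclusion
rather than resolving.

The sensitivity analysis retrains the model per removed feature (the
reduced input dimension requires it; zeroing a column of a standardized
kernel machine is not equivalent) and reports Y2 − Y1 and
100·(Y2 − Y1)/Y1 against the all-selected reference accuracy Y1.

## Problem sizes in the test suite

The suite exercises full-scale geometry once (the 1,120-recording database
and its 71,680 × 80 windowed matrix, ≈ 40 s) and otherwise works on small
instances chosen to make the checked property sharp: 6-gene instances where
exhaustive subset search (63 masks) is the oracle for GA/PSO optimality;
Gaussian-blob matrices with known informative/noise columns for selection
enrichment and sensitivity ranking; 200-row label-shuffled data for the
chance-level CV property. Wrapper selection at the benchmark's full
configuration (100 chromosomes × 100+ generations × 10-fold SVM fits) is
supported through the configs but is a multi-hour computation by nature;
the shipped tests verify the algorithms, not that budget.
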