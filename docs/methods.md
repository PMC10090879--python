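# Methods

This note documents the models, conventions and calibration behind
`groomacc`, an accelerometer-to-behaviour pipeline for collar-mounted
tri-axial loggers, with a focus on detecting allo-grooming (the giver and
receiver roles separately) in a terrestrial primate.

## 1. Problem

A collar accelerometer samples surge (X, front–back), sway (Y, side–side)
and heave (Z, up–down) acceleration at 40 Hz in units of g. Six mutually
exclusive state behaviours are of interest: resting, giving grooming,
receiving grooming, foraging, walking and running. The pipeline:

1. reduces the raw trace to 16 per-second variables,
2. trains a random forest on labelled seconds,
3. applies it to continuous data to build activity budgets, and
4. compares collar-derived behaviour rates with simulated human focal
   observation.

Because video-labelled field data are not redistributable, the package
ships a synthetic generator whose statistical structure matches the
published field calibration study, so every stage is testable offline.

## 2. Feature extraction

Per sample:

- **static acceleration** per axis: centred moving average over a 2 s
  window (80 samples); the window at index *i* covers
  `[i - w//2, i + w - w//2)`. Samples whose window crosses a trace
  boundary or a missing span are undefined (NaN).
- **dynamic acceleration** = raw − static.
- **pitch** = atan2(stX, hypot(stY, stZ)) and **roll** = atan2(stY, stZ),
  in degrees; upright (gravity on +Z) gives pitch = roll = 0.
- **VeDBA** = Euclidean norm of the dynamic triple; **VeDBAs** is its 3 s
  centred moving average.
- **PDBA** per axis = |dynamic|.

Per whole-second epoch (40 samples, half-open `[t, t+1)` aligned to
integer seconds) the per-sample variables are averaged, and per axis the
dynamic signal is mean-detrended and Fourier-transformed at 1 Hz
resolution. The one-sided amplitude spectrum is normalised so a
bin-aligned sinusoid of amplitude *a* produces a peak of *a* (the Nyquist
bin is halved because it is not mirrored). **PSD1** is the largest
spectral magnitude; **PSD2** is the second-largest *local maximum*
(a bin positive and ≥ both neighbours), 0 if none exists. This makes 16
features: stX, stY, stZ, pitch, roll, VeDBA, VeDBAs, PDBAx/y/z and
PSD1/PSD2 per axis.

An epoch containing any undefined sample is marked invalid; invalid
epochs flow through prediction as "unclassified" and are excluded from
budget denominators. This is the mechanism behind non-classified seconds
in real deployments (sensor gaps and smoothing edges).

## 3. Classifier

- **Split**: epochs are divided 70/30 within every
  (individual × behaviour) cell, with largest-remainder rounding so the
  overall training size is exactly `round(0.7 N)` and every cell's
  achieved proportion is within 0.01 of the target.
- **Forest**: 500 trees, canonical random-forest defaults (bootstrap
  resampling, ⌊√16⌋ = 4 candidate features per split, unlimited depth).
  Tree construction is delegated to scikit-learn; the package computes
  its own per-tree hard votes so the final label is an explicit majority
  vote with ties broken by the fixed alphabetical class order.
- **Evaluation**: 6×6 confusion matrix (rows predicted, columns
  observed); precision = TP/(TP+FP) (diagonal over row total), recall =
  TP/(TP+FN) (diagonal over column total). Feature importance is mean
  decrease in Gini impurity. A stability curve reports validation error
  using only the first *k* trees; on calibrated data the error at 100
  trees is within 0.02 of the error at 500.

A published 6×6 validation confusion matrix ships as a package fixture
(`data/reference_confusion_matrix.csv`) for worked examples; one printed
cell in the source table was inconsistent with its own row and column
totals and has been reconstructed from those totals (3599 in the
receiving-grooming diagonal), which reproduces every printed
precision/recall percentage.

## 4. Synthetic generator

Behaviour sequences are semi-Markov: bout lengths are geometric
(memoryless, support ≥ 1 s) with behaviour-specific means derived from
published per-behaviour totals and event counts; between bouts the next
behaviour follows a zero-diagonal transition matrix whose rows are
proportional to configurable state weights (shipped default: published
event counts). The per-second chain implied by this construction has a
closed-form stationary distribution used as a test oracle.

Acceleration per sample = gravity + oscillation + noise:

- **gravity**: the behaviour's unit posture vector, rotated once per bout
  by a random-axis rotation with Gaussian angle (`posture_jitter_deg`);
  posture varies between, not within, bouts. Optional transition
  smearing cross-fades gravity over the first ≤ 2 s of a bout.
- **noise**: isotropic Gaussian, `dynamic_sd_g`.
- **oscillation**: `amplitude_g · sin(2π f t + φ)` on one axis with a
  per-bout phase, plus an optional second harmonic at 2f scaled by
  `harmonic_ratio`.

Giving grooming carries a 2.0 Hz surge (X) oscillation of amplitude
0.0208 g with an equal-amplitude second harmonic at 4 Hz, over a
broadband noise floor deliberately matched to receiving grooming
(0.0171 g). Two modelling choices matter here. First, grooming strokes
are periodic but strongly non-sinusoidal; a pure off-bin sinusoid smears
into a single local-maximum region of the 1 Hz-resolution spectrum,
leaving no genuine second peak, whereas the harmonic yields the
distinctive two-peak surge signature (PSD1X ≈ PSD2X ≈ 0.02 g) that makes
PSD2X the giving-grooming marker. Second, matching the noise floor to
the other stationary behaviours ensures the sway and heave axes carry no
information about giving, so the surge rhythm is its sole discriminator —
while the median VeDBAs stays inside the resting/receiving overlap band.

### Calibration

`dynamic_sd_g` per behaviour was found by an implementer-run
simulate-and-measure loop before defaults were frozen, anchoring the
extracted median VeDBAs to field-calibration levels: running 0.85 g,
walking 0.35 g, foraging 0.15 g, resting 0.031 g, giving grooming
0.033 g, receiving grooming 0.027 g. The frozen constants live in
`data/ethogram_default.yaml` and `synthetic.default_behaviour_configs()`.

### Focal protocol

Follows of 30 min are placed uniformly at random without overlap; scans
read the true label at each minute mark (31 records per non-extended
follow); grooming bouts are copied from the label stream with exact
times; a follow whose nominal window ends mid-grooming is extended to
the bout's end; follows under 3 min are discarded.

## 5. Budgets and comparison statistics

Budgets report seconds and proportions per behaviour per clock window
(24 h, 07:00–17:00, night = its complement); proportions are over
classified seconds only. Independent events are maximal runs of one
state behaviour, with non-state interruptions up to a configurable merge
gap absorbed. Day/night summaries report per-behaviour VeDBAs quartiles
plus an IQR-overlap coefficient (IQR intersection length / IQR union
length) — an artifact-defined metric, since "more overlap" has no
standard definition.

Focal rates: instantaneous (scan) rates pool an individual's follows;
continuous grooming rates divide bout seconds by observation seconds.
The two are reconciled into six rates summing to 1 by taking grooming
from the continuous estimates and rescaling the four non-grooming scan
rates into the remainder (a declared artifact convention). Methods are
compared per behaviour with Spearman rank correlation — exact
permutation p for tie-free n ≤ 9 (full n! enumeration; larger n falls
back to the t-approximation) — and a two-sided Wilcoxon signed-rank test
with the normal approximation, zeros dropped, reporting Z.

## 6. Limitations

- The generator is phenomenological: no limb biomechanics, no GPS, no
  inter-individual amplitude variation (exposed as config knobs, not
  estimated), and none of the ~30 brief event behaviours seen in the
  field.
- The 70/30 split is on seconds, not bouts, so temporally adjacent
  (autocorrelated) epochs can land on both sides of the split; this
  replicates the published design and inflates validation scores
  relative to a bout-level split.
- Geometric bout lengths are a one-parameter convenience; real bout
  distributions are heavier-tailed.
- Exact Spearman p-values are computed only for n ≤ 9 (enumeration cost);
  published analyses at n = 12 may use other conventions.
- The IQR-overlap coefficient and the focal-rate normalisation recipe
  are artifact conventions, isolated in single operations.
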