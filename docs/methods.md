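# Methods

This note documents the models, parameter choices and numerical conventions
behind `faciemg`, and what the synthetic cohort can and cannot show.

## Signal model of the synthetic cohort

Each trace is one tension–relaxation cycle of one channel: zero-mean
Gaussian noise band-limited to 20–450 Hz (fourth-order Butterworth, applied
forward–backward), amplitude-modulated by a trapezoidal envelope. The
contraction occupies a 1 s window centered in a 4 s trace, with linear ramps
of 10% of the tension duration on each flank; outside the window only
stationary baseline noise remains. Band-limited noise times a deterministic
envelope is the simplest process whose rectified-and-smoothed envelope
behaves like real surface EMG for the statistics this pipeline uses
(a high percentile of the smoothed rectified signal); it does not model
motor-unit recruitment, firing-rate dynamics or fatigue.

Amplitude structure, per side of a repetition:

- contralateral drive RMS = `burst_amplitude_uv` (default 100 µV, a typical
  strong facial sEMG contraction);
- ipsilateral drive RMS = `burst_amplitude_uv` × `grade_attenuation[hb]` ×
  session asymmetry gain;
- each side additionally receives an independent leaked drive of RMS
  `synkinesis_gain` × (opposite side's drive RMS), emulating cross-talk and
  synkinetic co-activation. Modelling the leak as an independent noise
  process rather than the identical waveform leaves all envelope-amplitude
  statistics unchanged and keeps trace generation purely local;
- stationary baseline noise of RMS `baseline_noise_uv` (default 2 µV).

`grade_attenuation` defaults to {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.3, 5: 0.15,
6: 0.0}. Grade 1 is pinned to 1.0 (a normal face is symmetric in
expectation) and the map must be monotone non-increasing; the intermediate
values are an arbitrary but monotone choice that makes neighbouring grades
separable yet overlapping under noise, and they are fully configurable.

Two noise scales control task difficulty:

- `repetition_cv` (default 0.15): lognormal repetition-to-repetition
  variation of the voluntary effort, shared by both sides of a repetition
  (the effort is one event recorded on six channels).
- `session_asymmetry_sd` (default 0.2, log-scale SD): a per-session
  multiplicative gain on the ipsilateral side shared by all of that visit's
  channels. This emulates natural facial asymmetry and electrode-placement
  differences — the very confounders that motivate using a within-subject
  asymmetry ratio in the first place — and, being correlated across all 21
  features, it is the term that keeps classification honestly imperfect:
  purely per-repetition noise would be averaged away by the classifiers.

`synkinesis_gain` defaults to 0.1 (10% amplitude cross-talk), compressing
lateralization indices toward zero at high grades, as synkinesis does
clinically.

Cohort structure: 59 sessions over 28 patients — 15 patients with two
sessions (pre- and post-operative), 8 with three (plus follow-up), 5 with
one. Grade slots (30/17/5/3/2 labeled HB 1–5, none HB 6, plus 2 sessions
emitted without a label whose truth grade is drawn from the labeled-grade
frequencies) are shuffled over sessions by the seeded RNG. The operated side
is drawn once per patient (P(left) = 0.75) and never conflicts across a
patient's sessions. The sampling rate defaults to 1000 Hz; it is not a
physiological claim, merely ample for envelope statistics, and is
configurable. All randomness flows from a single integer seed; identical
configuration and seed reproduce the cohort bit-for-bit.

## Envelope extraction

- Rectification: absolute value (idempotent; makes the chain invariant to a
  sign flip of the raw signal).
- Running average: centered window of `round(window_ms × fs / 1000)` samples
  (minimum 1, default 100 ms). Edges use truncated windows — the average of
  the samples that exist — so constants map to constants; no zero padding.
  For even window lengths the window extends one sample further to the left.
- Epoch selection: the automated path scans every valid start offset of a
  500 ms window over the *smoothed rectified* trace and takes the window
  with the largest mean, earliest start on ties. Selecting on the envelope
  rather than the raw trace is what "the window containing the maximum
  amplitudes" requires operationally; externally (manually) chosen epochs
  can be supplied per trace and are honored verbatim, with range
  validation.
- Amplitude: 95th percentile of the smoothed rectified samples inside the
  epoch, with linear interpolation between order statistics (the numpy
  default). The percentile estimator is fixed for reproducibility; any
  reasonable alternative changes amplitudes by well under the noise level.

## Features

LI is computed per repetition and then averaged per (muscle, pose), giving
21 features per measurement rather than 63 per-repetition features. The most
compact representation was chosen because the repetition mean is what the
protocol's three repetitions exist to stabilize; the aggregation lives in
one place (`build_features`) if a different choice is wanted. Conventions:

- LI(0, 0) := 0 — no activity carries no lateralization information;
  keeping it finite avoids propagating NaNs into the classifiers.
- Repetitions with only one side recorded are unpaired and dropped from the
  cell mean; a cell with 1–2 surviving repetitions is flagged
  `partial_repetitions`.
- A cell with no usable repetitions receives the mean LI of the same muscle
  over its other poses (`whole_movement` flag). Imputation is per muscle
  because LI scales differ across muscles; it never leaves the convex hull
  of that muscle's observed values. A muscle with no observed pose at all is
  an error — there is nothing defensible to impute from.
- Measurements without a clinical HB rating flow through feature building
  but are excluded from all supervised training and evaluation.

## Grading

Scenarios: (1) HB 1 vs HB 2–6; (2) HB 1–2 vs HB 3–6; (3) HB 1/2/3 with
grades 4–6 excluded. Classes are coded ordinally with 1 = best function.
A scenario class with zero members raises — the AUC would be undefined.

Classifiers are deliberately untuned: logistic regression (scikit-learn
defaults; the lbfgs iteration cap is raised to 1000 purely so the optimizer
converges — it changes no hyperparameter), RBF-SVM with γ = 1/n_features
and Platt-style probability calibration on the training fold, KNN with
k = 5 and normalized inverse-distance neighbour weights (an exact-distance
match takes the whole weight). The HB scale's ordinality is ignored in
scenario 3; plain multinomial classification is used.

Cross-validation: one fold per patient; all of a patient's measurements are
held out together, and per-fold standardization statistics (mean/SD) are
computed on the training fold only. Standardization is on by default —
SVM and KNN are scale-sensitive — and can be disabled. Degenerate folds are
handled explicitly: a training fold missing one of several classes trains
on the remaining classes with a warning; a training fold reduced to a
single class predicts that class with probability 1; k is capped at the
training-fold size. Predicted class = argmax of the accumulated
probabilities with ties broken toward the lower (better) grade — a
deterministic rule whose bias direction is at least visible in the
under-/over-estimation table rather than hidden in hash order.

Metrics: binary AUC is the rank-based (Mann–Whitney) statistic with average
ranks for ties; the one-vs-one multiclass AUC restricts the data to each
unordered class pair, averages the two directed AUCs, and means over pairs.
Empty pairs are skipped with a warning. The evaluation report emits both the
mean and the median AUC over classifiers per scenario, since either
aggregate is a defensible headline figure. Scenario-3 predictions are also
broken down into concordant / underestimated (predicted better than rated) /
overestimated percentages, which sum to 100.

The single `seed` drives cohort generation and the SVM calibration split,
making end-to-end runs byte-identical.

## What the synthetic results do and do not show

Passing tests on the synthetic cohort demonstrate that the pipeline is
implemented correctly (oracle-equivalent metrics, leak-free patient-grouped
folds, correct imputation) and that the intended qualitative structure is
recovered: AUC well above chance in all scenarios, the slight-vs-moderate
split (scenario 2) easiest, and moderate under-/over-estimation in
scenario 3. They do **not** validate clinical performance: the generator's
grade-to-asymmetry map is an assumption, real sEMG has non-Gaussian texture,
artifacts, and electrode variability the simulator omits, and real HB
ratings carry interobserver noise that the synthetic truth lacks. Absolute
AUC values on synthetic data therefore characterize the generator's
difficulty settings, not the clinical method.

## Problem sizes

The default cohort (59 sessions × 126 traces of 4 s at 1000 Hz) processes in
well under two minutes on one CPU; the test suite uses miniature cohorts
(500 Hz, 2 s traces, 6–12 sessions) for everything except the
parameter-recovery check, which runs the full default cohort once.
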