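# Methods

This note documents the models, numerical choices and limitations of
`ecghorizon` at the level a maintainer or reviewer needs to reason about
the results.

## Problem setting

A subject's state is one of three classes (low/medium/high stress, or
alert / sleep stage 1 / sleep stage 2).  The task is *extended-range
prediction*: from the most recent pair of ECG beats, predict the class at
each lead time k = 1…60 s.  The last observed R wave is the anchor for
"now"; the label for horizon k is the class of the interval containing
t_R + k.  Label intervals are half-open [start, end) in seconds, which
removes ambiguity exactly at class transitions.

## Beat segmentation

The detector is the classic energy-envelope chain: remove the DC offset,
bandpass 10–30 Hz, differentiate, square, integrate over a moving window,
threshold.  Choices the chain's name does not pin down:

- **Bandpass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), so the passband is flat and peaks are not displaced in
  time.  Requires fs > 60 Hz.
- **Derivative**: the five-point kernel (1/8)[−1, −2, 0, 2, 1] scaled by
  fs.
- **Integration window**: 150 ms (about the QRS-plus-slope support);
  **refractory period**: 200 ms (physiological upper bound on QRS rate);
  **adaptive threshold**: running signal/noise envelope estimates with
  threshold = noise + 0.25·(signal − noise), both levels updated with an
  8:1 exponential moving average, initialized from the first two seconds.
- Accepted envelope peaks are refined to the local maximum of the
  *bandpassed* signal within ±50 ms, then deduplicated under the
  refractory period.

A beat (R-to-R slice) is standardized to L = 100 samples: linear
resampling onto a 100 Hz grid — a typical 0.6–1.0 s beat occupies 60–100
samples — then right zero-padding (or tail truncation for slices longer
than 1 s).  The zero-pad tail length therefore encodes the instantaneous
heart rate, which is a deliberate property: rate is the dominant
class-dependent signal.  Each beat is z-scored (ε = 1e−8 guard) before
feature extraction so the conv/xcorr features are amplitude-invariant
across recordings.

## Features

For consecutive z-scored beats the feature vector is the full linear
convolution (199 terms) concatenated with the full cross-correlation at
lags −99…99 (199 terms), total 398.  The printed definition of the
convolution sum would give a length-L output, which contradicts the
stated 199×2 input dimensioning; the full (2L−1) convolution is the
definition consistent with 398 and is what is implemented.  The
cross-correlation's piecewise index bounds are likewise normalized to the
standard lag ordering −(L−1)…(L−1), stored left to right.  Beat pairs are
strictly consecutive with stride 1 (overlapping pairs), maximizing sample
count while preserving temporal order.  Pairs whose horizon times extend
past the labeled part of the record are dropped, not imputed.

## Recurrent classifiers

All cells are NumPy implementations of their update equations, with
analytic backpropagation-through-time (verified against central finite
differences in the test suite, tolerance 2e−5).

- **Elman RNN** with the power-sigmoid activation σ(x) = xᵅ for |x| ≥ 1
  and (1+e^−β)(1−e^−βx) / ((1−e^−β)(1+e^−βx)) for |x| < 1; the inner
  branch equals c·tanh(βx/2) with c = (1+e^−β)/(1−e^−β), so σ is odd,
  strictly increasing and continuous at ±1.  α is restricted to odd
  integers ≥ 3 (even α would break oddness and monotonicity) and β > 2.
  Defaults α = 3, β = 3; a grid search over α ∈ {3,5,7}, β ∈ {3,4,5} on
  validation overall accuracy is available
  (`grid_search_power_sigmoid`).
- **GRU** exactly as printed, including the update-gate polarity
  h = (1−u)⊙h_prev + u⊙h̃ and no gate biases.  The declared-but-unused
  output weight matrix of the formulation is not implemented.
- **LSTM** with the standard cell update C_t = f⊙C_{t−1} + i⊙C̃_t.  The
  printed update omits C_{t−1} (the forget gate would gate nothing and
  memory would be destroyed every step); this deviation is deliberate and
  the single substantive correction made.

**Readout and loss.** The final hidden state feeds a linear map into
n_horizons independent 3-way softmax heads; the loss is the mean
cross-entropy over heads.  Prediction ties break toward the lowest class
id for determinism.

**Sequences.** Each training sequence is a sliding window of W
consecutive beat-pair samples (default W = 8) ending at the labeled
sample; windows near a record's start are left-padded by repeating the
record's earliest sample, so every labeled sample is usable.

**Optimization.** Plain mini-batch gradient descent, learning rate 1e−3,
30 epochs, batch 32 by default, with global gradient-norm clipping at 1.0
— the clip also guards the power-sigmoid's polynomial branch.  Features
are standardized (per-dimension mean/sd from the training set, stored on
the model) before entering the cells; conv/xcorr features span two orders
of magnitude otherwise.  In the trained RNN the hidden pre-activations
are clipped to [−3, 3] so the recursion through xᵅ stays bounded; the
stand-alone `rnn_step` operation is exact apart from its output
activation seeing inputs clipped to [−1, 1] (bounded branch only), which
keeps y finite.  Training is deterministic given the seed; zero epochs
leaves the initialized parameters untouched.

## NSGA-III

Implemented in full: Das–Dennis reference directions (p = 6 divisions for
M = 4 gives C(9,3) = 84 points; population 92, the next multiple of four),
fast nondominated sorting, normalization by the ideal point and
extreme-point intercepts (achievement-scalarizing extreme points; fallback
to per-objective maxima when the hyperplane system is singular or yields
nonpositive intercepts), association by perpendicular distance, and the
niche-count selection rule: repeatedly take a minimum-count reference
(random among ties from the run's seeded generator), its closest
candidate if the niche is empty, a random associated candidate otherwise.
Variation is SBX (η = 30, probability 0.9) and polynomial mutation
(η = 20, rate 1/genome-length) — standard literature defaults, as the
operator parameters are otherwise unspecified.  Maximization is handled
by negation at the optimizer boundary.  An archive accumulates every
nondominated solution evaluated; per-generation logs report archive-wise
best objectives, which are monotone by construction.  A single-objective
run degenerates gracefully to one trivial reference ray.

## Ensemble merge

The genome is one weight triple per horizon over (RNN, GRU, LSTM) class
scores, normalized to the simplex per horizon (an all-zero row falls back
to uniform weights).  Base models are trained once per cross-validation
fold and their validation scores cached, so a genome evaluation is a
weighted argmax — this is what makes a population × generations search
affordable.  The four objectives are the fold-mean, pooled-over-horizons
overall accuracy and per-class recalls.  Cross-validation is stratified
on the horizon-1 label at the sample level (k = 10 by default); a
`group_by_record` switch uses grouped folds instead to prevent
within-record leakage — with overlapping windowed samples inside one
record, sample-level stratification is optimistic, and the flag is the
honest protocol for cross-subject claims.  The selected solution is the
archive member with maximal OA_all, ties broken by the maximal minimum
per-class accuracy.  Because the three one-hot genomes are seeded into
the initial population and the archive keeps every nondominated point,
the selection provably never scores below the best stand-alone model on
the selection folds.

The "boosting" baseline is a committee of B same-cell models trained with
different seeds, their scores averaged with validation-accuracy weights
(B = 1 reduces exactly to the stand-alone model).  Predicted classes 1
and 2 map to a boolean warning flag.

## Synthetic data generator

The generator defines the study conditions for all tests:

- **State dynamics**: a 3-state semi-Markov chain; exponential dwell times
  (a fixed-dwell switch exists for deterministic tests), zero-diagonal
  uniform transition matrix.  With a symmetric embedded chain, state
  occupancy is proportional to mean dwell, so the configured class mix —
  (0.425, 0.404, 0.170) for the stress profile, (0.580, 0.267, 0.153) for
  the drowsiness profile, scaled from the emulated corpora's per-class
  sample counts — is realized by scaling dwell means (overall mean 40 s).
- **Beats**: placed at 60/HR intervals with multiplicative lognormal
  jitter (cv 0.03); class mean heart rates 70/85/100 bpm (stress) and
  72/62/55 bpm (drowsiness) — physiologically oriented generator
  parameters, not measured facts.  Each beat is a derivative-of-Gaussian
  QRS (σ = 10 ms, positive lobe at the annotated R time) scaled by a
  class amplitude, plus small P and T Gaussian bumps, a constant DC
  offset and white noise (sd 0.05 default).
- **Pre-transition drift**: in the final `pre_transition_drift_s` seconds
  (default 10) of each state, HR and amplitude interpolate linearly
  toward the next state's values.  This is the mechanism that makes
  future labels partially predictable from current beats — exactly the
  structure the forecaster assumes — and it produces the characteristic
  accuracy decay with horizon.

What the generator does **not** emulate: real QRS morphology variation,
arrhythmias, movement artifacts, electrode noise spectra, inter-subject
variability, or any coupling between stress and heart-rate variability
beyond mean rate and amplitude.  Passing tests therefore demonstrate that
the pipeline recovers structure *of the kind assumed*, at desk scale; they
say nothing about accuracy on real driving or sleep recordings.

## Problem sizes used in tests and the acceptance script

Training at the emulated corpora's scale (10⁵ samples, 60 horizons,
10-fold CV) is out of scope; the package's own study conditions are
scaled down: 240–600 s records, horizons 1–10 (merge study) and 1–30
(horizon-decay study), hidden size 8, window 4, 8–10 epochs, learning
rate 0.05, 3-fold CV, NSGA-III population 24 × 10 generations for the
merge and 92 × 100 generations for the analytic-front benchmark.  These
sizes were chosen once as the smallest at which the studied effects are
stable across seeds.

## Known limitations

- Plain SGD with clipping is deliberate (inspectability, determinism);
  convergence is slower than adaptive optimizers and the default learning
  rate 1e−3 is conservative — the scaled-down studies use 0.05.
- The integrator onset/offset landmarks are exposed only implicitly; Q/S
  wave positions are not delineated (they are unused downstream).
- The WFDB reader is an optional adapter (`pip install ecghorizon[wfdb]`);
  the core pipeline and all tests use the delimited-text dialects.
- `per_class_accuracy` is class recall; for a class absent from a fold's
  validation labels the objective skips that fold rather than imputing 0.
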