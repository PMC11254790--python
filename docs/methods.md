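# Methods

This note documents the models, parameter choices and numerical decisions
behind `heartbeat-id`, and what the synthetic experiments do and do not
demonstrate.

## The identification problem

Closed-set identification: every probe beat belongs to one of the enrolled
subjects, and the classifier must name that subject. The biometric unit is
a single R-R segment — the signal between two consecutive R peaks —
interpolated to a fixed 150-sample vector. Compared with the more common
R-centered window, the R-R segment covers one complete systolic + diastolic
cycle regardless of heart rate, at the cost of a rate-dependent time
stretch that the fixed-length interpolation absorbs.

## Synthetic ECG model

Each subject is a template of five Gaussian waves (P, Q, R, S, T) with
per-wave center offset relative to the R peak (ms), signed amplitude (mV)
and Gaussian width (ms). Default sampling intervals keep the offsets
physiologically ordered and disjoint (P ≈ −220…−140 ms, Q ≈ −45…−20 ms,
R = 0, S ≈ 20…45 ms, T ≈ 220…340 ms) with R amplitude 0.8–1.6 mV dominating
all other waves. A beat is rendered as an R-R segment: R, S and T belong to
the current beat, while the P and Q near the segment's end belong to the
next one, so concatenated segments tile into a seamless trace and every
rendered R center is known exactly.

- **Rhythm**: R-R intervals are i.i.d. truncated normal with mean 800 ms,
  SD (SDNN) 40 ms, floored at 400 ms — a resting rhythm with realistic
  short-term variability. Artifact injection perturbs chosen intervals:
  ectopic shortening or dropped beats change the interval by more than
  3·SDNN + 10% of the mean (the aberration margin used throughout), and
  noise bursts corrupt amplitude without touching the rhythm.
- **Noise**: sinusoidal baseline wander (0.1 mV at 0.25 Hz), power-line
  interference (0.05 mV at 50 Hz), and white noise (SD 0.02 mV). Both
  periodic terms sit outside the 0.6–40 Hz analysis band by construction,
  so the band-pass visibly attenuates them.
- **Generation rate**: 500 Hz by default, so the 250 Hz resampling stage is
  always exercised.

What the generator does **not** emulate: pathological morphologies
(arrhythmia taxonomies), electrode-motion transients, within-subject
morphology drift across sessions, respiratory modulation of amplitude, or
multi-lead geometry. Synthetic subjects are therefore *easier* to separate
than a mixed clinical population: passing the end-to-end test shows the
pipeline is implemented correctly and that R-R morphology carries identity
under the stated noise model — not that any particular accuracy transfers
to clinical cohorts.

## Preprocessing

All records are resampled to 250 Hz by rational-factor polyphase filtering
(exact 128→250 and 500→250 conversions), then band-pass filtered with a
3rd-order Butterworth, 0.6–40 Hz. The filter is applied forward–backward by
default: beat clipping is anchored on fiducials, so zero group delay
matters more than a causal response, and the effective magnitude response
is |H(f)|². A causal mode (`zero_phase=False`) is retained for fidelity
experiments. Filtering follows resampling.

## R-peak detection

The Pan–Tompkins constants are the classic published values, scaled by the
sampling rate: detection band-pass 5–15 Hz (implemented as a 1st-order
Butterworth band-pass applied zero-phase; the original's recursive integer
filters are tied to 200 Hz), five-point derivative, squaring, 150 ms
moving-window integration, 200 ms refractory period, T-wave rejection by
slope comparison for candidates within 360 ms of the previous QRS, and a
search-back pass with halved thresholds when no beat appears within 166% of
the running R-R average. Signal/noise peak estimates and thresholds adapt
with the standard 0.125/0.875 running averages on both the integrated and
the band-passed signal; the first two seconds initialize them.

Reported indices are refined in two stages: an integration-hump maximum can
sit several tens of milliseconds away from the R wave, so the detector
first snaps to the strongest band-passed deflection within ±75 ms (half the
integration window), then to the maximum of the preprocessed signal within
±40 ms. Records shorter than 2 s are rejected.

## Rigid R-R thresholding

Per record — never pooled across records or subjects — eight reference R-R
lengths are selected and their mean μ and *population* standard deviation σ
(divisor N = 8) define the retention band [μ−σ, μ+σ], bounds inclusive.
The reference selection automates what would otherwise be a manual choice
of "normal-range" intervals: the default `median-nearest` rule takes the
eight intervals closest to the record median (ties broken by earliest
occurrence, returned in original order), because the median is robust to
exactly the artifacts the rule must exclude. A `first-k` rule is available
for sensitivity analysis.

Two consequences worth stating plainly:

- On a record with tightly clustered rhythm plus occasional aberrant
  intervals, the band rejects essentially all aberrations and keeps
  essentially all normal beats — this is the regime the rule is designed
  for, and the regime the selectivity tests use (constant rhythm with
  injected ectopic/dropped-beat artifacts).
- Under continuous physiological variability (SDNN ≈ 40 ms) the
  median-nearest reference intervals cluster near the mode, σ becomes
  small, and the band keeps only a few percent of beats. The rule is a
  *purity filter*, not a yield-preserving one; the retained beats have
  nearly identical R-R length, which also standardizes the interpolation
  stretch. Synthetic records are therefore generated ~33× longer than the
  number of beats wanted in a dataset (`pipeline.synthetic_beat_dataset`).

Retained half-open segments [xᵢ₋₁, xᵢ) are mapped onto 150 points by linear
interpolation over normalized time (exact on piecewise-linear data, no
ringing; cubic available). Endpoints are preserved exactly. A record
yielding fewer than eight intervals produces zero beats with a warning
rather than an exception, so cohort runs degrade gracefully.

## Balancing

Original SMOTE, not a variant: each synthetic beat is s = x + λ(x_nn − x)
with x a uniformly drawn beat of the minority subject, x_nn one of its
k = 5 nearest same-subject beats under Euclidean distance on the 150-sample
vectors, and λ ~ U[0,1]. Every synthetic row records (seed row, neighbor
row, λ) so the interpolation can be replayed and audited. Majority subjects
are randomly down-sampled. The target is either the rounded mean (half
away from zero) or the maximum of the per-subject counts; after balancing,
all counts are exactly equal. A subject with a single beat cannot be
interpolated and aborts with a clear message rather than silently
duplicating.

Scope: by default balancing is applied to the **training partition only**.
Balancing the whole dataset before splitting lets SMOTE interpolants of
test beats leak into training and inflates test scores; a `whole_dataset`
mode is retained for protocol-comparison experiments, with that caveat.

## Classifier

Architecture (valid padding, input length 150): conv(16 kernels, size 3) +
ReLU → maxpool(2) → conv(32, 3) + ReLU → maxpool(2) → flatten →
dense(100) + ReLU → dropout(0.2) → dense(n_classes) + softmax. Feature
lengths 148 → 74 → 72 → 36; flatten width 1152; parameter count
64 + 1 568 + 115 300 + 101·N (118 750 at N = 18).

Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch 32, categorical
cross-entropy, at most 500 epochs, early stopping on validation loss with
patience 20 and best-weights restoration. Padding convention and
early-stopping details are otherwise-open choices fixed here: `valid`
padding by default (`same` selectable), validation-loss monitoring as the
standard reading of "early stopping".

The network is written directly in numpy — im2col convolutions, analytic
backpropagation (verified against finite differences to ~1e-10), inverted
dropout, Glorot-uniform initialization — so training is bit-reproducible
for a fixed seed on a single thread and carries no deep-learning framework
dependency. Beats are fed in mV without per-beat normalization; a per-beat
z-score flag exists for robustness studies.

## Evaluation

Confusion matrix with rows = true subject, columns = predicted. Overall
accuracy is trace/total (the multi-class reading of "correctly classified
over all instances"); per-class TP/FP/TN/FN are one-vs-rest, with
precision TP/(TP+FP), sensitivity TP/(TP+FN), F1 their harmonic mean, and
the per-class binary accuracy (TP+TN)/total also recorded. Macro averages
are unweighted means over classes; weighted averaging is never used. Any
0/0 ratio is defined as 0 and logged.

## Experimental scenarios

Both scenarios split 60:20:20 (train:validation:test), stratified by
subject via largest-remainder apportionment within each class — closed-set
identification requires every subject in every partition.

- **Imbalanced**: no balancing. The 20% test split is held out once; the
  remaining 80% is divided into five stratified folds, and each fold's
  model (trained on four folds, validated on the fifth) is evaluated on
  the held-out test split; per-fold and mean ± SD metrics are reported.
- **Balanced**: split first, balance the training partition (default
  scope), train once, evaluate on the untouched test split.

Problem sizes used by the test suite and the acceptance script: 20
subjects with 30–200 dataset beats each for the end-to-end run, 20 subjects
× ~60 s for detector quality, five ~85 s constant-rhythm records with six
injected artifacts each for thresholding selectivity. These sizes keep the
full run to a few CPU-minutes while leaving each check statistically
meaningful (≈1 600 beats for detection, ≈500 normal + 30 aberrant intervals
for selectivity, ≈2 400 beats for identification).

## Known limitations

- Synthetic cohorts have stationary morphology; cross-session drift, the
  main failure mode of real ECG biometrics, is not modeled.
- The rigid band's low yield under physiological variability means long
  records are needed for large per-subject counts (see above).
- The WFDB reader supports the format-16 single-segment subset only.
- Open-set rejection (unknown subjects) is out of scope; the softmax
  always names an enrolled subject.
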