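# Methods

This note documents the models, the synthetic-data assumptions, the
tunable parameters and the design decisions behind `graspfuse`. It
states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Surface EMG under a stationary motor state is treated as a zero-mean
Gaussian random process; a reach-to-grasp trial is a concatenation of
four such states (reach, grasp, return, rest) with different
per-channel statistics. Preprocessing follows standard EMG practice:

* **Band-pass 40–500 Hz**, 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`). The filter order is a package
  choice: 4th order is the common EMG default, and zero-phase
  application keeps envelope timing aligned with the raw signal (and
  hence with ground-truth breakpoints). The high-pass edge removes
  motion artifact and DC; the low-pass edge removes out-of-band noise.
* **RMS envelope**, sliding window of 150 samples (96 ms at
  1,562.5 Hz), *centered* with edge truncation. Centering is a package
  choice (the alternative, causal alignment, delays the envelope by
  half a window and would bias phase-boundary timing).
* **MVC normalization**: each channel is divided by the maximum of that
  channel's MVC-recording envelope, processed with identical settings.
  A non-positive MVC maximum raises an error naming the channel.
* **Windowing**: T = 320 ms windows (exactly 500 samples) with 32 ms
  overlap, read literally as a shared 32 ms between consecutive windows
  (stride 288 ms = 450 samples). The alternative reading — stride of
  32 ms — exists in the literature, so both window and overlap are
  configuration values. Windows are taken over the normalized envelope
  (the preprocessing order band-pass → envelope → normalize → window);
  ms-to-sample conversions round half-up.

## Greedy Gaussian segmentation

Each candidate segment `[s, e)` of the *raw* trial (segmentation runs
before any filtering or normalization) is scored by

    ψ(s, e) = −(T/2) · log det(S + (λ/T)·I),        T = e − s,

where `S` is the empirical covariance about the estimated segment mean
(or about zero with `zero_mean=True`). Partition-independent constants
are dropped; with λ = 0 and a singular covariance the score is −∞
(returned, never raised). K breakpoints are fitted by greedy insertion
— each insertion exhaustively scans every admissible split of every
current segment (vectorized via cumulative first/second moments and a
batched `slogdet`) — followed by adjustment sweeps that re-optimize
each breakpoint between its neighbours until none moves, capped at 20
sweeps. Ties in split position go to the smallest index, which makes
the fit deterministic.

Parameters and defaults:

* `n_breakpoints = 3` (four phases; K is fixed, not selected).
* `lambda_reg = None` → resolved to 0.1 × the mean per-channel variance
  of the whole series. The regularizer keeps short-segment covariances
  well-conditioned and, being scaled to the data variance, is unit-free.
* `min_segment_samples = 50` (≈ 32 ms): prevents degenerate slivers; it
  must be ≥ C+1 when λ = 0.
* `zero_mean = False` by default: segments are modeled with "different
  means and variances"; the zero-mean variant of the stationarity
  assumption is available as a flag.
* `split_stride` (default 1, i.e. full scan; a 4 s × 12-channel trial
  takes well under a second) enables a coarse-to-fine scan for longer
  recordings: coarse stride followed by a ±stride refinement at 1.

`exhaustive_segment` brute-forces all admissible breakpoint tuples
(refusing above a configurable cap) with the same scoring and serves as
the independent oracle in the tests: greedy never exceeds it, and on
clearly two-regime series it attains it. Phase tags are positional
(temporal order reach, grasp, return, rest), not statistics-driven.

## Features and classifiers

Per window and channel: RMS = √(mean x²), MAV = mean |x|,
VAR = mean (x − x̄)², concatenated as (RMS₁..RMS_C, MAV₁..MAV_C,
VAR₁..VAR_C). The identity VAR = RMS² − x̄² is used as a cross-check in
the tests. Windows are labeled by the phase containing their **center
sample** (the package's resolution of boundary-straddling windows;
the center minimizes ambiguity), gesture l ∈ {1..13} in
reach/grasp/return and l = 0 (open palm) at rest.

Both classifiers are scikit-learn `ExtraTreesClassifier` ensembles with
50 trees and `min_samples_split = 2`, seeded for determinism: a
14-class gesture model (rest included) and a 4-class motion-phase
model, trained on the identical feature pipeline. Return-phase windows
are excluded from gesture training by default (the hand has released
the object; validation always keeps all phases). Class imbalance from
abundant rest windows is left unweighted by default. For fusion, the
14-class posterior is restricted to {1..13} and renormalized; if the
grasp classes carry no mass (the classifier is certain of rest) the
restriction is uniform, which is inert under the product rule.

## Evidence fusion

With a uniform prior over grasp types and conditionally independent
evidence streams, the maximum-a-posteriori grasp maximizes
`P(L=l|M)·P(L=l|V)` over l ∈ {1..13}. Implementation choices:

* inputs are floored at ε = 1e-6 and renormalized before the product,
  so a hard zero cannot permanently veto a class; outputs change by
  < 1e-4 total variation when ε is halved;
* a missing modality is replaced by the uniform vector (the
  multiplicative identity after renormalization), so fusion degrades
  gracefully to the available modality; both missing is a distinct
  no-evidence signal;
* argmax ties break to the smallest label;
* rest is handled outside fusion: the product rule operates over the 13
  grasp classes only, and the 4-class phase classifier provides the
  when-to-act signal;
* decision smoothing is a causal majority vote over the last w = 5
  decisions, ties to the most recent tied label. Kalman or learned
  temporal fusion is out of scope.

Gaze selects the fused vision evidence: the detection box containing
the gaze point (if exactly one does), else the box with the nearest
center, ties to the smallest index; no detections is a distinct
no-detection value.

**Cross-modal pairing.** EMG posteriors are paired with the nearest
vision frame within a 50 ms tolerance. Pairing uses the EMG window's
*center* time: the features summarize the whole 320 ms window and the
window is phase-labeled by its center, so the co-temporal vision frame
is the one at the midpoint (which is already in the past at the time
the window completes, so the pairing remains causal). Pairing at the
window's end time would systematically fuse evidence from 160 ms later
— across the reach-to-grasp transition, evidence from the wrong phase.
Evaluation timelines keep the window-end timestamp convention.

## Synthetic sessions

The generator emulates the acquisition protocol: sessions of objects ×
6 trials, each trial 4 s with phases reach/grasp/return/rest. Defaults,
chosen once for physiological plausibility:

* **Phase durations** (1120, 800, 704, 1376) ms — variable-length
  phases with a ~1.4 s rest (half a rest ≈ the 700 ms display-shift
  convention); each duration is an exact multiple of the 0.64 ms sample
  period so a trial is exactly 6250 samples.
* **EMG**: unit-variance Gaussian noise band-limited to 40–500 Hz,
  multiplied by a per-channel standard-deviation profile
  `base + activation(phase) · scale` (base noise floor 0.05 arbitrary
  units; per-gesture activation weights U(0.3, 1) per channel and
  phase; per-phase scale U(0.5, 0.8)). Rest has zero activation, giving
  grasp-to-rest power ratios well above 4 on active channels. Phase
  boundaries blend through 50 ms raised-cosine cross-fades (real phase
  transitions are not instantaneous, which stress-tests the segmenter);
  the ground-truth breakpoint is the cross-fade midpoint. A per-trial,
  per-channel lognormal gain jitter (σ = 0.2, matching the ~20–30%
  repetition variability of surface EMG) keeps the classification task
  realistically imperfect.
* **MVC**: a 3 s burst per channel whose plateau standard deviation is
  1.2× the largest task-phase value, so normalized task envelopes stay
  ≈ ≤ 1 (checked as a 99th-percentile bound in the tests).
* **Vision**: per-frame logits with the true class at 3.0 and Gaussian
  noise (sd 1.1) on all classes, softmaxed at temperature 1.5; this
  yields ~85% frame-level accuracy when the object is visible. During
  the grasp phase (± a 150 ms margin ramp) the true-class logit is
  scaled by `1 − depth` (default depth 0.8), collapsing accuracy toward
  chance — occlusion degrades evidence continuously instead of flipping
  labels. The temperature is set by a calibration criterion: at 1.5 the
  occluded stream's mean confidence matches its accuracy and the
  un-occluded stream is under-confident, so the synthetic detector is
  never over-confident (the behaviour of a score-calibrated detector).
* **Gaze and boxes**: gaze scatters (σ = 15 px) around the true
  object's box; each frame also carries a distractor box confidently
  peaked on a different class, so box selection is exercised end to end.

What the generator does *not* model: images or detector internals,
eye-tracker noise models, electrode shift, fatigue, cross-talk, or any
non-Gaussian EMG structure. Passing tests therefore demonstrate the
correctness and the qualitative complementarity structure of the
inference chain — vision dips under occlusion, EMG is uninformative at
rest, fusion dominates both — not performance on real recordings.

## Evaluation conventions

* Per object, 4 of 6 trials train and 2 validate (216/108 on a
  54-object session); the split is a seeded uniform partition.
* Trials are aligned at grasp onset (0 ms) using their own segmentation
  breakpoints; the additional 700 ms backward shift affects only
  exported display timelines, never accuracy.
* Accuracy-over-time bins default to one window stride (288 ms), one
  point per window position; empty bins are omitted. With phases of
  variable length, averaging is over absolute aligned time bins.
* The per-phase table has the five-phase layout with two rest columns:
  rest windows before grasp onset (present when trials are chained)
  and after the return. The total is the window-count-weighted mean,
  i.e. exactly the overall window accuracy.
* The expected label is the trial's grasp type in every phase for every
  source. The EMG row uses the 14-class argmax, so its rest-phase
  accuracy sits near (or below) the 14-class chance level — muscles at
  rest carry no grasp information, and a well-behaved classifier says
  "rest", which never matches a grasp label.

## Problem sizes

The test suite and acceptance script run everything at desk scale,
which the experiments show is statistically sufficient for the
properties checked: oracle comparisons on ≤ 60-sample series (where
brute force is exact), breakpoint recovery over 100 independent
trials, fusion complementarity over 20 sessions of 10 objects × 6
trials with ground-truth phase annotation (isolating the fusion
property from segmentation error), and the full pipeline including
greedy segmentation on sessions of 10 objects. The headline accuracies
reported by `scripts/acceptance.py` average 5 full end-to-end sessions.

## Known limitations

* Phase tagging is positional; a trial that does not follow
  reach→grasp→return→rest would be mistagged.
* The greedy segmenter is a local optimizer; optimality is only
  guaranteed (and only checked) against brute force on small instances.
* The product rule assumes conditionally independent, reasonably
  calibrated posteriors; a persistently over-confident wrong modality
  can still flip fused decisions.
* The synthetic vision stream models detector *output* statistics, not
  detection failure modes such as dropped boxes (missing frames are
  supported by the fusion layer but not generated by default).
* Smoothing is evaluated as a fixed causal majority vote; no claim is
  made about the smoothing used in any particular hardware controller.
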