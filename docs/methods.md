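# Methods

`kicksense` implements an end-to-end pipeline for detecting shots and passes
from in-shoe inertial sensors in football, together with the baselines and
evaluation protocols needed to study how such detectors degrade between
laboratory and real-world recordings. This note documents the models, the
synthetic data they are exercised on, and the numerical choices that were
genuinely open.

## Signal model and conventions

Each foot carries a 6-channel IMU: tri-axial accelerometer (full scale
±16 g) and tri-axial gyroscope (±2000 °/s), nominally sampled at 200 Hz.
Channel order is fixed as `(ax, ay, az, gx, gy, gz)`; `gx` is the
sagittal-plane angular velocity, the axis on which the forward leg swing of
a kick appears. Windows are half-open `[start, end)`, indices 0-based,
times in seconds.

Signals are scaled to [−1, 1] by dividing by the *fixed sensor full scale*
(16 g, 2000 °/s), not by per-session min–max. This keeps scaling
session-independent and preserves the semantics of accelerometer
saturation: a saturated shot impact maps to ±1 in every session, and
saturation is one of the cues that distinguish shots from passes. Samples
with |a| ≥ 15.9 g are treated as saturated for synthesis and QC only; no
classifier thresholds on that value.

## Synchronization and resampling

Sessions are synchronized to video by clapping a rod holding all sensors to
the ground three times at the start and end of a recording. Detection is
rule-based: the pointwise minimum across accelerometer axis magnitudes
exceeds a threshold only when *all* axes peak simultaneously; clusters of
≥ 3 such peaks within a bounded span qualify as a burst. The threshold
(8 g) and span (2 s) are module defaults chosen for the synthetic claps,
not measured constants. The true sampling rate is the sample count between
bursts divided by the video-derived duration; streams are then linearly
interpolated onto a uniform 200 Hz grid (interpolation strategy is
config-selectable; only linear ships). Estimated rates outside ±5% of
200 Hz are rejected.

## Candidate selection

The classifiers only see *candidate* windows. The gyroscope is high-pass
filtered (2nd-order Butterworth, 20 Hz cutoff, causal by default — a
zero-phase variant exists but is not deployable), the per-sample Euclidean
norm of the filtered axes (signal magnitude vector, SMV) is computed, and a
moving window of 2 s with 25% overlap is scanned. Peaks are local SMV
maxima above `0.3 × max(SMV in the window)` thinned greedily so kept peaks
are ≥ 300 samples apart (highest first, ties to the earliest index).

A purely relative threshold can never reject a window — every window
attains its own maximum — so an absolute activity floor is applied on top:
`min_height = 0.025` in scaled units (50 °/s of high-passed SMV). Gait and
running residue after the 20 Hz high-pass stays well below this floor;
every ball-contact transient sits well above it. With the floor, standing
or walking windows produce no peaks and are rejected.

Peaks found in overlapping windows within 100 samples (0.5 s, the closest
detectable event spacing under this segmentation) are merged keeping the
larger SMV. Each surviving peak yields a 2 s block centered on the peak
(zero-padded symmetrically at stream edges and flagged); its ground-truth
label is derived from the events inside a 1 s window around the peak, with
precedence shot > pass > null so that rare-class ground truth survives
multi-event windows. Candidates whose only events are off-camera
(`unknown`) contacts are marked excluded and dropped from evaluation.

## Feature-based baseline

The literature baseline segments the *kick phase*: ball contact is the
maximum first difference of `gx` (discrete sagittal angular acceleration at
200 Hz, no smoothing; ties to the earliest index), and the phase starts at
the last zero crossing of `gx` before contact (exact zero sample, or the
index after a sign change). If no crossing exists the window start is used
and a warning logged — needed for degenerate real windows. Six features —
the absolute sum of each channel over the closed phase interval — feed a
linear one-vs-rest SVM. Training under-samples to the minority class once
per run (seeded), then selects C from {2^N, N = −10…10} by best mean
weighted F1 over session-grouped 5-fold cross-validation and refits on all
data. Windows with a constant sagittal channel cannot be segmented and are
scored as null (logged).

## Deep window classifiers

Three architectures classify raw scaled 400 × 6 windows into
(shot, pass, null). They are implemented in NumPy with hand-written
backprop; gradient correctness is pinned by finite-difference tests, and
every per-layer parameter count and intermediate shape is asserted against
the architecture tables.

* **CNN** — three valid conv(+ReLU)+maxpool blocks (256/128/16 filters,
  kernel 3, pool 2) with dropout 0.30228/0.03576 after the 2nd/3rd conv,
  dropout 0.43372 before a dense softmax head; LR 0.09996. 111,763
  parameters (4864 + 98,432 + 6160 + 2307).
* **LSTM** — one 64-unit layer returning the final state, batch feature
  normalization, and a dense head with L1 = 0.00013 / L2 = 0.00111 kernel
  penalties; gradient-value clipping at 0.19517; LR 0.06955. The recurrent
  layer uses two independent bias vectors per gate set (input-path and
  recurrent-path), a hard contract: 4·64·(6+64) + 2·4·64 = 18,432
  parameters (single-bias would give 18,176... i.e. not match).
* **convLSTM** — the window is cut into 8 segments of 50 samples forming a
  (8, 1×50, 6) sequence; a convolutional LSTM with 128 filters and a 1×3
  kernel (valid input conv 50→48, same-padded recurrent conv, one bias per
  gate: 4·128·(3·(6+128)+1) = 206,336 parameters) returns its final state,
  followed by dropout 0.22620, flatten (6144) and a dense head (18,435);
  LR 0.09403.

These hyperparameters are the published optima of a 500-trial Bayesian
search on the original large-scale dataset; the search spaces ship in
`kicksense.nn.search`, which provides a desk-scale random-search
replacement with grouped CV and median pruning.

**Initialization.** Kernel weights are Glorot-uniform, recurrent LSTM
matrices orthogonal. The 400-step LSTM uses a chrono-style gate-bias
initialization (forget bias +4, input bias −4): with the conventional
forget bias of 1 the initial memory time constant is ~3 steps, an event at
the center of a 400-step window is invisible in the final hidden state,
gradients carry no information about it, and the layer cannot start
learning at the data scales this package targets. Chrono biases give the
cell an initial memory horizon comparable to the sequence length, which is
what makes last-state classification of centered events trainable. The
convLSTM runs over only 8 segment steps, where the classic unit forget
bias already spans the sequence, so it keeps the conventional
initialization. Parameter counts are unchanged in both cases.

**Training.** Plain SGD (momentum 0 by default, configurable), batch size
64, up to 100 epochs. Class balance is restored by random under-sampling
of the majority classes once per run (seeded), drawn before training, not
per epoch. Epoch-level validation weighted F1 drives the schedule: LR ×0.2
after 20 stagnant epochs, early stop after 40, best-epoch weights restored.
All randomness (under-sampling, shuffling, dropout) derives from the config
seed; training is invariant to input order given the seed.

## Metrics and evaluation scenarios

Per-class F1 is the harmonic mean of precision and recall with the 0/0 → 0
convention; the headline metric is the class-support-weighted mean F1.
Sensitivity of class c is TP_c/(TP_c+FN_c); with zero support it is
reported as not available rather than 0. The fine-grained confusion matrix
tabulates predicted class against detailed ball-contact type and normalizes
each column, so a perfect classifier places a single 1 per nonempty column.

Three scenarios: `segmented_lab` (one centered window per labelled contact,
no candidate selection), and `window_lab` / `window_field` (moving windows
over the whole stream, candidate selection, classification of candidates
only, with rejection statistics reported). Reports serialize to JSON with
the fully resolved configuration embedded.

## Synthetic data

The original dataset (181 sessions, 836 players, 93,846 labelled contacts)
is proprietary, so all testing runs on a generator that reproduces the
statistical structure the pipeline depends on:

* background as piecewise standing/walking/running segments — harmonic
  stride pattern (configurable cadence, ~2.2 Hz walking, ×1.4 running)
  plus Gaussian sensor noise;
* ball contacts built from three cues: a damped accelerometer impact
  (shots draw 18–26 g and clip at the ±16 g full scale, producing the
  saturation plateau), a high-frequency gyroscope transient at contact
  (fixed 45 Hz band; amplitude is the class cue), and a sagittal half-sine
  swing on `gx` ending at contact, preceded by a small counter-swing so the
  last zero crossing before contact marks the kick-phase onset;
* accelerometer ringing frequency grows with contact hardness
  (28–55 Hz from light contact to shot) — a morphology cue that integrals
  barely see;
* class imbalance null > pass > shot in every default configuration, and a
  helper to hit an arbitrary shot:pass:null ratio (e.g. the real-world
  8424 : 24,254 : 61,168) within rounding;
* the three-clap synchronization burst, with ground-truth clap times
  returned for testing the detector;
* field-flagged sessions widen every amplitude range (spread ×1.8) and use
  a more agile background than lab-flagged ones.

Amplitude ranges are free parameters, not estimates of the real data. Two
regimes are named: **separable** (default; per-class ranges disjoint on
every cue) and **confusable**, in which everything the absolute-sum
features integrate — swing amplitude × duration, impact amplitude × decay —
overlaps heavily across shot/pass/strong-contact (the low-intensity-shot
vs hard-long-pass confound), while instantaneous morphology still differs.
In the confusable regime the sum-feature SVM degrades with shot and pass
sensitivities falling below null, while shape-aware models keep
discriminating — the qualitative pattern reported for real data, at desk
scale.

What passing tests do **not** show: the generator has no biomechanically
validated kick dynamics, no two-foot coupling, no player-level variation
beyond amplitude jitter, no camera/labelling noise, and its background
lacks the long tail of agile no-contact movements that dominate real
false-positive analyses. Absolute scores on synthetic benchmarks say
nothing about absolute real-world performance; only directional and
structural claims (candidate recall, deep-vs-shallow ordering, metric
definitions, determinism) transfer.

## Benchmark harnesses and problem sizes

The acceptance studies run at sizes chosen for a single desktop CPU:
16-session (~560-window) benchmarks for the separable CNN study, 24
sessions for the four-way comparison, 20 default sessions for the
candidate-recall study. Per-architecture epoch budgets reflect convergence
speed: 30 epochs for the CNN, the full 100-epoch schedule for the LSTM,
60 for the convLSTM. The benchmark harness configures SGD momentum 0.9
uniformly for all architectures: the published learning rates were tuned
for tens of thousands of gradient updates, and at the few hundred updates
of a desk-scale benchmark plain SGD is too noisy to converge reliably,
while momentum restores stable learning for every model. The separable
study stops early once the target validation F1 is reached.

## Degenerate inputs and tie-breaks

* `detect_peaks` on an all-zero window returns no peaks (avoids a zero
  threshold firing everywhere); equal-height peaks keep the earliest.
* Constant sagittal gyro → degenerate-window error; scored as null in
  pipeline evaluation.
* Candidate blocks overrunning the stream are zero-padded symmetrically
  and flagged.
* Sensitivity with zero support is n/a, never 0; weighted F1 with all
  supports zero is an error, and window scenarios with zero candidates
  report empty metrics with rejection fraction 1.

## Known limitations

* Recurrent training at the published learning rates is noisy at desk
  scale (hundreds of gradient updates rather than tens of thousands);
  best-epoch restoration and LR annealing mitigate but do not remove
  run-to-run variance.
* The sync detector assumes the rod pattern is the only simultaneous
  all-axis super-threshold event; it has no manual fallback.
* Only linear interpolation is implemented for resampling.
* The generator's `unknown` contacts reuse pass-like morphology; real
  off-camera contacts are more heterogeneous.
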