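# Methods

`fmdetect` re-implements, as a tested and reusable pipeline, a
detection-validation analysis for wearable fetal-movement (FM) monitoring:
six abdominal vibroacoustic channels (three piezoelectric, three acoustic)
are cleaned, turned into STFT features under three sensor-fusion
strategies, and classified into movement / non-movement windows against
ultrasound-detected fetal movement (UDFM) annotations, with maternally
perceived movement (MPM) button presses analysed for agreement.  Because
no clinical recordings are deposited, the package ships a synthetic
session generator with the statistical structure the analysis assumes;
every result in the test-suite and acceptance script is computed on that
synthetic data and should be read as a validation of the *pipeline*, not
as a clinical claim.

## Synthetic sessions

A session is a 30-minute (default) recording at 512 Hz: six sensor
channels, one IMU channel on the ultrasound probe, one push-button
channel.  Defaults encode the study conditions:

| parameter | default | meaning |
|---|---|---|
| `duration_s` | 1800 | session length (s) |
| `fs` | 512 | sampling rate (Hz) |
| `event_rate` | 240 · duration/1800 | expected UDFM events per session |
| `event_duration_s` | 1.0 | mix-weighted mean event length (s) |
| `event_class_mix` | general .40, limb .30, breathing .15, startle .15 | class probabilities |
| `perception_prob` | 0.61 | probability a UDFM event triggers an MPM press |
| `probe_episode_rate` | 8 · duration/1800 | probe-motion artefact episodes |
| `sensor_gains` / `sensor_noise_sd` / `sensor_offsets` | heterogeneous per channel | modality and placement differences |

With 240 events of ~1 s in 1800 s the expected annotated-active fraction
is 240/1800 ≈ 13.3%, matching the class imbalance the classifiers must
cope with.  Event classes differ only in duration and amplitude
statistics (duration multipliers 1.03 / 0.93 / 1.65 / 0.41 and amplitude
factors 1.0 / 1.2 / 0.45 / 2.2 for general / limb / breathing / startle;
the multipliers are mix-weighted to 1.0 so the active-time arithmetic is
preserved).  Breathing bursts are additionally amplitude-modulated at
~1.1 Hz.  The binary movement label downstream makes richer class realism
unnecessary.

Each movement burst is an exponentially damped packet of **three**
superimposed sinusoids with independent carriers drawn uniformly from
1–25 Hz and geometrically decaying amplitudes (0.6^k).  A mechanical
transient excites several modes at once; a single pure tone per event
would concentrate each event's energy in one spectral bin, which is both
physically implausible and adversarial to threshold-on-one-bin weak
learners.  The waveform is a stand-in — nothing about the clinical
signal morphology is published — and only its band-limitation (≲25 Hz
carriers, >99% of energy below 35 Hz), duration and energy statistics
are relied on by tests.  Per event, each channel receives the burst
scaled by its modality gain and a random per-event sensor emphasis
(uniform 0.3–1).

The IMU channel is unit-variance Gaussian when quiescent; probe-motion
episodes (exponential durations ≈ 3 s) raise |IMU| to uniform 4–8 and
simultaneously add broadband noise to the sensor channels, so the
integer gating thresholds {4, 5, 6} are meaningful on the synthetic
scale and artefact samples are strictly co-registered with elevated IMU.
The button channel holds one synchronisation press at a uniform 2–25 s,
plus an MPM press 0–2 s after the onset of each perceived event
(independent Bernoulli(`perception_prob`) thinning).

One integer seed spawns independent substreams (one per sensor channel,
plus events, IMU, button) via `numpy.random.SeedSequence`, so sessions
are bit-reproducible.

What the generator does **not** emulate: maternal heart/respiration
interference, gestational-age effects, sensor detachment, non-stationary
noise floors, correlated inter-channel noise, or any biomechanical
transfer function of the abdomen.  Passing tests therefore demonstrate
that the pipeline's bookkeeping, algorithms and statistical behaviour
are correct under the stated assumptions — not that the method achieves
any particular performance on clinical data.

Two auxiliary generators support focused studies.
`make_imbalanced_dataset` emulates labelled windows directly in feature
space (13% positives, a 0.7-SD mean shift on 4 of 8 features against
unit Gaussian noise): separable-with-noise conditions under which an
accuracy-driven learner gravitates to the majority class, used to study
undersampling without the cost of full sessions.
`make_threshold_validation_scan` constructs a session in which a gating
threshold of 5 is exactly right: decoy IMU excursions of magnitude 4.5
over held-out movement events (threshold 4 zeroes real signal) and
movement-like artefact bursts with IMU magnitude 5.5 placed well away
from any event (threshold 6 admits fake movements).  Both manipulations
live in the final 30% of the session so training data are identical
across candidate thresholds and the comparison isolates the gating
decision.

## Preprocessing

Stages run in a fixed order: synchronise → per-channel offset removal →
per-channel RMS normalisation → IMU-gated zeroing → 30 Hz low-pass.

* **Synchronisation** shifts the time origin to the first button press,
  drops earlier samples, and shifts annotation onsets and MPM presses
  identically; events or presses before the sync press are dropped with
  a warning.
* **Offset removal / RMS normalisation** use the full channel, including
  any later-gated segments; normalisation makes channels of different
  modality comparable, and placing it before gating keeps the sensor
  processing scale-free.
* **IMU gating** zeroes all sensor channels wherever |IMU| exceeds the
  threshold (default 5, candidates {4, 5, 6}), optionally padded by
  `guard_s` (default 0: only samples actually flagged are zeroed).  The
  threshold applies to the *raw* IMU magnitude — integer candidate
  values would be meaningless on a normalised IMU.
* **Low-pass**: linear-phase FIR, Kaiser window, designed by the Kaiser
  formula for a 30→35 Hz transition band at 45 dB ripple (≈ 0.05 dB
  passband ripple), applied via centred convolution so the integer group
  delay (L−1)/2 is exactly compensated and labels stay time-aligned.
  A forward–backward pass would also be zero-phase but squares the
  response; a single compensated pass matches the single-filter design.

## Features

Each cleaned channel yields a magnitude STFT on a fixed grid: windows of
`window_s` (default 8 s) starting at 0, hop, 2·hop, …, with hop =
window − overlap (default overlap 2 s ⇒ hop 6 s), no padding at either
end; frequency bins above 30 Hz are discarded (floor(30·window_s)+1
bins; 0.125 Hz resolution at the defaults).  "Overlap" is read as the
shared duration between consecutive windows, consistent with the grid
search iterating overlaps of 1–4 s against windows of 2–10 s.  Frames
are Hann-tapered by default; the taper is a config field (`taper=None`
gives rectangular frames) because tapering interacts with labelling at
window edges (below).  Magnitude (not power, not dB) is used so that the
summed fusion stays linear in the per-sensor spectra.

A window is labelled movement if **any** annotated event overlaps it by
a positive duration: 1 s events inside 8 s windows would be lost to a
majority rule.  A consequence worth knowing: windows that catch only the
first or last fraction of a second of an event are labelled positive but
contain almost no usable signal — under a Hann taper essentially none —
which caps attainable recall below 1 even on noiseless data.  The
recall-ceiling test therefore runs with rectangular frames.

Fusion strategies (model inputs): (1) *individual* — one dataset per
sensor, results averaged; (2) *concatenated* — the six spectrograms
stacked feature-wise in fixed array order (6 × 241 = 1446 features at
defaults); (3) *summed* — element-wise sum of the six magnitude
spectrograms.

## Classifiers

All four are written from scratch behind one `fit(X, y[, w]) / predict(X)`
contract; every vote tie resolves to non-movement.

* **KNN**: brute-force distances (Euclidean default; Manhattan,
  Chebyshev, Minkowski available), uniform or inverse-distance votes,
  k = 3 default (odd to avoid ties).
* **Decision tree**: greedy top-down axis-aligned splits; thresholds are
  midpoints of consecutive distinct sorted feature values; the split
  minimises weighted Gini impurity (entropy optional) over all features
  and thresholds at once (vectorised cumulative sums); ties break to the
  earliest sorted position then the lowest feature index, making refits
  deterministic.  Supports per-sample weights so it can serve as a
  boosting weak learner.
* **AdaBoost.M1** (two-class, so M2 machinery is unnecessary): uniform
  initial weights; per round, weighted error ε_t, α_t = lr·½·ln((1−ε_t)/ε_t),
  multiplicative re-weighting, renormalisation.  ε_t = 0 keeps the round
  with α capped at the ε = 1/(2n) value; ε_t ≥ 0.5 stops (AdaBoost) or
  discards the round and resamples, up to 10 attempts (RUSBoost).
* **RUSBoost**: per round, a random undersample of the majority class
  down to `target_majority_ratio` × minority (default 1.0, i.e. 50:50);
  the weak learner is fitted on the subsample under the current
  full-data weights restricted to it, but ε_t and the weight update are
  computed on the full training set, per the published scheme.
* Defaults: depth-1 stumps, 100 rounds, learning rate 1.  The reference
  analysis does not report its ensemble sizes or depths; these are
  package choices, exposed in the configs.  Trees and ensembles
  serialise to JSON for audit.

## Evaluation protocol

Movement is the positive class; precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = harmonic mean, specificity = TN/(TN+FP).  Zero
denominators flag a metric undefined (`None`) rather than silently 0.

Per scan, the pipeline is preprocess → per-sensor STFT → fusion → split
→ fit → predict → confusion matrix.  The 70/30 split is chronological
within each scan: STFT windows overlap in time, so a random split would
leak test information into training.  If the training portion contains a
single class the scan is scored by a constant majority-class predictor
(with a logged note) rather than aborting the run.  Aggregation follows
the study protocol: model input 1 averages the six sensor matrices
element-wise into per-scan counts; all model inputs then average
per-scan counts element-wise across scans, compute precision and recall
from the averaged counts, and take F1 as their harmonic mean (this
reproduces the internal consistency of the reported per-input table).
Averaging is over scans (the study's 38 analysis units).

Searches: the IMU-threshold search evaluates {4, 5, 6} on the scan with
the most UDFM events and selects the threshold maximising
mean(precision, recall), ties to the lower threshold.  The STFT grid
search covers windows 2–10 s × overlaps 1–4 s (30 valid pairs; pairs
with overlap ≥ window are skipped), selects by F1, ties to the larger
window then the smaller overlap.

`performance_vs_event_count` sorts per-scan metrics by UDFM count and
reports Spearman correlations (undefined when counts are tied).  In
tests the recall-vs-count direction is asserted on pooled recall over
three scans per count level — a single 5-event scan leaves recall
defined on one or two windows, which is pure noise.

**MPM/UDFM agreement.**  The session is discretised into non-overlapping
windows (default 8 s).  A press is attributed to the latest UDFM event
starting within the 2 s perception latency before it; presses with no
such event are spurious.  A window is UDFM-positive when an event
overlaps it, MPM-positive when it holds a matched event or a spurious
press.  Matching presses to events (rather than requiring the press to
fall in the same discretised window) is deliberate: a press fired up to
2 s after an event that starts late in a window lands in the next
window, which would bias the perceived fraction down by ~12% at an 8 s
window regardless of session length and make the perception probability
unrecoverable.  Metric naming follows the study's agreement figure:
"precision" is the fraction of UDFM-positive windows that are
MPM-positive (the maternally perceived fraction, ≈ 61% at the default
perception probability), "recall" the fraction of MPM-positive windows
that are UDFM-positive.  The recovery test uses sparse sessions (12
events per 600 s) so that windows hold at most one event; at the default
density multi-event windows raise the per-window perceived fraction
above the per-event probability, which is a property of the
discretisation, not an estimator error.

## Problem sizes and numerical choices

Tests and the acceptance script run on scaled-down sessions (60–900 s,
1–4 scans, 10–100 boosting rounds) — the package's choice of desk-scale
defaults; all statistical checks keep the study's proportions (13%
active time, 0.61 perception) so the recovered quantities are unchanged.
Directional comparisons (RUSBoost vs AdaBoost recall; recall vs event
count) are asserted over 10 paired seeds with ≥ 8 wins required.
Tolerances: binomial recoveries use 3 standard errors of the pooled
estimate; the harmonic-mean identity on the reported three-decimal
precision/recall pairs is checked to ±0.001, the worst-case propagation
of ±0.0005 input rounding (one of the three published F1 values is off
by one unit in the third decimal relative to its own P/R pair).
Filter contract: ±0.5 dB to 27 Hz, ≥ 40 dB from 35 Hz, verified on the
frequency response and on pure tones.

## Known limitations

* The burst morphology, per-sensor transfer functions and artefact
  spectra are stand-ins; clinical performance numbers cannot be, and are
  not, reproduced.
* Any-overlap labelling plus tapered frames systematically hides events
  clipped at frame edges (≈ 0.87 recall ceiling with Hann frames on
  otherwise easy data); a real deployment would use overlap-weighted
  labels or event-level scoring.
* The probe-noise model zeroes samples rather than reconstructing them;
  long gated stretches leave all-zero windows in training.
* KNN stores its training set; no probability calibration, no
  SMOTE-style oversampling, no neural models.
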