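# fmdetect

Fetal-movement detection from multichannel abdominal vibroacoustic
recordings: signal cleaning, STFT sensor fusion, imbalance-aware boosted
classification, and the evaluation protocol to validate a wearable
fetal-movement (FM) monitor against ultrasound annotations.

## The problem

Maternal perception is the de-facto out-of-clinic FM monitor, but it is
subjective and misses many movements; ultrasound is objective but
sporadic, expensive and clinician-bound.  A low-cost wearable array —
three piezoelectric and three acoustic contact sensors on the abdomen —
can record movement vibrations continuously, but its output must be
validated against ultrasound-detected fetal movements (UDFM) called out
in real time during scanning sessions.  This package implements that
validation pipeline end to end and, because the clinical recordings are
not publicly deposited, ships a synthetic session generator with the
statistical structure the analysis assumes (30-minute 512 Hz sessions,
~13% annotated-active time from ~1 s events of four movement classes,
probe-motion artefacts co-registered with an IMU on the ultrasound
probe, a sync button press, and partial maternal perception of events).

## The method

For each session the six sensor channels are synchronised to a button
press, de-offset, RMS-normalised, gated to zero wherever the probe IMU
magnitude exceeds a threshold (candidates 4, 5, 6), and low-pass
filtered at 30 Hz with a Kaiser-window FIR (fetal movements live below
~30 Hz).  Each channel then yields a magnitude STFT (8 s windows, 2 s
overlap ⇒ 0.125 Hz resolution, bins ≤ 30 Hz), and three fusion
strategies build the feature matrix **X** over time windows:

1. **individual** — one model per sensor, confusion matrices averaged;
2. **concatenated** — per-sensor spectra stacked feature-wise;
3. **summed** — element-wise sum of the six spectra.

Windows are labelled movement when any UDFM event overlaps them.  With
movement as the positive class,

    P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R),

computed from confusion counts averaged over sensors (input 1) and over
scans, after a chronological 70/30 train/test split per scan.  Four
classifiers are implemented from scratch behind one fit/predict
contract: k-nearest neighbours, a Gini decision tree, AdaBoost.M1 over
depth-1 stumps, and RUSBoost — AdaBoost with a random undersample of
the majority (non-movement) class each round, which is what handles the
~13%-positive imbalance.  The evaluation module adds the IMU-threshold
and STFT-grid searches, the recall-vs-event-count analysis, and the
agreement analysis between maternally perceived movement (MPM) button
presses and UDFM.

## Worked example

```python
import fmdetect as fd
from fmdetect.evaluate import run_experiment, ExperimentConfig

scans = [fd.generate_recording(fd.SessionConfig(duration_s=420, seed=s,
                                                scan_id=f"scan{s:02d}"))
         for s in (0, 1, 2)]
result = run_experiment(scans, ExperimentConfig(
    model_input=2, classifier="rusboost",
    classifier_params={"n_estimators": 30}, seed=0))
print(result.summary())
```

prints

```
model input 2 / rusboost on 3 scan(s)
     precision: 0.773
        recall: 0.850
            f1: 0.810
   specificity: 0.474
      accuracy: 0.729
```

Three 7-minute synthetic sessions are generated, cleaned, featurised
with the concatenated fusion (model input 2) and classified by RUSBoost;
the report holds the metrics computed from the confusion counts averaged
over the three scans' held-out final 30% of windows.  `result.per_scan`
is the per-scan table behind it:

```
scan_id  n_udfm   tp  fp  fn  tn  precision  recall
 scan00      42 11.0 3.0 1.0 4.0      0.786   0.917
 scan01      57 12.0 2.0 3.0 3.0      0.857   0.800
 scan02      57 11.0 5.0 2.0 2.0      0.688   0.846
```

Synthetic sessions are far cleaner than clinical data, so these numbers
are a pipeline validation, not a clinical performance estimate (see
`docs/methods.md`).

The same experiment runs from the shell:

```bash
fmdetect simulate --out data --n-scans 3 --seed 0
fmdetect run --data data --out results           # all three model inputs
fmdetect search-imu  --data data --out search    # thresholds 4, 5, 6
fmdetect search-stft --data data --out search --windows 6,8 --overlaps 2
fmdetect agreement   --data data --out agree
```

Each output directory contains CSV tables, a PNG comparison plot and a
`manifest.json` (config snapshot, seed, input hashes) sufficient to
reproduce the run exactly.

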