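# skidetect

Unsupervised detection of alpine-skiing activities in smartphone IMU
recordings.

A phone in a skier's pocket records tri-axial acceleration (m/s²) and
angular velocity (rad/s) over a whole day on the slopes. `skidetect`
segments such a recording into **Skiing** and **Not_Skiing** intervals
without any labeled training data, for skiers, coaches and movement
scientists who want automatic pre-labeling of field recordings.

## Method

1. **Orientation tracking.** A quaternion complementary filter fuses the
   gyroscope (integrated each step, `q ← q ⊗ exp(ω Δt / 2)`) with the
   accelerometer, which pulls the tilt estimate toward the measured gravity
   direction by a small gain per step. Rotating the accelerometer into the
   resulting world frame puts gravity on +Y and proper acceleration on X/Z,
   so the feature space is invariant to how the phone sits in the pocket —
   even if the skier re-pockets it differently mid-session.
2. **Two-stage smoothing.** A centered moving average (0.5 s) then a
   zero-phase Butterworth low-pass (3 Hz, order 4) remove pocket-shake and
   snow-vibration noise while keeping turn oscillations (≤ 1.5 Hz).
3. **Windowed features.** The six channels are cut into windows (3–10 s,
   sliding rate 0.2–1.0, where rate 1.0 means no overlap). Each window
   yields mean, SD, RMS, min, max, median, variance, MAD and energy of the
   raw samples and of their normalized autocorrelation; mean/25%/50%/75%
   percentile-crossing counts of both; mean and median of the periodogram;
   and the signal magnitude area (SMA) over the accelerometer channels.
   Periodic turns keep high autocorrelation; idle noise does not.
4. **Normalization + PCA.** Min–max scaling to [−1, 1] gives the normalized
   feature set (NFS); projecting onto principal components keeping 95% of
   variance gives the PCA set.
5. **Two-cluster detection.** KMeans, a Gaussian mixture, or Ward
   agglomerative clustering splits the windows into two groups; the group
   with the larger raw accelerometer energy is Skiing. Window labels are
   majority-voted onto the timeline and any Skiing segment shorter than
   30 s — too short to be a real run — is relabeled Not_Skiing.

Evaluation against ground-truth segments uses per-sample accuracy, the
all-Not_Skiing baseline, the Rand index `RI = (a + b) / C(N,2)`, its
chance-adjusted form `ARI = (RI − E[RI]) / (max RI − E[RI])`, and
normalized mutual information
`NMI = I(U;V) / √(H(U) · H(V))`. On long imbalanced sessions accuracy
saturates near the baseline; NMI/ARI are the metrics that expose missed,
split or spurious activities.

## Worked example

```python
import skidetect as sk

# a synthetic 20-minute session with 3 runs and known ground truth
spec = sk.random_session_spec(seed=11, sample_rate=100.0)
recording, truth = sk.generate_session(spec)

result = sk.run_pipeline(recording, sk.PipelineConfig(seed=0))
report = sk.evaluate(result.segments, truth, result.operating_recording)
print(report.accuracy, report.ari, report.detected_activities)
```

Running `python examples/02_detect_activities.py` (the same computation)
prints:

```
session: 1206 s, 3 skiing runs
detected segments:
  [    0.0,   120.0) s  Not_Skiing
  [  120.0,   208.0) s  Skiing
  ...
accuracy   99.60 %   (baseline 73.40 %)
NMI        0.960
ARI        0.983
activities detected/true: 3/3
```

99.60% of samples are classified correctly (against a 73.40% majority-class
baseline), the cluster agreement scores are near 1, and all three runs are
found exactly — boundary errors of a few seconds per run are the only
mistakes. The other scripts in `examples/` show session simulation,
orientation invariance under pocket flips, and the model-selection grid
(32 window/rate combinations × 6 models).

## Command line

```sh
skidetect simulate --config session.yaml --seed 7 --output session.csv
skidetect run --input session.csv --output segments.csv
skidetect evaluate --pred segments.csv --labels session.csv.labels.csv --input session.csv
skidetect gridsearch --input session.csv --output grid.csv
```

Recordings are CSV with columns `time_s, acc_x, acc_y, acc_z, gyr_x, gyr_y,
gyr_z`; label segments are CSV with `start_s, end_s, label`.

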