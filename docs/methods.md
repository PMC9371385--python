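# Methods

## Problem and model

A pocket smartphone IMU records body-frame acceleration **a**(t) (m/s²,
includes gravity) and angular velocity **ω**(t) (rad/s) at a few hundred Hz
over a skiing day. Skiing runs produce sustained periodic signals — lateral
and vertical proper acceleration and body roll at the turn frequency
(roughly 0.2–1.5 Hz depending on technique) — while lift rides and standing
produce gravity plus unstructured noise. The task is binary, unsupervised
segmentation of the timeline into Skiing and Not_Skiing.

The pipeline assumes: (i) the phone's attitude changes slowly except for
occasional re-pocketing; (ii) skiing windows carry more acceleration energy
and more autocorrelation structure than idle windows; (iii) any real skiing
activity lasts at least 30 s.

## Orientation tracking

Attitude is a world-from-body unit quaternion, Hamilton convention, world
frame Y-up. Each step integrates the gyro, `q ← q ⊗ exp(ω Δt / 2)`, then
rotates q by `gain × tilt angle` about the axis `â_world × ŷ`, where
`â_world = q a q*` is the world image of the (normalized) accelerometer
sample. This is the standard single-gain complementary filter: gyro trusted
at high frequency, accelerometer at low frequency. Yaw is unobservable
without a magnetometer; initial yaw is 0 and yaw drift is accepted (only
the gravity axis matters downstream).

Parameters:

* `gain` (accelerometer trust per step, default **0.02** at 50 Hz): sets the
  correction time constant ≈ Δt/gain ≈ 1 s — slow enough not to be fooled
  by proper acceleration during turns, fast enough to re-converge within a
  couple of seconds after a pocket flip. No magnitude gating is applied
  (the correction runs on every nonzero sample); a gate is a possible
  extension.
* Initialization: the attitude aligning the **mean of the first 0.5 s** of
  accelerometer samples with +Y. Averaging instead of taking the single
  first sample avoids seeding the filter with one noisy reading, whose ~1 s
  decay transient would otherwise dominate short-session error budgets.

Measured behaviour (test suite): for random static attitudes with 0.3 m/s²
accelerometer noise, the session-mean world acceleration is within
0.05 m/s² of (0, 9.81, 0).

## Two-stage smoothing

Moving average first, then low-pass, applied to all six world-frame
channels (the gyro is filtered unchanged in frame — it has no preferred
world decomposition without yaw):

* `ma_window` = **0.5 s**, centered, edges shrink to available samples
  (unit DC gain everywhere).
* `lp_cutoff` = **3 Hz**, Butterworth order **4**, zero-phase
  (forward–backward, reflect padding).

3 Hz keeps every plausible turn frequency (≤ 1.5 Hz) and removes
pocket-shake noise. The 0.5 s moving average attenuates a 1.5 Hz component
by roughly 20% in amplitude — acceptable because detection uses energy
contrasts, not absolute amplitudes; a 0.3 Hz long-turn signal passes within
5% RMS. At a 500 Hz input rate wideband noise loses > 90% of its SD through
the two stages; at the 50 Hz operating rate the reduction is smaller
because the noise band is already narrow.

## Features

Windows of `window_size` ∈ {3,…,10} s slide at `sliding_rate` ∈
{1.0, 0.8, 0.5, 0.2} × window (overlaps 0/20/50/80%; the incomplete
trailing window is dropped; window count = ⌊(T − w)/step⌋ + 1). Per
channel and window: nine statistics (mean, SD, RMS, min, max, median,
variance, MAD, energy) on the raw samples and on the normalized
autocorrelation; four crossing counts (of the mean and the 25th/50th/75th
percentiles — the percentile reading of "25/50/75 percent crossing", chosen
so the 50% level coincides with the median) on both; periodogram mean and
median (detrended window, nonzero-frequency bins). Plus one SMA column:
mean over time of |ax| + |ay| + |az|. 169 columns total.

Numerical conventions:

* **Energy = mean of squares**, so values are comparable across window
  sizes.
* Autocorrelation uses the biased estimator (divide by N), giving the
  (1 − k/N)·cos envelope for periodic inputs; lag 0 is defined as 1 and a
  constant window maps to zeros beyond lag 0.
* Crossing counts: samples exactly at the level inherit the previous sign,
  so touching without crossing does not count.
* Min–max scaling to [−1, 1] per column, computed per session (the
  single-session unsupervised use case — there is no training split);
  columns whose span is at floating-point noise level (≤ 1e−9 relative)
  map to 0 rather than having jitter amplified to full range.
* PCA keeps components until ≥ `variance_kept` (default **0.95**) of
  variance; deterministic sign convention (largest-magnitude loading
  positive); full SVD solver.

## Detection

Clustering always asks for two clusters: KMeans (k-means++ init, 10
restarts, seeded), Gaussian mixture (full covariances, k-means init,
seeded, reg_covar 1e−5), or Ward agglomerative (deterministic). Literally
identical feature rows cannot be split and are returned as a single flagged
cluster.

Cluster → class mapping is the package's own convention (energy heuristic):
Skiing is the cluster with the larger mean raw accelerometer energy; exact
ties fall to the smaller cluster (skiing is the minority of a day). The
evaluation always uses this mapping — never a best-of-two-orientations
oracle — to avoid optimistic bias.

Window classes are majority-voted onto the timeline (ties → Not_Skiing),
maximal constant-class intervals become segments, and Skiing segments
shorter than `min_duration` = **30 s** (closed bound) are relabeled
Not_Skiing and merged, keeping the timeline fully covered so per-sample
accuracy remains well-defined.

## Evaluation

Both segmentations are expanded to one class per recording sample
(half-open intervals; uncovered time defaults to Not_Skiing). Accuracy and
the all-Not_Skiing baseline are percentages. RI, ARI and NMI are computed
from the contingency table; NMI uses natural logs and the geometric-mean
normalization √(H(U)H(V)) (any consistent log base gives the same value),
with 0·log 0 = 0. Degenerate conventions, flagged in the report rather than
silently scored: two identical trivial (single-cluster) partitions score
ARI = NMI = 1; NMI of a trivial against a non-trivial partition is 0. The
report also flags the high-accuracy/low-agreement regime in which accuracy
is uninformative.

## Synthetic sessions

The generator emulates the statistical structure the pipeline assumes, not
ski biomechanics. A session is idle time (gravity + white noise, default SD
**0.3 m/s²**) interleaved with runs in which the world-frame proper
acceleration is `A sin(2πft)` laterally and `A/2 cos(2πft)` vertically
(quadrature; default A = **3 m/s²**, f ∈ [0.2, 1.5] Hz) with body roll
`0.1·A sin(2πft)` rad and noise SD **1.0 m/s²**. Phone re-orientations are
0.5 s slerp transitions. The gyroscope is obtained by discrete quaternion
differencing of the true attitude track plus noise (SD **0.02 rad/s**), so
the generated stream is kinematically self-consistent: integrating the
noiseless gyro reproduces the true orientation exactly. Optional 2–5 s
amplitude ramps at run boundaries emulate semi-skiing transitions (off by
default).

`random_session_spec` lays out a plausible day fragment: 3–7 runs of
45–120 s (f ∈ [0.3, 1.2] Hz), 5–10 min idle gaps, 1–3 min lead-in, ~1–2 min
tail, and with probability ½ one mid-gap pocket flip — skiing occupies
10–20% of the timeline, matching the heavy class imbalance of real skiing
days.

What passing tests on this generator do **not** show: robustness to
non-sinusoidal turn patterns, skill-dependent variability, slope/terrain
effects, walking or other structured non-skiing activities, or sensor bias
and temperature drift. In particular, idle phases here are statistically
featureless; a real day contains walking bouts that share some feature
structure with skiing.

## Problem sizes and defaults

The shipped default setting is KMeans on PCA features with 8 s windows at
sliding rate 0.5, operating at **50 Hz** (recordings at higher native rates
are linearly downsampled first; 50 Hz amply covers a ≤ 3 Hz passband).
Synthetic sessions in the tests and the acceptance script are generated at
100 Hz — twice the operating rate, so resampling is still exercised —
with 20-to-40-minute durations; the full test suite runs in about two
minutes and the acceptance script in under a minute on one CPU.

## Known limitations

* Yaw drift: proper acceleration is isolated only up to rotation about
  gravity; technique-level analysis would need magnetometer fusion.
* On an all-idle *noisy* session the two-cluster model must still split
  something; fragments can occasionally survive the 30 s rule as spurious
  detections. The degenerate (identical-window) path catches only the
  noise-free case. Real sessions are assumed to contain skiing.
* Fixed-size windows blur activity boundaries by up to one window step per
  edge; detected runs are typically a few seconds short at each end.
* The 30 s rule is applied to Skiing segments only; short Not_Skiing gaps
  between runs are kept.
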