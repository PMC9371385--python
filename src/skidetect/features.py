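"""Windowing, per-window features, min-max normalization and PCA.

Each window of the six filtered world-frame channels yields statistics in
three domains:

* ``raw``  — the window samples themselves,
* ``ac``   — its normalized autocorrelation (repetitive turn patterns keep
  high autocorrelation; idle noise does not),
* ``spec`` — the periodogram of the detrended window.

Per channel: {mean, sd, rms, min, max, median, variance, mad, energy} on the
raw window and on its autocorrelation; {mean-, 25%-, 50%-, 75%-percentile
crossings} on both; {mean, median} of the power spectrum.  One extra column,
the signal magnitude area (SMA), sums mean absolute acceleration over the
three accel channels.  Energy is the mean of squares, so values are
comparable across window sizes.

The min-max-scaled matrix is the normalized feature set (NFS); PCA scores
retaining a configurable fraction of variance form the PCA feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.decomposition import PCA

from .orientation import WorldFrameRecording

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

_STATS = ("mean", "sd", "rms", "min", "max", "median", "variance", "mad", "energy")
_CROSSINGS = ("mean_crossings", "p25_crossings", "p50_crossings", "p75_crossings")

#: sliding rates matching the studied overlaps {0, 20, 50, 80}%
GRID_WINDOW_SIZES = (3, 4, 5, 6, 7, 8, 9, 10)
GRID_SLIDING_RATES = (1.0, 0.8, 0.5, 0.2)


@dataclass(frozen=True)
class WindowConfig:
    """Window length (s) and sliding rate (step as a fraction of the window;
    1.0 means no overlap, 0.2 means 80% overlap)."""

    window_size: float = 8.0
    sliding_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError(f"window_size must be positive, got {self.window_size}")
        if not 0 < self.sliding_rate <= 1:
            raise ValueError(f"sliding_rate must be in (0, 1], got {self.sliding_rate}")

    @property
    def step(self) -> float:
        return self.window_size * self.sliding_rate


@dataclass
class Window:
    """One window: ``[start, end)`` span plus per-channel sample arrays."""

    start: float
    end: float
    samples: dict[str, np.ndarray]
    sample_rate: float

    def __len__(self) -> int:
        return len(next(iter(self.samples.values())))


@dataclass
class FeatureMatrix:
    """Windows x named features, with window spans and a feature-set tag."""

    values: pd.DataFrame
    starts: np.ndarray
    ends: np.ndarray
    feature_set: str  # "raw", "NFS" or "PCA"

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        df = self.values.copy()
        df.insert(0, "window_start_s", self.starts)
        df.insert(1, "window_end_s", self.ends)
        df.to_csv(path, index=False)


def segment_windows(recording: WorldFrameRecording, cfg: WindowConfig) -> list[Window]:
    """Slice the recording into windows at starts 0, step, 2*step, ...

    The incomplete trailing window is dropped; a recording shorter than one
    window yields an empty list.
    """
    import warnings

    ts = recording.timestamps
    t0 = ts[0]
    # each sample represents one sampling interval, so a recording of n
    # samples at rate fs spans n/fs seconds
    duration = ts[-1] - t0 + 1.0 / recording.sample_rate
    if duration < cfg.window_size:
        warnings.warn(
            f"recording ({duration:.3g} s) shorter than one window "
            f"({cfg.window_size} s); no windows produced",
            stacklevel=2,
        )
        return []
    step = cfg.step
    count = int(np.floor((duration - cfg.window_size) / step + 1e-9)) + 1
    channels = recording.channels
    out = []
    for i in range(count):
        start = t0 + i * step
        end = start + cfg.window_size
        lo = np.searchsorted(ts, start - 1e-12, side="left")
        hi = np.searchsorted(ts, end - 1e-12, side="left")
        out.append(
            Window(
                start=float(start),
                end=float(end),
                samples={ch: col[lo:hi] for ch, col in channels.items()},
                sample_rate=recording.sample_rate,
            )
        )
    return out


def autocorrelate(x: np.ndarray) -> np.ndarray:
    """Normalized (biased) autocorrelation over nonnegative lags.

    Lag 0 is 1 for non-constant input; a constant input is defined as 1 at
    lag 0 and 0 beyond (it has no fluctuation to correlate).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("autocorrelation needs at least 2 samples")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    out = np.zeros(n)
    out[0] = 1.0
    if denom == 0.0:
        return out
    full = sps.correlate(xc, xc, mode="full", method="auto")
    out = full[n - 1 :] / denom
    out[0] = 1.0
    return out


def crossings(x: np.ndarray, level: float) -> int:
    """Count sign changes of ``x - level`` between consecutive samples.

    Samples exactly at the level inherit the previous sign, so touching the
    level without crossing it does not count.
    """
    x = np.asarray(x, dtype=float)
    s = np.sign(x - level)
    # zeros inherit the previous nonzero sign (vectorized forward fill)
    nz = s != 0
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    s = np.where(idx >= 0, s[idx], 0.0)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _stats(x: np.ndarray) -> dict[str, float]:
    med = float(np.median(x))
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x)),
        "rms": float(np.sqrt(np.mean(x * x))),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": med,
        "variance": float(np.var(x)),
        "mad": float(np.median(np.abs(x - med))),
        "energy": float(np.mean(x * x)),
    }


def _crossing_features(x: np.ndarray) -> dict[str, int]:
    p25, p50, p75 = np.percentile(x, [25, 50, 75])
    return {
        "mean_crossings": crossings(x, float(np.mean(x))),
        "p25_crossings": crossings(x, float(p25)),
        "p50_crossings": crossings(x, float(p50)),
        "p75_crossings": crossings(x, float(p75)),
    }


def window_features(w: Window) -> dict[str, float]:
    """Named feature vector of one window; columns ``channel__domain__feature``."""
    if len(w) == 0:
        raise ValueError("empty window")
    out: dict[str, float] = {}
    for ch in CHANNELS:
        x = w.samples[ch]
        ac = autocorrelate(x)
        for name, val in _stats(x).items():
            out[f"{ch}__raw__{name}"] = val
        for name, val in _crossing_features(x).items():
            out[f"{ch}__raw__{name}"] = val
        for name, val in _stats(ac).items():
            out[f"{ch}__ac__{name}"] = val
        for name, val in _crossing_features(ac).items():
            out[f"{ch}__ac__{name}"] = val
        freqs, pxx = sps.periodogram(x, fs=w.sample_rate, detrend="constant")
        pxx = pxx[freqs > 0]
        out[f"{ch}__spec__mean"] = float(np.mean(pxx)) if len(pxx) else 0.0
        out[f"{ch}__spec__median"] = float(np.median(pxx)) if len(pxx) else 0.0
    out["sma"] = float(
        np.mean(
            np.abs(w.samples["acc_x"]) + np.abs(w.samples["acc_y"]) + np.abs(w.samples["acc_z"])
        )
    )
    return out


def extract_features(windows: list[Window]) -> FeatureMatrix:
    """Raw (unnormalized) feature matrix for a list of windows."""
    if not windows:
        raise ValueError("no windows to extract features from")
    rows = [window_features(w) for w in windows]
    return FeatureMatrix(
        values=pd.DataFrame(rows),
        starts=np.array([w.start for w in windows]),
        ends=np.array([w.end for w in windows]),
        feature_set="raw",
    )


def normalize_minmax(features: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale every column to [-1, 1]; constant columns map to 0."""
    if len(features) < 2:
        raise ValueError("min-max scaling needs at least 2 rows")
    vals = features.values.to_numpy(float)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    # a numerically-constant column (span at floating-point noise level) must
    # map to 0, not have its jitter amplified to the full [-1, 1] range
    constant = span <= 1e-9 * np.maximum(np.maximum(np.abs(lo), np.abs(hi)), 1.0)
    span[constant] = 1.0
    scaled = 2.0 * (vals - lo) / span - 1.0
    scaled[:, constant] = 0.0
    return FeatureMatrix(
        values=pd.DataFrame(scaled, columns=features.values.columns),
        starts=features.starts.copy(),
        ends=features.ends.copy(),
        feature_set="NFS",
    )


def pca_reduce(nfs: FeatureMatrix, variance_kept: float = 0.95) -> FeatureMatrix:
    """Project the NFS onto the principal components retaining
    ``variance_kept`` of the total variance.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores deterministic across SVD backends.
    """
    if not 0 < variance_kept <= 1:
        raise ValueError(f"variance_kept must be in (0, 1], got {variance_kept}")
    if len(nfs) < 2:
        raise ValueError("PCA needs at least 2 rows")
    X = nfs.values.to_numpy(float)
    if np.allclose(X.var(axis=0), 0.0):
        # no variance to decompose: a single all-zero score column keeps the
        # degenerate case representable downstream
        return FeatureMatrix(
            values=pd.DataFrame(np.zeros((X.shape[0], 1)), columns=["pc1"]),
            starts=nfs.starts.copy(),
            ends=nfs.ends.copy(),
            feature_set="PCA",
        )
    n_components = variance_kept if variance_kept < 1 else min(X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(pca.components_.shape[0]),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    cols = [f"pc{i + 1}" for i in range(scores.shape[1])]
    return FeatureMatrix(
        values=pd.DataFrame(scores, columns=cols),
        starts=nfs.starts.copy(),
        ends=nfs.ends.copy(),
        feature_set="PCA",
    )
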