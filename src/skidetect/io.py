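"""Reading, writing and resampling of IMU recordings and label segments.

An :class:`IMURecording` is a timestamped six-channel inertial stream
(tri-axial accelerometer in m/s^2, tri-axial gyroscope in rad/s) in the
body (sensor) frame.  Activity labels are half-open ``[start, end)`` time
intervals carrying one of the two classes ``Skiing`` / ``Not_Skiing``.

File formats are plain comma-delimited text with a header row:

* recordings: ``time_s, acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z``
* segments:   ``start_s, end_s, label``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SKIING = "Skiing"
NOT_SKIING = "Not_Skiing"
LABELS = (SKIING, NOT_SKIING)

RECORDING_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]
SEGMENT_COLUMNS = ["start_s", "end_s", "label"]

#: significant digits used when writing floating point columns
_FLOAT_DIGITS = 9


class ParseError(ValueError):
    """Raised when a recording or segment file violates its contract."""


@dataclass
class IMURecording:
    """Six-channel body-frame inertial stream with per-sample timestamps.

    Parameters
    ----------
    timestamps : array of float, seconds, strictly increasing
    accel : (n, 3) array, m/s^2
    gyro : (n, 3) array, rad/s
    sample_rate : nominal sampling rate in Hz; if omitted it is estimated
        from the median timestep.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float = 0.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if n < 2:
            raise ParseError(f"recording needs at least 2 samples, got {n}")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ParseError(
                f"channel shape mismatch: {n} timestamps, accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ParseError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1} "
                f"(t={self.timestamps[bad[0] + 1]!r})"
            )
        if self.sample_rate <= 0:
            self.sample_rate = float(1.0 / np.median(dt))

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class ActivitySegment:
    """Half-open labeled time interval ``[start, end)``."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ParseError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not self.start < self.end:
            raise ParseError(f"segment start {self.start} must be < end {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start


def read_recording(path) -> IMURecording:
    """Read a recording CSV; the nominal rate is the median reciprocal timestep."""
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise ParseError(f"{path}: needs at least 2 data rows, got {len(df)}")
    if df[RECORDING_COLUMNS].isna().any().any():
        col = df[RECORDING_COLUMNS].isna().any().idxmax()
        raise ParseError(f"{path}: missing values in column {col!r}")
    return IMURecording(
        timestamps=df["time_s"].to_numpy(float),
        accel=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
        gyro=df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(float),
    )


def write_recording(recording: IMURecording, path) -> None:
    df = pd.DataFrame(
        np.column_stack([recording.timestamps, recording.accel, recording.gyro]),
        columns=RECORDING_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=f"%.{_FLOAT_DIGITS}g")


def read_segments(path) -> list[ActivitySegment]:
    df = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(ActivitySegment(float(row.start_s), float(row.end_s), str(row.label)))
        except ParseError as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return out


def write_segments(segments: list[ActivitySegment], path) -> None:
    df = pd.DataFrame(
        [(s.start, s.end, s.label) for s in segments], columns=SEGMENT_COLUMNS
    )
    df.to_csv(path, index=False, float_format=f"%.{_FLOAT_DIGITS}g")


def resample(recording: IMURecording, target_rate: float) -> IMURecording:
    """Resample to a uniform grid at ``target_rate`` by linear interpolation.

    Only downsampling (or re-gridding at the native rate) is supported; the
    pipeline's default operating rate is 50 Hz, well below typical phone IMU
    rates.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate > recording.sample_rate * (1 + 1e-9):
        raise ValueError(
            f"upsampling not supported: target {target_rate} Hz > "
            f"source {recording.sample_rate:.6g} Hz"
        )
    t0, t1 = recording.timestamps[0], recording.timestamps[-1]
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    ts = t0 + np.arange(n) / target_rate
    accel = np.column_stack(
        [np.interp(ts, recording.timestamps, recording.accel[:, i]) for i in range(3)]
    )
    gyro = np.column_stack(
        [np.interp(ts, recording.timestamps, recording.gyro[:, i]) for i in range(3)]
    )
    return IMURecording(ts, accel, gyro, sample_rate=float(target_rate))
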