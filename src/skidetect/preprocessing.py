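"""Two-stage smoothing of world-frame channels.

Pocket shake and snow-quality vibration sit well above the turn-oscillation
band (ski turns are at most ~1.5 Hz), so each channel is smoothed twice:
first a centered moving average keeps the persistent pattern, then a
zero-phase Butterworth low-pass removes whatever high-frequency content
survives.  Both stages have unit DC gain and preserve signal length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .orientation import WorldFrameRecording


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the two smoothing stages.

    ma_window : moving-average length in seconds (default 0.5 s).
    lp_cutoff : Butterworth cutoff in Hz (default 3 Hz: keeps turn
        frequencies <= 1.5 Hz, kills pocket-shake noise).
    lp_order : Butterworth order (default 4; applied forward-backward).
    """

    ma_window: float = 0.5
    lp_cutoff: float = 3.0
    lp_order: int = 4

    def __post_init__(self) -> None:
        if self.ma_window <= 0:
            raise ValueError(f"ma_window must be positive, got {self.ma_window}")
        if self.lp_cutoff <= 0:
            raise ValueError(f"lp_cutoff must be positive, got {self.lp_cutoff}")
        if self.lp_order < 1:
            raise ValueError(f"lp_order must be >= 1, got {self.lp_order}")


def moving_average(x: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Centered moving average; edges shrink to the available samples."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    x = np.asarray(x, dtype=float)
    k = max(int(round(window * rate)), 1)
    if k == 1:
        return x.copy()
    # sum over the centered window / number of in-range samples
    kernel_sum = ndimage.uniform_filter1d(x, size=k, mode="constant", cval=0.0) * k
    counts = ndimage.uniform_filter1d(np.ones_like(x), size=k, mode="constant", cval=0.0) * k
    return kernel_sum / counts


def low_pass(x: np.ndarray, cutoff: float, order: int, rate: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, unit DC gain)."""
    nyquist = rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must be in (0, {nyquist}) Hz, got {cutoff}")
    x = np.asarray(x, dtype=float)
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, padtype="even")


def two_stage_filter(recording: WorldFrameRecording, cfg: FilterConfig | None = None) -> WorldFrameRecording:
    """Apply moving average then low-pass to all six world-frame channels.

    The order matters (the stages do not commute); the moving average runs
    first on the raw world-frame signal.
    """
    cfg = cfg or FilterConfig()
    rate = recording.sample_rate

    def smooth(col: np.ndarray) -> np.ndarray:
        return low_pass(moving_average(col, cfg.ma_window, rate), cfg.lp_cutoff, cfg.lp_order, rate)

    accel = np.column_stack([smooth(recording.accel_world[:, i]) for i in range(3)])
    gyro = np.column_stack([smooth(recording.gyro[:, i]) for i in range(3)])
    return WorldFrameRecording(
        timestamps=recording.timestamps,
        accel_world=accel,
        gyro=gyro,
        sample_rate=rate,
    )
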