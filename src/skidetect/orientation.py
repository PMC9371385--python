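"""Quaternion orientation tracking and body-to-world rotation.

The phone's attitude is tracked with a complementary filter: the gyroscope
is integrated at every step (accurate over short horizons, drifts over long
ones) and the accelerometer, whose time average points along gravity, pulls
the tilt estimate back by a small fraction per step.  Rotating the
accelerometer stream into the resulting world frame isolates gravity on the
+Y axis and proper acceleration on X/Z, which makes the downstream feature
space invariant to how the phone sits in the pocket.

Conventions: Hamilton quaternion product, quaternions are world-from-body,
the world frame is Y-up.  Yaw (rotation about gravity) is unobservable from
accelerometer + gyroscope alone; the initial yaw is fixed to zero and yaw
drift is accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import IMURecording

log = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2, world gravity magnitude along +Y

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

#: default accelerometer-trust gain per filter step at the 50 Hz operating
#: rate; the slow-correction regime (time constant ~1 s).
DEFAULT_GAIN = 0.02


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ∘ b``, renormalized."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    out = np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )
    return quat_normalize(out)


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate 3-vector ``v`` by unit quaternion ``q`` (q v q*)."""
    w, x, y, z = q
    vx, vy, vz = v
    # t = 2 (q_vec x v); v' = v + w t + q_vec x t
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return np.array(
        [
            vx + w * tx + y * tz - z * ty,
            vy + w * ty + z * tx - x * tz,
            vz + w * tz + x * ty - y * tx,
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        return IDENTITY.copy()
    half = 0.5 * angle
    s = math.sin(half) / norm
    return np.array([math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s])


def integrate_gyro(q: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Advance world-from-body ``q`` by the body-frame rate ``omega`` over ``dt``."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    omega = np.asarray(omega, dtype=float)
    angle = float(np.linalg.norm(omega)) * dt
    if angle == 0.0:
        return quat_normalize(q)
    dq = quat_from_axis_angle(omega, angle)
    return quat_multiply(q, dq)


def tilt_correct(q: np.ndarray, accel_body: np.ndarray, gain: float) -> np.ndarray:
    """Pull ``q`` toward the attitude whose world-frame accel lies on +Y.

    The correction rotates by ``gain`` times the tilt angle about the axis
    perpendicular to both the measured world-frame acceleration and +Y.
    ``gain=0`` leaves ``q`` unchanged; ``gain=1`` aligns fully.  A zero
    acceleration sample carries no gravity information and is skipped.
    """
    accel_body = np.asarray(accel_body, dtype=float)
    norm = np.linalg.norm(accel_body)
    if norm == 0:
        log.warning("tilt_correct: zero acceleration sample, correction skipped")
        return quat_normalize(q)
    if gain == 0:
        return quat_normalize(q)
    a_world = quat_rotate(q, accel_body / norm)
    # axis = a_world x (0,1,0); cos(tilt) = a_world . (0,1,0)
    axis = np.array([-a_world[2], 0.0, a_world[0]])
    s = float(np.linalg.norm(axis))
    c = float(a_world[1])
    angle = math.atan2(s, c)
    if s < 1e-12:
        if c > 0:  # already aligned
            return quat_normalize(q)
        axis = np.array([1.0, 0.0, 0.0])  # antiparallel: axis is degenerate
        s = 1.0
    corr = quat_from_axis_angle(axis / s, gain * angle)
    return quat_multiply(corr, q)


def _initial_quaternion(accel0: np.ndarray) -> np.ndarray:
    """Attitude aligning the first accel sample with +Y (zero yaw)."""
    norm = np.linalg.norm(accel0)
    if norm == 0:
        return IDENTITY.copy()
    return tilt_correct(IDENTITY.copy(), accel0, gain=1.0)


@dataclass
class OrientationTrack:
    """Per-sample world-from-body unit quaternions, aligned with a recording."""

    quaternions: np.ndarray  # (n, 4)

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4)")

    def __len__(self) -> int:
        return len(self.quaternions)


@dataclass
class WorldFrameRecording:
    """Recording rotated into the gravity-aligned (Y-up) world frame.

    Acceleration channels are world-frame; the gyroscope is passed through
    unchanged (its windowed statistics are orientation-change robust enough
    for clustering, and angular rate has no preferred world decomposition
    without yaw).
    """

    timestamps: np.ndarray
    accel_world: np.ndarray
    gyro: np.ndarray
    sample_rate: float

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {
            "acc_x": self.accel_world[:, 0],
            "acc_y": self.accel_world[:, 1],
            "acc_z": self.accel_world[:, 2],
            "gyr_x": self.gyro[:, 0],
            "gyr_y": self.gyro[:, 1],
            "gyr_z": self.gyro[:, 2],
        }


def track_orientation(recording: IMURecording, gain: float = DEFAULT_GAIN) -> OrientationTrack:
    """Run the complementary filter over a recording.

    Each step integrates the gyroscope over the sample interval and then
    applies the accelerometer tilt correction with the given per-step gain.
    The initial quaternion aligns the accelerometer's gravity estimate with
    +Y (yaw = 0); the estimate averages the first 0.5 s of samples so a
    single noisy reading cannot seed a long convergence transient.
    """
    ts = recording.timestamps
    acc = recording.accel
    gyr = recording.gyro
    n = len(ts)
    out = np.empty((n, 4))

    k0 = min(max(int(round(0.5 * recording.sample_rate)), 1), n)
    q = _initial_quaternion(acc[:k0].mean(axis=0))
    out[0] = q
    # scalar inner loop: unpacked floats are ~10x faster than ndarray ops here
    qw, qx, qy, qz = q
    for k in range(1, n):
        dt = ts[k] - ts[k - 1]
        wx, wy, wz = gyr[k]
        angle = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
        if angle > 0.0:
            half = 0.5 * angle
            s = math.sin(half) / (angle / dt)  # = sin(half)/|omega|
            dw = math.cos(half)
            dx, dy, dz = wx * s, wy * s, wz * s
            qw, qx, qy, qz = (
                qw * dw - qx * dx - qy * dy - qz * dz,
                qw * dx + qx * dw + qy * dz - qz * dy,
                qw * dy - qx * dz + qy * dw + qz * dx,
                qw * dz + qx * dy - qy * dx + qz * dw,
            )
        ax, ay, az = acc[k]
        anorm = math.sqrt(ax * ax + ay * ay + az * az)
        if anorm > 0.0 and gain > 0.0:
            ax, ay, az = ax / anorm, ay / anorm, az / anorm
            # world-frame image of the (unit) accel sample
            tx = 2.0 * (qy * az - qz * ay)
            ty = 2.0 * (qz * ax - qx * az)
            tz = 2.0 * (qx * ay - qy * ax)
            awx = ax + qw * tx + qy * tz - qz * ty
            awy = ay + qw * ty + qz * tx - qx * tz
            awz = az + qw * tz + qx * ty - qy * tx
            cx, cz = -awz, awx  # correction axis = a_world x yhat
            s2 = math.sqrt(cx * cx + cz * cz)
            if s2 >= 1e-12:
                theta = gain * math.atan2(s2, awy)
                half = 0.5 * theta
                cs = math.sin(half) / s2
                cw = math.cos(half)
                cx, cz = cx * cs, cz * cs
                qw, qx, qy, qz = (
                    cw * qw - cx * qx - cz * qz,
                    cw * qx + cx * qw - cz * qy,
                    cw * qy - cx * qz + cz * qx,
                    cw * qz + cx * qy + cz * qw,
                )
        norm = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
        out[k, 0], out[k, 1], out[k, 2], out[k, 3] = qw, qx, qy, qz
    return OrientationTrack(out)


def to_world(recording: IMURecording, track: OrientationTrack) -> WorldFrameRecording:
    """Rotate acceleration into the world frame per sample; gyro passes through."""
    if len(track) != len(recording):
        raise ValueError(
            f"length mismatch: recording {len(recording)}, track {len(track)}"
        )
    q = track.quaternions
    v = recording.accel
    # vectorized q v q*
    w = q[:, 0:1]
    qv = q[:, 1:]
    t = 2.0 * np.cross(qv, v)
    accel_world = v + w * t + np.cross(qv, t)
    return WorldFrameRecording(
        timestamps=recording.timestamps,
        accel_world=accel_world,
        gyro=recording.gyro.copy(),
        sample_rate=recording.sample_rate,
    )
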