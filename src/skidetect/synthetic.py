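"""Synthetic IMU sessions with known ground truth.

A generated day-of-skiing session alternates gravity-dominated idle phases
(lift rides, standing around) with skiing runs that superpose periodic turn
oscillations — lateral and vertical proper acceleration in quadrature plus a
consistent body-roll angular rate — on rotated gravity.  The phone's
attitude can change abruptly mid-session (pocket re-insertion); each change
is realized as a fast 0.5 s rotation whose angular rate is written into the
gyroscope, so an orientation tracker sees exactly what a real IMU would.

The gyroscope channel is derived from the true attitude track by discrete
quaternion differencing, which makes the generated session kinematically
self-consistent: integrating the noiseless gyro reproduces the true
orientation to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import NOT_SKIING, SKIING, ActivitySegment, IMURecording
from .orientation import GRAVITY, IDENTITY, quat_normalize

#: duration of the smooth attitude transition realizing an orientation event
_EVENT_TRANSITION_S = 0.5

#: body-roll oscillation amplitude per unit of turn amplitude, rad/(m/s^2)
_ROLL_PER_AMPLITUDE = 0.1


@dataclass(frozen=True)
class RunSpec:
    """One skiing run: start time, duration and its turn oscillation."""

    start: float
    duration: float
    turn_frequency: float = 0.6  # Hz; short turns ~1-1.5 Hz, long ~0.3-0.5 Hz
    turn_amplitude: float = 3.0  # m/s^2 lateral proper-acceleration amplitude

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"run duration must be positive, got {self.duration}")
        if self.turn_frequency <= 0:
            raise ValueError(f"turn_frequency must be positive, got {self.turn_frequency}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class SessionSpec:
    """Layout of a synthetic session.

    ``orientation_events`` is a list of ``(time_s, quaternion)`` pairs: from
    that time on the phone sits in the new attitude (world-from-body).
    ``ramp_s`` > 0 adds linear amplitude ramps at run boundaries emulating
    semi-skiing transitions; off by default.
    """

    duration: float
    runs: tuple[RunSpec, ...] = ()
    idle_noise_sd: float = 0.3  # m/s^2
    run_noise_sd: float = 1.0  # m/s^2
    gyro_noise_sd: float = 0.02  # rad/s
    orientation_events: tuple[tuple[float, np.ndarray], ...] = ()
    initial_orientation: np.ndarray = field(default_factory=lambda: IDENTITY.copy())
    ramp_s: float = 0.0
    sample_rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        runs = tuple(r if isinstance(r, RunSpec) else RunSpec(*r) for r in self.runs)
        object.__setattr__(self, "runs", tuple(sorted(runs, key=lambda r: r.start)))
        prev_end = 0.0
        for r in self.runs:
            if r.start < prev_end:
                raise ValueError(
                    f"runs overlap or leave [0, duration): run at {r.start} s "
                    f"starts before {prev_end} s"
                )
            prev_end = r.end
        if prev_end > self.duration:
            raise ValueError("last run extends beyond the session duration")
        object.__setattr__(self, "initial_orientation", quat_normalize(self.initial_orientation))
        events = tuple(
            (float(t), quat_normalize(q)) for t, q in sorted(self.orientation_events)
        )
        object.__setattr__(self, "orientation_events", events)


# ---------------------------------------------------------------------------
# vectorized quaternion helpers (arrays of shape (n, 4))

def _qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def _qconj(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def _qrot(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    w = q[..., 0:1]
    qv = q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def _slerp(q0: np.ndarray, q1: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical interpolation between two unit quaternions, elementwise frac."""
    dot = float(np.dot(q0, q1))
    if dot < 0:
        q1 = -q1
        dot = -dot
    dot = min(dot, 1.0)
    theta = np.arccos(dot)
    if theta < 1e-10:
        out = q0[None, :] * (1 - frac[:, None]) + q1[None, :] * frac[:, None]
    else:
        s = np.sin(theta)
        out = (
            np.sin((1 - frac)[:, None] * theta) * q0[None, :]
            + np.sin(frac[:, None] * theta) * q1[None, :]
        ) / s
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _gyro_from_track(quats: np.ndarray, dt: float) -> np.ndarray:
    """Body angular rate whose step-wise integration reproduces ``quats``."""
    dq = _qmul(_qconj(quats[:-1]), quats[1:])
    neg = dq[:, 0] < 0
    dq[neg] *= -1.0
    vnorm = np.linalg.norm(dq[:, 1:], axis=1)
    angle = 2.0 * np.arctan2(vnorm, dq[:, 0])
    scale = np.zeros_like(vnorm)
    nz = vnorm > 1e-15
    scale[nz] = angle[nz] / (vnorm[nz] * dt)
    omega = dq[:, 1:] * scale[:, None]
    return np.vstack([omega, omega[-1:]])


def _base_orientation_track(spec: SessionSpec, t: np.ndarray) -> np.ndarray:
    """Piecewise attitude from orientation events, smoothed over 0.5 s."""
    quats = np.broadcast_to(spec.initial_orientation, (len(t), 4)).copy()
    prev = spec.initial_orientation
    for ev_time, ev_quat in spec.orientation_events:
        frac = np.clip((t - ev_time) / _EVENT_TRANSITION_S, 0.0, 1.0)
        active = frac > 0
        quats[active] = _slerp(prev, ev_quat, frac[active])
        prev = ev_quat
    return quats


def generate_session(spec: SessionSpec) -> tuple[IMURecording, list[ActivitySegment]]:
    """Generate a session and its ground-truth segments.

    The returned segments are exactly the run intervals labeled Skiing and
    their complement labeled Not_Skiing, partitioning ``[0, duration)``.
    Identical specs (including seed) produce bit-identical recordings.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    proper_world = np.zeros((n, 3))
    roll = np.zeros(n)
    noise_sd = np.full(n, spec.idle_noise_sd)
    in_run = np.zeros(n, dtype=bool)
    for run in spec.runs:
        mask = (t >= run.start) & (t < run.end)
        tau = t[mask] - run.start
        env = np.ones_like(tau)
        if spec.ramp_s > 0:
            env = np.minimum(env, np.minimum(tau, run.duration - tau) / spec.ramp_s)
            env = np.clip(env, 0.0, 1.0)
        phase = 2.0 * np.pi * run.turn_frequency * tau
        proper_world[mask, 0] = run.turn_amplitude * env * np.sin(phase)
        proper_world[mask, 1] = 0.5 * run.turn_amplitude * env * np.cos(phase)
        roll[mask] = _ROLL_PER_AMPLITUDE * run.turn_amplitude * env * np.sin(phase)
        noise_sd[mask] = spec.run_noise_sd
        in_run[mask] = True

    q_base = _base_orientation_track(spec, t)
    half = 0.5 * roll
    q_roll = np.column_stack(
        [np.cos(half), np.zeros(n), np.zeros(n), np.sin(half)]
    )  # roll about the body Z axis
    q_true = _qmul(q_base, q_roll)
    q_true /= np.linalg.norm(q_true, axis=1, keepdims=True)

    a_world = proper_world.copy()
    a_world[:, 1] += GRAVITY
    accel_body = _qrot(_qconj(q_true), a_world)
    accel_body += rng.normal(0.0, 1.0, size=(n, 3)) * noise_sd[:, None]

    gyro = _gyro_from_track(q_true, dt)
    if spec.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, spec.gyro_noise_sd, size=(n, 3))

    recording = IMURecording(t, accel_body, gyro, sample_rate=fs)
    segments = _segments_from_runs(spec)
    return recording, segments


def _segments_from_runs(spec: SessionSpec) -> list[ActivitySegment]:
    segments: list[ActivitySegment] = []
    cursor = 0.0
    for run in spec.runs:
        if run.start > cursor:
            segments.append(ActivitySegment(cursor, run.start, NOT_SKIING))
        segments.append(ActivitySegment(run.start, run.end, SKIING))
        cursor = run.end
    if cursor < spec.duration:
        segments.append(ActivitySegment(cursor, spec.duration, NOT_SKIING))
    return segments


def generate_static(
    orientation: np.ndarray,
    duration: float,
    sample_rate: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IMURecording:
    """Motionless recording of a phone held in a fixed attitude.

    ``orientation`` is the world-from-body unit quaternion; the accelerometer
    reads gravity rotated into the body frame plus white noise, the
    gyroscope is zero plus (small) noise when ``noise_sd`` > 0.
    """
    orientation = np.asarray(orientation, dtype=float)
    norm = np.linalg.norm(orientation)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"orientation must be a unit quaternion (norm {norm:.6g})")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    g_body = _qrot(_qconj(orientation[None, :]), np.array([[0.0, GRAVITY, 0.0]]))
    accel = np.repeat(g_body, n, axis=0)
    gyro = np.zeros((n, 3))
    if noise_sd > 0:
        accel = accel + rng.normal(0.0, noise_sd, size=(n, 3))
        gyro = gyro + rng.normal(0.0, 0.01, size=(n, 3))
    return IMURecording(t, accel, gyro, sample_rate=sample_rate)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def random_session_spec(
    seed: int,
    n_runs: int | None = None,
    sample_rate: float = 500.0,
) -> SessionSpec:
    """A plausible day-of-skiing session layout with 3-7 runs.

    Runs of 45-120 s (turn frequency 0.3-1.2 Hz) separated by 5-10 minute
    idle gaps (lift queue plus ride), a 1-3 minute lead-in and a ~1 minute
    tail, so skiing occupies roughly 10-15% of the session as in a real
    skiing day; with probability 1/2 one mid-gap phone re-orientation.
    """
    rng = np.random.default_rng(seed)
    if n_runs is None:
        n_runs = int(rng.integers(3, 8))
    cursor = float(rng.uniform(60.0, 180.0))
    runs = []
    events = []
    gap_mids = []
    for i in range(n_runs):
        duration = float(rng.uniform(45.0, 120.0))
        freq = float(rng.uniform(0.3, 1.2))
        runs.append(RunSpec(cursor, duration, turn_frequency=freq))
        cursor += duration
        if i < n_runs - 1:
            gap = float(rng.uniform(300.0, 600.0))
            gap_mids.append(cursor + gap / 2.0)
            cursor += gap
    total = cursor + float(rng.uniform(60.0, 120.0))
    if rng.random() < 0.5 and gap_mids:
        flip_time = float(rng.choice(gap_mids))
        events.append((flip_time, random_orientation(rng)))
    return SessionSpec(
        duration=total,
        runs=tuple(runs),
        orientation_events=tuple(events),
        initial_orientation=random_orientation(rng),
        sample_rate=sample_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
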