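"""Planar delivery-movement generators.

The receiver model observes the deliverer's hand as a uniformly sampled planar
path.  Two movement families are provided: spatial minimum-jerk reaches (the
stereotypical human profile, straight path with a bell-shaped speed curve) and
trapezoidal joint-velocity motions of a planar two-link arm (the industrial
robot profile, which produces curved end-effector paths).  Observation noise is
additive isotropic Gaussian per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Vec2 = tuple[float, float]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise ValueError("point components must be finite")
    return a


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar hand path.

    Attributes
    ----------
    times : (n,) seconds, strictly increasing, uniform spacing.
    positions : (n, 2) metres, columns (x, y).
    sampling_rate : Hz; spacing of ``times`` is ``1/sampling_rate``.
    """

    times: np.ndarray
    positions: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("times must be (n,), positions (n, 2)")
        if len(t) != len(p):
            raise ValueError("times and positions must have equal length")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-3, atol=1e-9):
            raise ValueError("sample spacing inconsistent with sampling_rate")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def prefix(self, n: int) -> "Trajectory":
        """First ``n`` samples as a trajectory (n >= 2)."""
        return Trajectory(self.times[:n], self.positions[:n], self.sampling_rate)


@dataclass(frozen=True)
class ArmGeometry:
    """Planar two-link arm: fixed base and two link lengths (metres)."""

    # base offset laterally like a shoulder: straight joint-space motion then
    # sweeps a visibly curved end-effector arc toward the table centre
    base: Vec2 = (-0.50, -0.35)
    link_lengths: tuple[float, float] = (0.45, 0.45)

    def __post_init__(self):
        if min(self.link_lengths) <= 0:
            raise ValueError("link lengths must be positive")


def min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5.

    Clamped to [0, 1] outside the movement interval, so it can be evaluated on
    times beyond a hypothesized duration (the movement has ended there).
    """
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _uniform_times(duration: float, rate: float) -> np.ndarray:
    n = int(round(duration * rate)) + 1
    n = max(n, 2)
    return np.linspace(0.0, duration, n)


def generate_min_jerk(start: Vec2, end: Vec2, duration: float, rate: float) -> Trajectory:
    """Straight-path minimum-jerk movement from ``start`` to ``end``.

    Position is start + (end - start) * s(t/T); speed peaks at 15/8 * d/T at
    mid-movement and is zero at both boundaries.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate <= 0:
        raise ValueError("rate must be positive")
    p0, p1 = _as_point(start), _as_point(end)
    t = _uniform_times(duration, rate)
    s = min_jerk_profile(t / duration)
    pos = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    return Trajectory(t, pos, (len(t) - 1) / duration)


def _trapezoid_profile(t: np.ndarray, duration: float, accel_fraction: float) -> np.ndarray:
    """Normalized position profile of a symmetric trapezoidal speed curve.

    Linear ramp over ``accel_fraction * duration``, constant cruise, mirrored
    ramp down; integrates to 1 over the movement.
    """
    ta = accel_fraction * duration
    v = 1.0 / (duration - ta)  # cruise speed of the normalized profile
    t = np.clip(np.asarray(t, dtype=float), 0.0, duration)
    s = np.empty_like(t)
    ramp_up = t <= ta
    ramp_down = t >= duration - ta
    cruise = ~(ramp_up | ramp_down)
    s[ramp_up] = 0.5 * v * t[ramp_up] ** 2 / ta
    s[cruise] = v * (t[cruise] - 0.5 * ta)
    s[ramp_down] = 1.0 - 0.5 * v * (duration - t[ramp_down]) ** 2 / ta
    return s


def forward_kinematics(arm: ArmGeometry, angles: np.ndarray) -> np.ndarray:
    """End-effector positions of a two-link arm for joint angles (n, 2) or (2,)."""
    q = np.atleast_2d(np.asarray(angles, dtype=float))
    l1, l2 = arm.link_lengths
    base = _as_point(arm.base)
    x = base[0] + l1 * np.cos(q[:, 0]) + l2 * np.cos(q[:, 0] + q[:, 1])
    y = base[1] + l1 * np.sin(q[:, 0]) + l2 * np.sin(q[:, 0] + q[:, 1])
    out = np.column_stack([x, y])
    return out[0] if np.asarray(angles).ndim == 1 else out


def inverse_kinematics(arm: ArmGeometry, target: Vec2, elbow_up: bool = True) -> np.ndarray:
    """Joint angles reaching ``target`` (elbow-up by default).

    Raises ValueError for unreachable targets.
    """
    p = _as_point(target) - _as_point(arm.base)
    l1, l2 = arm.link_lengths
    r2 = float(p @ p)
    c2 = (r2 - l1**2 - l2**2) / (2 * l1 * l2)
    if not -1.0 <= c2 <= 1.0:
        raise ValueError(f"target {target} unreachable by arm {arm}")
    q2 = np.arccos(c2)
    if elbow_up:
        q2 = -q2
    q1 = np.arctan2(p[1], p[0]) - np.arctan2(l2 * np.sin(q2), l1 + l2 * np.cos(q2))
    return np.array([q1, q2])


def generate_trapezoid_joint(
    arm: ArmGeometry,
    start_angles,
    end_angles,
    duration: float,
    accel_fraction: float = 0.2,
    rate: float = 100.0,
) -> Trajectory:
    """End-effector path of a two-link arm moving each joint with a symmetric
    trapezoidal angular-speed profile.

    Joint interpolation is straight in joint space, so the Cartesian path is
    curved whenever start and end poses are not collinear with the base.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if not 0.0 < accel_fraction <= 0.5:
        raise ValueError("accel_fraction must lie in (0, 0.5]")
    q0 = np.asarray(start_angles, dtype=float).reshape(2)
    q1 = np.asarray(end_angles, dtype=float).reshape(2)
    t = _uniform_times(duration, rate)
    s = _trapezoid_profile(t, duration, accel_fraction)
    q = q0[None, :] + s[:, None] * (q1 - q0)[None, :]
    pos = forward_kinematics(arm, q)
    return Trajectory(t, pos, (len(t) - 1) / duration)


def add_observation_noise(traj: Trajectory, sigma: float, seed) -> Trajectory:
    """Perturb positions with i.i.d. zero-mean isotropic Gaussian noise.

    ``seed`` may be an int or a ``numpy.random.Generator``; sigma is the
    per-axis standard deviation in metres.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return traj
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = traj.positions + rng.normal(0.0, sigma, size=traj.positions.shape)
    return Trajectory(traj.times, noisy, traj.sampling_rate)
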