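"""Data-reduction rules for motion-capture handover recordings.

Operational definitions used on recorded (or synthetic) hand paths:

* positions are low-pass filtered with a Gaussian kernel whose -3 dB point is
  the stated cutoff (48 Hz for 240 Hz magnetic-tracker data, 10 Hz for 20 Hz
  acoustic-tracker data);
* the receiver's movement onset is the first sample whose speed reaches
  0.01 m/s;
* the deliverer's movement onset (start of the cube transport) is the first
  local speed minimum after grasping the cube at which the speed is below
  0.3 m/s;
* reaction time is receiver onset minus deliverer onset;
* an online correction is flagged when a reach's speed profile has two or more
  prominent local maxima or an overlong deceleration phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .trajectories import Trajectory

__all__ = [
    "HandoverRecording",
    "OnsetNotFoundError",
    "gaussian_lowpass",
    "default_cutoff",
    "speed",
    "detect_receiver_onset",
    "detect_deliverer_onset",
    "reaction_time",
    "detect_online_correction",
    "rt_slope",
    "RECEIVER_ONSET_SPEED",
    "DELIVERER_ONSET_SPEED",
]

RECEIVER_ONSET_SPEED = 0.01  # m/s
DELIVERER_ONSET_SPEED = 0.3  # m/s


class OnsetNotFoundError(RuntimeError):
    """Raised when an onset rule never fires on a trace."""


@dataclass(frozen=True)
class HandoverRecording:
    """Paired deliverer/receiver trajectories sharing a time origin.

    ``annotations`` may carry ground-truth event times (seconds): grasp_time,
    deliverer_onset, receiver_onset, handover_time, reaction_time.
    """

    deliverer: Trajectory
    receiver: Trajectory
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        span = (
            min(self.deliverer.times[0], self.receiver.times[0]),
            max(self.deliverer.times[-1], self.receiver.times[-1]),
        )
        for key, value in self.annotations.items():
            if key.endswith("_time") or key.endswith("_onset"):
                if not span[0] <= value <= span[1]:
                    raise ValueError(f"annotation {key}={value} outside recorded span {span}")


def default_cutoff(rate: float) -> float:
    """Filter cutoff by tracker class: 48 Hz for fast (>=100 Hz) data, 10 Hz otherwise."""
    return 48.0 if rate >= 100.0 else 10.0


def gaussian_lowpass(traj: Trajectory, cutoff: float) -> Trajectory:
    """Gaussian low-pass filter with its -3 dB frequency at ``cutoff``.

    The Gaussian kernel's transfer function is exp(-2 pi^2 sigma_t^2 f^2);
    solving for half power gives sigma_t = sqrt(ln 2) / (2 pi cutoff).
    Reflective boundary handling, length preserved.
    """
    if not 0 < cutoff <= traj.sampling_rate / 2:
        raise ValueError(f"cutoff must lie in (0, Nyquist]; got {cutoff}")
    sigma_samples = np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff) * traj.sampling_rate
    filtered = gaussian_filter1d(traj.positions, sigma_samples, axis=0, mode="reflect")
    return Trajectory(traj.times, filtered, traj.sampling_rate)


def speed(traj: Trajectory) -> np.ndarray:
    """Per-sample planar speed (m/s): central differences, one-sided at the ends."""
    v = np.gradient(traj.positions, traj.times, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def detect_receiver_onset(traj: Trajectory) -> float:
    """Time of the first sample whose speed reaches the 0.01 m/s threshold."""
    s = speed(traj)
    idx = np.flatnonzero(s >= RECEIVER_ONSET_SPEED)
    if len(idx) == 0:
        raise OnsetNotFoundError("receiver speed never reached 0.01 m/s")
    return float(traj.times[idx[0]])


def _local_minima(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Indices that are minima of their centered ``window``; ties to the earliest."""
    half = window // 2
    n = len(values)
    out = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = values[lo:hi]
        if values[i] <= w.min() and i - lo == int(np.argmin(w)):
            out.append(i)
    return np.asarray(out, dtype=int)


def detect_deliverer_onset(traj: Trajectory, grasp_time: float) -> float:
    """Start of the cube transport: first local speed minimum after the grasp
    at which the speed is below 0.3 m/s."""
    if not traj.times[0] <= grasp_time <= traj.times[-1]:
        raise ValueError("grasp_time outside the recorded span")
    s = speed(traj)
    candidates = _local_minima(s)
    for i in candidates:
        if traj.times[i] >= grasp_time and s[i] < DELIVERER_ONSET_SPEED:
            return float(traj.times[i])
    raise OnsetNotFoundError("no qualifying speed minimum after the grasp")


def reaction_time(
    rec: HandoverRecording,
    grasp_time: float | None = None,
    cutoff: float | None = None,
) -> float:
    """Receiver onset minus deliverer onset on the filtered recording.

    ``grasp_time`` defaults to the recording's annotation.  A negative value is
    returned as-is with a warning (the receiver anticipated the delivery).
    """
    if grasp_time is None:
        grasp_time = rec.annotations["grasp_time"]
    c_d = cutoff if cutoff is not None else default_cutoff(rec.deliverer.sampling_rate)
    c_r = cutoff if cutoff is not None else default_cutoff(rec.receiver.sampling_rate)
    t_d = detect_deliverer_onset(gaussian_lowpass(rec.deliverer, c_d), grasp_time)
    t_r = detect_receiver_onset(gaussian_lowpass(rec.receiver, c_r))
    rt = t_r - t_d
    if rt < 0:
        warnings.warn("receiver onset precedes deliverer onset", stacklevel=2)
    return float(rt)


def detect_online_correction(
    receiver_speed: np.ndarray,
    rel_peak_height: float = 0.2,
    max_decel_fraction: float = 0.65,
    min_prominence: float = 0.05,
) -> bool:
    """Flag a reach whose speed profile suggests mid-flight re-aiming.

    True when the onset-to-stop segment has two or more local maxima above
    ``rel_peak_height`` of the global peak, or its deceleration phase (global
    peak to stop) exceeds ``max_decel_fraction`` of the movement duration.
    A maximum only counts if it rises by at least ``min_prominence`` of the
    global peak above its surroundings, so measurement ripple on a single
    bell is not mistaken for a second submovement.
    """
    s = np.asarray(receiver_speed, dtype=float)
    if len(s) < 5:
        raise ValueError("need at least 5 samples of one reaching movement")
    peak = float(s.max())
    if peak <= 0:
        return False
    peaks, _ = find_peaks(s, height=rel_peak_height * peak, prominence=min_prominence * peak)
    # a profile ending on a rise has its maximum at the boundary
    if len(peaks) >= 2:
        return True
    decel_fraction = (len(s) - 1 - int(np.argmax(s))) / (len(s) - 1)
    return decel_fraction > max_decel_fraction


def rt_slope(rts) -> float:
    """Ordinary least-squares slope (s/trial) of six reaction times vs trial 1..6."""
    r = np.asarray(rts, dtype=float)
    if r.shape != (6,):
        raise ValueError("expected exactly 6 reaction times")
    x = np.arange(1, 7, dtype=float)
    x = x - x.mean()
    return float((r @ x) / (x @ x))
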