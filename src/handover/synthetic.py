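"""Synthetic motion-capture recordings of handover dyads.

Emulates what the trackers would record during one handover so that every
data-reduction rule can be exercised round-trip against known ground truth.

Deliverer: three superposed minimum-jerk segments — reach to the cube,
transport to the handover position, and lowering the hand back to the table —
producing exactly three speed peaks.  The reach and transport are blended over
a short velocity overlap instead of a full-stop dwell: the transport-onset rule
("first speed minimum after grasping the cube") needs a well-defined dip, and
a flat zero-speed pause has no unique minimum once observation noise is added.
A genuine dwell is kept at the handover itself, before the hand is lowered.

Receiver: stationary, then a minimum-jerk reach to the handover position timed
so that its 0.01 m/s onset-rule crossing occurs exactly ``reaction_time``
after the deliverer's transport-onset dip, a dwell while grasping, and a
transport to the placement row.

Annotations store the operational-definition event times measured on the
noiseless recording, so extracted and annotated quantities are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .kinematics import (
    HandoverRecording,
    RECEIVER_ONSET_SPEED,
    default_cutoff,
    detect_deliverer_onset,
    detect_receiver_onset,
    gaussian_lowpass,
)
from .trajectories import Trajectory

__all__ = ["HandoverScenario", "generate_recording", "generate_cohort"]


@dataclass(frozen=True)
class HandoverScenario:
    """Ground-truth layout and timing of one synthetic handover.

    Durations in seconds, positions in metres (same frame as the simulator:
    origin at the table centre, cube row at y = -0.25, placement row at
    y = +0.25).
    """

    handover_position: tuple[float, float] = (0.0, 0.0)
    reaction_time: float = 0.4
    deliverer_rest: tuple[float, float] = (0.0, -0.35)
    receiver_rest: tuple[float, float] = (0.0, 0.35)
    placement_position: tuple[float, float] = (0.05, 0.25)
    lead_in: float = 0.2
    reach_duration: float = 0.5
    transport_duration: float = 1.0
    lower_duration: float = 0.5
    receiver_reach_duration: float = 1.0
    receiver_transport_duration: float = 0.8
    grasp_overlap: float = 0.10
    handover_dwell: float = 0.15
    sampling_rate: float = 240.0
    noise_sigma: float = 3e-6

    def __post_init__(self):
        durations = (
            self.reach_duration,
            self.transport_duration,
            self.lower_duration,
            self.receiver_reach_duration,
            self.receiver_transport_duration,
            self.sampling_rate,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("durations and sampling rate must be positive")
        if self.reaction_time < 0:
            raise ValueError("reaction_time must be non-negative")
        if not 0 < self.grasp_overlap < self.reach_duration:
            raise ValueError("grasp_overlap must be positive and shorter than the reach")


def _segment(times, start_t, duration, displacement):
    """Displacement contribution of one minimum-jerk segment starting at start_t."""
    tau = np.clip((times - start_t) / duration, 0.0, 1.0)
    s = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    return s[:, None] * np.asarray(displacement, dtype=float)[None, :]


def _onset_rule_delay(distance: float, duration: float) -> float:
    """Time after movement start at which a minimum-jerk reach hits the 0.01 m/s rule."""
    peak = 1.875 * distance / duration
    if peak <= RECEIVER_ONSET_SPEED:
        raise ValueError("reach too slow to ever cross the onset threshold")

    def f(tau):
        return 30.0 * tau**2 * (1 - tau) ** 2 * distance / duration - RECEIVER_ONSET_SPEED

    return duration * brentq(f, 0.0, 0.5)


def generate_recording(scenario: HandoverScenario, seed: int = 0) -> HandoverRecording:
    """One synthetic paired recording with annotated ground-truth event times.

    Deterministic given the seed; additive isotropic Gaussian observation
    noise of ``scenario.noise_sigma`` per axis.
    """
    sc = scenario
    rate = sc.sampling_rate
    rest_d = np.asarray(sc.deliverer_rest, dtype=float)
    handover = np.asarray(sc.handover_position, dtype=float)
    cube = np.array([handover[0], -0.25])

    t_reach = sc.lead_in
    grasp_time = t_reach + sc.reach_duration - sc.grasp_overlap  # blend start
    t_transport = grasp_time
    handover_time = t_transport + sc.transport_duration
    t_lower = handover_time + sc.handover_dwell
    lower_target = rest_d + np.array([0.05, 0.0])

    # build the deliverer first so the transport-onset dip can be measured
    total_guess = t_lower + sc.lower_duration + 0.2
    n = int(np.ceil(total_guess * rate)) + 1
    times = np.arange(n) / rate
    pos_d = (
        rest_d[None, :]
        + _segment(times, t_reach, sc.reach_duration, cube - rest_d)
        + _segment(times, t_transport, sc.transport_duration, handover - cube)
        + _segment(times, t_lower, sc.lower_duration, lower_target - handover)
    )
    clean_d = Trajectory(times, pos_d, rate)
    filtered = gaussian_lowpass(clean_d, default_cutoff(rate))
    deliverer_onset = detect_deliverer_onset(filtered, grasp_time)

    # schedule the receiver reach so its onset-rule crossing lands at the
    # annotated reaction time after the deliverer's transport-onset dip
    rest_r = np.asarray(sc.receiver_rest, dtype=float)
    reach_dist = float(np.linalg.norm(handover - rest_r))
    delay = _onset_rule_delay(reach_dist, sc.receiver_reach_duration)
    receiver_onset = deliverer_onset + sc.reaction_time
    t_recv_reach = receiver_onset - delay
    if t_recv_reach < times[0]:
        raise ValueError("reaction time too short for the configured lead-in")
    t_recv_transport = t_recv_reach + sc.receiver_reach_duration + sc.handover_dwell
    placement = np.asarray(sc.placement_position, dtype=float)

    end = max(times[-1], t_recv_transport + sc.receiver_transport_duration + 0.2)
    n = int(np.ceil(end * rate)) + 1
    times = np.arange(n) / rate
    pos_d = (
        rest_d[None, :]
        + _segment(times, t_reach, sc.reach_duration, cube - rest_d)
        + _segment(times, t_transport, sc.transport_duration, handover - cube)
        + _segment(times, t_lower, sc.lower_duration, lower_target - handover)
    )
    pos_r = (
        rest_r[None, :]
        + _segment(times, t_recv_reach, sc.receiver_reach_duration, handover - rest_r)
        + _segment(times, t_recv_transport, sc.receiver_transport_duration, placement - handover)
    )

    # annotations carry the operational event definitions, measured on the
    # clean sampled traces, so extracted quantities are directly comparable
    clean_r = Trajectory(times, pos_r, rate)
    receiver_onset_op = detect_receiver_onset(gaussian_lowpass(clean_r, default_cutoff(rate)))

    rng = np.random.default_rng(seed)
    if sc.noise_sigma > 0:
        pos_d = pos_d + rng.normal(0.0, sc.noise_sigma, pos_d.shape)
        pos_r = pos_r + rng.normal(0.0, sc.noise_sigma, pos_r.shape)

    annotations = {
        "grasp_time": float(grasp_time),
        "deliverer_onset": float(deliverer_onset),
        "receiver_onset": float(receiver_onset_op),
        "handover_time": float(handover_time),
        "reaction_time": float(receiver_onset_op - deliverer_onset),
    }
    return HandoverRecording(
        Trajectory(times, pos_d, rate), Trajectory(times, pos_r, rate), annotations
    )


def generate_cohort(
    n_pairs: int,
    rt_mean: float = 0.4,
    rt_sd: float = 0.1,
    template: HandoverScenario | None = None,
    seed: int = 0,
) -> list[HandoverRecording]:
    """Recordings for ``n_pairs`` dyads with reaction times drawn from a
    truncated-at-zero Gaussian; reproducible given the seed."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    if rt_sd < 0:
        raise ValueError("rt_sd must be non-negative")
    template = template or HandoverScenario()
    rng = np.random.default_rng(seed)
    if rt_sd == 0:
        rts = np.full(n_pairs, rt_mean)
    else:
        a = (0.0 - rt_mean) / rt_sd
        rts = truncnorm.rvs(a, np.inf, loc=rt_mean, scale=rt_sd, size=n_pairs, random_state=rng)
    seeds = rng.integers(0, 2**31 - 1, size=n_pairs)
    return [
        generate_recording(replace(template, reaction_time=float(rt)), seed=int(s))
        for rt, s in zip(rts, seeds)
    ]
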