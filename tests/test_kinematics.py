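import numpy as np
import pytest

from handover.kinematics import (
    HandoverRecording,
    OnsetNotFoundError,
    detect_deliverer_onset,
    detect_online_correction,
    detect_receiver_onset,
    gaussian_lowpass,
    reaction_time,
    rt_slope,
    speed,
)
from handover.trajectories import Trajectory, generate_min_jerk


def sinusoid(freq, rate=240.0, duration=2.0, amp=0.01):
    t = np.arange(int(duration * rate)) / rate
    pos = np.column_stack([amp * np.sin(2 * np.pi * freq * t), np.zeros_like(t)])
    return Trajectory(t, pos, rate)


class TestGaussianLowpass:
    def test_dc_gain_is_one(self):
        t = np.arange(200) / 240.0
        traj = Trajectory(t, np.tile([0.1, -0.2], (200, 1)), 240.0)
        out = gaussian_lowpass(traj, 48.0)
        np.testing.assert_allclose(out.positions, traj.positions, atol=1e-12)

    def test_minus_3db_at_cutoff(self):
        traj = sinusoid(48.0)
        out = gaussian_lowpass(traj, 48.0)
        # steady-state amplitude ratio away from the edges
        sl = slice(100, -100)
        ratio = out.positions[sl, 0].std() / traj.positions[sl, 0].std()
        assert ratio == pytest.approx(0.708, abs=0.01)

    def test_strong_attenuation_at_4x_cutoff(self):
        traj = sinusoid(48.0, rate=480.0)
        out = gaussian_lowpass(traj, 12.0)
        sl = slice(200, -200)
        ratio = out.positions[sl, 0].std() / traj.positions[sl, 0].std()
        assert ratio < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(sinusoid(10.0), 200.0)


class TestSpeed:
    def test_uniform_linear_motion(self):
        t = np.arange(100) / 100.0
        pos = np.column_stack([0.2 * t, np.zeros_like(t)])
        s = speed(Trajectory(t, pos, 100.0))
        np.testing.assert_allclose(s, 0.2, atol=1e-9)

    def test_stationary_is_zero(self):
        t = np.arange(50) / 100.0
        s = speed(Trajectory(t, np.ones((50, 2)), 100.0))
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_min_jerk_peak_speed(self):
        tr = generate_min_jerk((0, -0.25), (0, 0), 1.0, 100)
        assert speed(tr).max() == pytest.approx(0.46875, abs=0.002)


class TestOnsets:
    def test_receiver_onset_threshold_crossing(self):
        # stationary for 0.5 s then a reach; onset is the first sample at >= 0.01 m/s
        rate = 240.0
        t = np.arange(int(2.0 * rate)) / rate
        reach = generate_min_jerk((0, 0), (0, 0.35), 1.0, rate)
        pos = np.zeros((len(t), 2))
        i0 = int(0.5 * rate)
        n = min(len(t) - i0, reach.n_samples)
        pos[i0 : i0 + n] = reach.positions[:n]
        pos[i0 + n :] = reach.positions[-1]
        traj = Trajectory(t, pos, rate)
        onset = detect_receiver_onset(traj)
        s = speed(traj)
        expected = t[np.flatnonzero(s >= 0.01)[0]]
        assert onset == expected
        assert 0.5 < onset < 0.6

    def test_receiver_onset_not_found_on_stationary(self):
        t = np.arange(100) / 240.0
        with pytest.raises(OnsetNotFoundError):
            detect_receiver_onset(Trajectory(t, np.zeros((100, 2)), 240.0))

    def test_receiver_moving_from_first_sample(self):
        t = np.arange(100) / 100.0
        pos = np.column_stack([0.2 * t, np.zeros_like(t)])
        assert detect_receiver_onset(Trajectory(t, pos, 100.0)) == t[0]

    def dip_trajectory(self, dip_t=1.0, rate=240.0):
        """Speed decreasing to a clear minimum at dip_t, then rising."""
        t = np.arange(int(2.0 * rate)) / rate
        # position with speed |t - dip_t| * a + small floor -> V-shaped speed
        a = 0.5
        x = np.where(
            t < dip_t,
            -0.5 * a * (dip_t - t) ** 2,
            0.5 * a * (t - dip_t) ** 2,
        )
        pos = np.column_stack([x, np.zeros_like(t)])
        return Trajectory(t, pos, rate)

    def test_deliverer_onset_finds_annotated_dip(self):
        traj = self.dip_trajectory(dip_t=1.0)
        onset = detect_deliverer_onset(traj, grasp_time=0.5)
        assert abs(onset - 1.0) <= 1.0 / 240.0

    def test_deliverer_onset_requires_slow_speed(self):
        t = np.arange(200) / 240.0
        pos = np.column_stack([0.5 * t, np.zeros_like(t)])  # 0.5 m/s throughout
        with pytest.raises(OnsetNotFoundError):
            detect_deliverer_onset(Trajectory(t, pos, 240.0), grasp_time=0.1)

    def test_first_of_two_qualifying_minima_wins(self):
        rate = 240.0
        t = np.arange(int(3.0 * rate)) / rate
        x = 0.02 * (np.cos(2 * np.pi * 1.0 * t) - 1)  # speed minima at t = 1, 2
        traj = Trajectory(t, np.column_stack([x, np.zeros_like(t)]), rate)
        onset = detect_deliverer_onset(traj, grasp_time=0.6)
        assert abs(onset - 1.0) <= 2.0 / rate


class TestReactionTime:
    def test_round_trip_against_annotations(self):
        from handover.synthetic import HandoverScenario, generate_recording

        rec = generate_recording(HandoverScenario(reaction_time=0.40), seed=3)
        rt = reaction_time(rec)
        assert abs(rt - rec.annotations["reaction_time"]) <= 1.5 / 240.0

    def test_negative_reaction_time_warns(self):
        # receiver starts moving before the deliverer's dip
        rate = 240.0
        t = np.arange(int(2.0 * rate)) / rate
        a = 0.5
        dip = 1.5
        x = np.where(t < dip, -0.5 * a * (dip - t) ** 2, 0.5 * a * (t - dip) ** 2)
        deliverer = Trajectory(t, np.column_stack([x, np.zeros_like(t)]), rate)
        reach = generate_min_jerk((0, 0.35), (0, 0), 1.0, rate)
        pos_r = np.vstack([reach.positions, np.tile(reach.positions[-1], (len(t) - reach.n_samples, 1))])
        receiver = Trajectory(t, pos_r[: len(t)], rate)
        rec = HandoverRecording(deliverer, receiver, {"grasp_time": 0.5})
        with pytest.warns(UserWarning):
            rt = reaction_time(rec)
        assert rt < 0


class TestOnlineCorrection:
    def bell(self, n=100):
        tau = np.linspace(0, 1, n)
        return 30 * tau**2 * (1 - tau) ** 2

    def test_single_reach_not_flagged(self):
        assert not detect_online_correction(self.bell())

    def test_double_submovement_flagged(self):
        s = np.concatenate([self.bell(), 0.8 * self.bell()])
        assert detect_online_correction(s)

    def test_monotone_ramp_not_flagged(self):
        assert not detect_online_correction(np.linspace(0, 1, 50))

    def test_long_deceleration_flagged(self):
        s = np.concatenate([np.linspace(0, 1, 20), np.linspace(1, 0, 80)])
        assert detect_online_correction(s)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            detect_online_correction(np.array([0.1, 0.2, 0.3]))


class TestRtSlope:
    def test_exact_decline(self):
        rts = 0.5 - 0.02 * np.arange(6)
        assert rt_slope(rts) == pytest.approx(-0.02)

    def test_constant(self):
        assert rt_slope([0.3] * 6) == pytest.approx(0.0)

    def test_hand_computed_ols(self):
        assert rt_slope([0.6, 0.4, 0.5, 0.3, 0.4, 0.2]) == pytest.approx(-2.2 / 35)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            rt_slope([0.1, 0.2, 0.3])
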