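import numpy as np
import pytest

from handover.bayes import (
    NATURAL,
    UNNATURAL,
    GaussianBelief,
    ModelParams,
    case_posterior,
    decision_value,
    fuse_map,
    run_trial,
    trial_trace,
)
from handover.endpoint import EndpointEstimate, EndpointSearchConfig, fit_endpoint, lookup_covariance
from handover.trajectories import add_observation_noise, generate_min_jerk


def est(mean, cov, frac=0.5):
    return EndpointEstimate(np.asarray(mean, float), frac, 1.0, np.asarray(cov, float))


def prior_at(mean, var=1e-4):
    return GaussianBelief(np.asarray(mean, float), np.diag([var, var]))


class TestCasePosterior:
    def test_matching_estimate_is_confidently_natural(self, params):
        p = case_posterior(est([0, 0], np.diag([5e-5, 5e-5])), prior_at([0, 0], 5e-5), params)
        assert p.p_natural > 0.99
        assert p.case == NATURAL

    def test_displaced_estimate_is_confidently_unnatural(self, params):
        p = case_posterior(est([0.20, 0], np.diag([5e-5, 5e-5])), prior_at([0, 0], 5e-5), params)
        assert p.p_natural < 0.01
        assert p.case == UNNATURAL

    def test_tie_resolves_to_unnatural(self):
        # choose the combined covariance so the Gaussian density at the mean
        # equals the uniform density: sqrt(det) = area / (2 pi)
        params = ModelParams(case_prior_natural=0.5)
        v = params.support_area / (2 * np.pi)  # sqrt(det) of the diagonal sum
        p = case_posterior(est([0, 0], np.diag([v / 2, v / 2])), prior_at([0, 0], v / 2), params)
        assert p.p_natural == pytest.approx(0.5, abs=1e-12)
        assert p.case == UNNATURAL

    def test_numerical_integration_oracle(self, params):
        """Closed-form marginal matches explicit integration over the hypothesized
        handover position on a fine lattice."""
        prior = GaussianBelief([0.02, -0.01], np.diag([0.002, 0.001]))
        for mean, cov in [
            ([0.0, 0.0], np.diag([0.004, 0.002])),
            ([0.15, 0.05], np.diag([0.001, 0.003])),
        ]:
            e = est(mean, cov)
            closed = case_posterior(e, prior, params).p_natural

            xs = np.linspace(-0.5, 0.5, 200)
            ys = np.linspace(-0.4, 0.4, 200)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            dx, dy = xs[1] - xs[0], ys[1] - ys[0]

            def gauss(px, py, mu, c):
                det = c[0, 0] * c[1, 1]
                q = (px - mu[0]) ** 2 / c[0, 0] + (py - mu[1]) ** 2 / c[1, 1]
                return np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))

            like_n = np.sum(
                gauss(X, Y, e.mean, e.covariance) * gauss(X, Y, prior.mean, prior.covariance)
            ) * dx * dy
            u = 1.0 / params.support_area
            x0, x1, y0, y1 = params.uniform_support
            inside = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
            like_un = np.sum(gauss(X, Y, e.mean, e.covariance) * u * inside) * dx * dy
            a = params.case_prior_natural * like_n
            b = (1 - params.case_prior_natural) * like_un
            assert abs(closed - a / (a + b)) <= 1e-3


class TestFusion:
    def test_equal_precisions_give_midpoint(self):
        e = est([0.1, 0.0], np.diag([1e-3, 1e-3]))
        pr = GaussianBelief([0.0, 0.1], np.diag([1e-3, 1e-3]))
        fused = fuse_map(NATURAL, e, pr)
        np.testing.assert_allclose(fused.mean, [0.05, 0.05], atol=1e-12)

    def test_unnatural_case_reduces_to_estimate(self):
        e = est([0.1, -0.2], np.diag([3e-3, 2e-3]))
        fused = fuse_map(UNNATURAL, e, prior_at([0, 0]))
        np.testing.assert_array_equal(fused.mean, e.mean)
        np.testing.assert_array_equal(fused.covariance, e.covariance)

    def test_fusion_never_increases_averaged_variance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(1e-4, 5e-3, 2)
            b = rng.uniform(1e-4, 5e-3, 2)
            e = est(rng.normal(0, 0.1, 2), np.diag(a))
            pr = GaussianBelief(rng.normal(0, 0.1, 2), np.diag(b))
            fused = fuse_map(NATURAL, e, pr)
            assert fused.averaged_variance <= min(np.mean(a), np.mean(b)) + 1e-15

    def test_grid_argmax_oracle(self):
        """Fused mean coincides with the argmax of the gridded density product."""
        e = est([0.06, -0.03], np.diag([2e-3, 1e-3]))
        pr = GaussianBelief([0.0, 0.0], np.diag([1e-3, 2e-3]))
        fused = fuse_map(NATURAL, e, pr)
        xs = np.linspace(-0.1, 0.15, 251)
        ys = np.linspace(-0.1, 0.1, 201)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        logp = -0.5 * (
            (X - e.mean[0]) ** 2 / e.covariance[0, 0]
            + (Y - e.mean[1]) ** 2 / e.covariance[1, 1]
            + (X - pr.mean[0]) ** 2 / pr.covariance[0, 0]
            + (Y - pr.mean[1]) ** 2 / pr.covariance[1, 1]
        )
        i, j = np.unravel_index(np.argmax(logp), logp.shape)
        cell = max(xs[1] - xs[0], ys[1] - ys[0])
        assert abs(fused.mean[0] - xs[i]) <= cell
        assert abs(fused.mean[1] - ys[j]) <= cell


class TestDecisionValue:
    def test_identity(self):
        assert decision_value(np.eye(2)) == 1.0

    def test_arithmetic(self):
        assert decision_value(np.diag([0.004, 0.002])) == pytest.approx(0.003)

    def test_rotation_invariance(self):
        cov = np.diag([0.004, 0.001])
        for angle in (0.3, 1.1, 2.0):
            c, s = np.cos(angle), np.sin(angle)
            R = np.array([[c, -s], [s, c]])
            assert decision_value(R @ cov @ R.T) == pytest.approx(decision_value(cov))

    def test_equals_mean_eigenvalue(self):
        cov = np.array([[0.003, 0.001], [0.001, 0.002]])
        assert decision_value(cov) == pytest.approx(np.mean(np.linalg.eigvalsh(cov)))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            decision_value(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestRunTrial:
    def delivery(self, end=(0.0, 0.0), seed=0, sigma=0.005):
        clean = generate_min_jerk((end[0], -0.25), end, 1.0, 100)
        return add_observation_noise(clean, sigma, seed)

    def test_immediate_crossing_for_huge_threshold(self, table, params):
        from dataclasses import replace

        gamma = float(table.averaged_variances()[0]) * 1.1  # above the clamp-low entry
        p = replace(params, decision_threshold=gamma)
        r = run_trial(self.delivery(), p.natural_prior(), p, table, (0, 0))
        assert r.threshold_crossed
        assert r.reaction_time == pytest.approx(0.02)  # first usable 3-sample prefix

    def test_unattainable_threshold_caps_at_movement_end(self, table, params):
        from dataclasses import replace

        p = replace(params, decision_threshold=1e-12)
        r = run_trial(self.delivery(), p.natural_prior(), p, table, (0, 0))
        assert not r.threshold_crossed
        assert r.reaction_time == pytest.approx(1.0)

    def test_displaced_delivery_is_slower(self, table, params):
        prior = params.natural_prior()
        rts_nat, rts_dis = [], []
        for seed in range(10):
            rts_nat.append(
                run_trial(self.delivery((0, 0), seed), prior, params, table, (0, 0)).reaction_time
            )
            rts_dis.append(
                run_trial(self.delivery((0.20, 0), seed), prior, params, table, (0.20, 0)).reaction_time
            )
        assert np.mean(rts_dis) > np.mean(rts_nat)

    def test_motor_latency_is_additive(self, table, params):
        from dataclasses import replace

        base = run_trial(self.delivery(), params.natural_prior(), params, table, (0, 0))
        p = replace(params, motor_latency=0.1)
        delayed = run_trial(self.delivery(), p.natural_prior(), p, table, (0, 0))
        assert delayed.reaction_time == pytest.approx(base.reaction_time + 0.1)

    def test_trace_matches_scalar_pipeline(self, table, params):
        """The vectorized within-trial trace equals composing the four scalar
        operations (grid fit, lookup keyed by elapsed fraction, case posterior,
        fusion, decision value) sample by sample."""
        delivery = self.delivery(seed=4)
        trace = trial_trace(delivery, params.natural_prior(), params, table)
        cfg = EndpointSearchConfig(refine=False)
        for k in (10, 30, 50, 70, 99):
            partial = delivery.prefix(k + 1)
            e = fit_endpoint(partial, cfg)
            frac = (delivery.times[k] - delivery.times[0]) / delivery.duration
            e = e.with_covariance(lookup_covariance(table, frac))
            cp = case_posterior(e, params.natural_prior(), params)
            fused = fuse_map(cp.case, e, params.natural_prior())
            assert trace["p_natural"].iloc[k] == pytest.approx(cp.p_natural, rel=1e-6)
            assert trace["case"].iloc[k] == cp.case
            assert trace["dv"].iloc[k] == pytest.approx(decision_value(fused.covariance), rel=1e-6)

    def test_dv_non_increasing_after_fusion(self, shrinking_table, params):
        """With an isotropically shrinking uncertainty table, the decision value
        never rises once the trial is classified natural."""
        delivery = self.delivery(seed=2, sigma=0.002)
        trace = trial_trace(delivery, params.natural_prior(), params, shrinking_table)
        natural = trace["case"].to_numpy() == NATURAL
        dv = trace["dv"].to_numpy()[natural]
        assert np.all(np.diff(dv) <= 1e-12)

    def test_p_natural_endpoints(self, table, params):
        prior = params.natural_prior()
        t_nat = trial_trace(self.delivery((0, 0), 1), prior, params, table)
        t_dis = trial_trace(self.delivery((0.20, 0), 1), prior, params, table)
        assert t_nat["p_natural"].iloc[-1] > 0.99
        assert t_dis["p_natural"].iloc[-1] < 0.01


class TestValidation:
    def test_model_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(case_prior_natural=1.5)
        with pytest.raises(ValueError):
            ModelParams(decision_threshold=0.0)
        with pytest.raises(ValueError):
            ModelParams(learning_rate_mean=-0.1)
        with pytest.raises(ValueError):
            ModelParams(uniform_support=(0, 0, 0, 1))

    def test_belief_requires_spd_covariance(self):
        with pytest.raises(ValueError):
            GaussianBelief([0, 0], np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD
        with pytest.raises(ValueError):
            GaussianBelief([0, 0], np.array([[1.0, 0.5], [0.0, 1.0]]))  # asymmetric
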