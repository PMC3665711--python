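"""Causal inference over the handover case and the within-trial decision.

The receiver holds two sources of information about where a handover will end:
a Gaussian prior over the natural handover position, and the online endpoint
estimate of the observed delivery movement.  A causal-inference step decides
whether the two share a cause (natural handover, C = N: integrate) or not
(unnatural, C = UN: reject the prior in favour of a uniform workspace prior).

* case posterior:  P(C=N | x_hat) = A / (A + B) with
  A = P(C=N) * N(x_hat; mu_prior, Sigma_est + Sigma_prior) and
  B = (1 - P(C=N)) / area(workspace),
  i.e. the marginal likelihood of the estimate under each causal structure.
* fusion:          in the N case the MAP handover position is the
  precision-weighted product of estimate and prior; in the UN case the belief
  reduces to the endpoint estimate itself.
* decision value:  the averaged variance (mean of the covariance eigenvalues,
  trace/2 in 2-D) of the current handover-position belief; the receiver reacts
  as soon as it falls below the threshold Gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endpoint import EndpointEstimate, EndpointSearchConfig, UncertaintyTable, _fit_prefixes
from .trajectories import Trajectory

__all__ = [
    "GaussianBelief",
    "CasePosterior",
    "ModelParams",
    "TrialResult",
    "case_posterior",
    "fuse_map",
    "decision_value",
    "run_trial",
    "trial_trace",
    "NATURAL",
    "UNNATURAL",
]

NATURAL = "N"
UNNATURAL = "UN"


def _check_spd(cov: np.ndarray, what: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError(f"{what} must be 2x2")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise ValueError(f"{what} must be symmetric")
    if np.min(np.linalg.eigvalsh(cov)) <= 0:
        raise ValueError(f"{what} must be positive-definite")
    return cov


@dataclass(frozen=True)
class GaussianBelief:
    """Gaussian belief over a planar position: mean (m) and 2x2 covariance (m^2)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).reshape(2))
        object.__setattr__(self, "covariance", _check_spd(self.covariance, "belief covariance"))

    @property
    def averaged_variance(self) -> float:
        return float(np.trace(self.covariance)) / 2.0


@dataclass(frozen=True)
class CasePosterior:
    """Posterior probability of the natural-handover case and the reported label."""

    p_natural: float
    case: str = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.p_natural <= 1.0:
            raise ValueError("p_natural must lie in [0, 1]")
        # tie at 0.5 resolves to UN: without positive evidence for the prior's
        # relevance, do not fuse
        object.__setattr__(self, "case", NATURAL if self.p_natural > 0.5 else UNNATURAL)


@dataclass(frozen=True)
class ModelParams:
    """All tunable constants of the receiver model.

    case_prior_natural   P(C=N), the receiver's trust in a natural handover.
    decision_threshold   Gamma (m^2): react when the averaged variance of the
                         handover-position belief falls below it.
    uniform_support      (xmin, xmax, ymin, ymax) of the workspace rectangle
                         backing the unnatural-case uniform prior.
    prior_mean/prior_cov natural handover-position prior at the start of an
                         experiment (reset per simulated subject).
    learning_rate_mean   pi_mu, trial-to-trial update rate of the prior mean.
    learning_rate_cov    pi_sigma, update rate of the prior covariance.
    observation_noise    per-axis sd (m) of the noise on observed deliveries.
    motor_latency        additive constant (s) on reaction times.
    """

    case_prior_natural: float = 0.8
    decision_threshold: float = 1.2e-3
    uniform_support: tuple[float, float, float, float] = (-0.375, 0.375, -0.25, 0.25)
    prior_mean: tuple[float, float] = (0.0, 0.0)
    prior_cov: tuple[float, float] = (0.0016, 0.0016)  # diagonal, m^2
    learning_rate_mean: float = 0.5
    learning_rate_cov: float = 0.2
    observation_noise: float = 0.005
    motor_latency: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.case_prior_natural <= 1.0:
            raise ValueError("case_prior_natural must lie in [0, 1]")
        if self.decision_threshold <= 0:
            raise ValueError("decision_threshold must be positive")
        if not (0.0 <= self.learning_rate_mean <= 1.0 and 0.0 <= self.learning_rate_cov <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.support_area <= 0:
            raise ValueError("uniform support must have positive area")

    @property
    def support_area(self) -> float:
        x0, x1, y0, y1 = self.uniform_support
        return (x1 - x0) * (y1 - y0)

    def natural_prior(self) -> GaussianBelief:
        return GaussianBelief(np.asarray(self.prior_mean), np.diag(self.prior_cov))


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated handover from the receiver's viewpoint."""

    reaction_time: float
    decided_case: str
    predicted_position: np.ndarray
    actual_position: np.ndarray
    threshold_crossed: bool
    trial_index: int = 1


def _gauss2_pdf(delta: np.ndarray, cov: np.ndarray) -> float:
    det = float(np.linalg.det(cov))
    if det <= 0:
        raise np.linalg.LinAlgError("singular covariance in case posterior")
    inv = np.linalg.inv(cov)
    q = float(delta @ inv @ delta)
    return float(np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(det)))


def case_posterior(est: EndpointEstimate, prior: GaussianBelief, params: ModelParams) -> CasePosterior:
    """Probability that the observed delivery targets the natural position.

    Compares the marginal likelihood of the endpoint estimate under the
    Gaussian prior (estimate noise convolved with prior spread) with its
    likelihood under the uniform workspace prior, weighted by the case prior.
    """
    if est.covariance is None:
        raise ValueError("endpoint estimate needs a covariance (attach one from the table)")
    cov = _check_spd(est.covariance, "estimate covariance") + prior.covariance
    g = _gauss2_pdf(est.mean - prior.mean, cov)
    u = 1.0 / params.support_area
    a = params.case_prior_natural * g
    b = (1.0 - params.case_prior_natural) * u
    return CasePosterior(a / (a + b))


def fuse_map(case: str, est: EndpointEstimate, prior: GaussianBelief) -> GaussianBelief:
    """MAP handover-position belief given the inferred case.

    Natural case: precision-weighted Gaussian product of estimate and prior.
    Unnatural case: the belief reduces to the endpoint estimate unchanged.
    """
    if est.covariance is None:
        raise ValueError("endpoint estimate needs a covariance")
    if case == UNNATURAL:
        return GaussianBelief(est.mean, est.covariance)
    if case != NATURAL:
        raise ValueError(f"unknown case label {case!r}")
    pe = np.linalg.inv(_check_spd(est.covariance, "estimate covariance"))
    pp = np.linalg.inv(prior.covariance)
    cov = np.linalg.inv(pe + pp)
    cov = 0.5 * (cov + cov.T)
    mean = cov @ (pe @ est.mean + pp @ prior.mean)
    return GaussianBelief(mean, cov)


def decision_value(cov: np.ndarray) -> float:
    """Averaged variance: mean of the covariance eigenvalues (trace/2 in 2-D)."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("decision value needs a symmetric 2x2 covariance")
    return float(np.trace(cov)) / 2.0


# ---------------------------------------------------------------------------
# within-trial evolution (vectorized over samples)

_EPS = 1e-300


def trial_trace(
    delivery: Trajectory,
    prior: GaussianBelief,
    params: ModelParams,
    table: UncertaintyTable,
    search: EndpointSearchConfig | None = None,
) -> pd.DataFrame:
    """Per-sample evolution of the receiver's inference over one delivery.

    Columns: time, fraction, p_natural, case, dv, pred_x, pred_y.  Semantically
    identical to composing fit_endpoint / case_posterior / fuse_map /
    decision_value sample by sample (grid fit without local refinement), but
    computed with closed-form 2x2 algebra over all prefixes at once.

    The endpoint *position* comes from the (possibly misspecified) minimum-jerk
    fit; the endpoint *reliability* is looked up at the elapsed fraction of the
    delivery movement.  Reliability is driven by observation time: the movement
    durations of a familiar partner are assumed known, whereas keying the
    lookup on the fit's own duration estimate would let a noise-collapsed fit
    manufacture confidence out of nothing.
    """
    search = search or EndpointSearchConfig()
    t = delivery.times - delivery.times[0]
    means, _, _, _ = _fit_prefixes(delivery.times, delivery.positions, search.durations)
    fracs = t / t[-1]
    cov_e = table.lookup_many(fracs)  # (n, 2, 2)

    mu_p, cov_p = prior.mean, prior.covariance
    delta = means - mu_p  # (n, 2)
    c = cov_e + cov_p
    det_c = c[:, 0, 0] * c[:, 1, 1] - c[:, 0, 1] ** 2
    # quadratic form via the 2x2 adjugate
    q = (
        c[:, 1, 1] * delta[:, 0] ** 2
        - 2.0 * c[:, 0, 1] * delta[:, 0] * delta[:, 1]
        + c[:, 0, 0] * delta[:, 1] ** 2
    ) / det_c
    g = np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(det_c))
    a = params.case_prior_natural * g
    b = (1.0 - params.case_prior_natural) / params.support_area
    p_nat = a / np.maximum(a + b, _EPS)
    natural = p_nat > 0.5

    # precision-weighted fusion, closed form for 2x2 matrices
    inv_e = _inv2(cov_e)
    inv_p = np.linalg.inv(cov_p)
    cov_f = _inv2(inv_e + inv_p[None, :, :])
    rhs = np.einsum("nij,nj->ni", inv_e, means) + (inv_p @ mu_p)[None, :]
    mean_f = np.einsum("nij,nj->ni", cov_f, rhs)

    dv = np.where(
        natural,
        0.5 * (cov_f[:, 0, 0] + cov_f[:, 1, 1]),
        0.5 * (cov_e[:, 0, 0] + cov_e[:, 1, 1]),
    )
    pred = np.where(natural[:, None], mean_f, means)
    return pd.DataFrame(
        {
            "time": t,
            "fraction": fracs,
            "p_natural": p_nat,
            "case": np.where(natural, NATURAL, UNNATURAL),
            "dv": dv,
            "pred_x": pred[:, 0],
            "pred_y": pred[:, 1],
        }
    )


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    out = np.empty_like(m)
    out[..., 0, 0] = m[..., 1, 1]
    out[..., 1, 1] = m[..., 0, 0]
    out[..., 0, 1] = -m[..., 0, 1]
    out[..., 1, 0] = -m[..., 1, 0]
    return out / det[..., None, None]


def run_trial(
    delivery: Trajectory,
    prior: GaussianBelief,
    params: ModelParams,
    table: UncertaintyTable,
    actual,
    search: EndpointSearchConfig | None = None,
    threshold_scale: float = 1.0,
    trial_index: int = 1,
) -> TrialResult:
    """Simulate the receiver's decision over one delivery movement.

    Sample by sample, the endpoint estimate, case posterior and fused belief
    are updated; the receiver reacts at the first instant the decision value
    falls below ``Gamma * threshold_scale`` (plus motor latency).  The prior is
    held constant within the trial.  If the threshold is never crossed the
    reaction time is capped at the movement end.
    """
    if delivery.duration <= 0:
        raise ValueError("delivery must have positive duration")
    trace = trial_trace(delivery, prior, params, table, search)
    gamma = params.decision_threshold * threshold_scale
    crossed = trace["dv"].to_numpy() < gamma
    # the earliest usable evidence is the first 3-sample prefix
    crossed[:2] = False
    idx = int(np.argmax(crossed)) if crossed.any() else len(trace) - 1
    hit = bool(crossed.any())
    rt = float(trace["time"].iloc[idx]) if hit else delivery.duration
    row = trace.iloc[idx]
    return TrialResult(
        reaction_time=rt + params.motor_latency,
        decided_case=str(row["case"]),
        predicted_position=np.array([row["pred_x"], row["pred_y"]]),
        actual_position=np.asarray(actual, dtype=float).reshape(2),
        threshold_crossed=hit,
        trial_index=trial_index,
    )
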