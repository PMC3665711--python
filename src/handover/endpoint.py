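"""Online endpoint estimation from a partial delivery trajectory.

The receiver is assumed to extrapolate the observed movement prefix to its
endpoint by fitting a member of the minimum-jerk family (least squares over a
duration grid; the endpoint is closed-form per candidate duration).  When the
observed movement is *not* minimum-jerk (the industrial trapezoidal profile),
the fit is deliberately misspecified: that is the mechanism by which curved
robot trajectories mislead early endpoint estimates.

The time course of the estimator's reliability is not derived analytically;
it is calibrated as a lookup table of empirical error covariances, indexed by
observed fraction of the movement, from Monte-Carlo simulations.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .trajectories import Trajectory, add_observation_noise, generate_min_jerk, min_jerk_profile

__all__ = [
    "EndpointEstimate",
    "EndpointSearchConfig",
    "CalibrationConfig",
    "UncertaintyTable",
    "InsufficientDataError",
    "fit_endpoint",
    "calibrate_uncertainty",
    "lookup_covariance",
]

_COV_FLOOR = 1e-12  # m^2, keeps calibrated matrices positive-definite


class InsufficientDataError(ValueError):
    """Raised when a partial trajectory is too short to fit."""


@dataclass(frozen=True)
class EndpointEstimate:
    """Current belief about where the observed movement will end.

    ``covariance`` is attached from an :class:`UncertaintyTable` (the fit
    itself yields only the point estimate and the implied duration).
    """

    mean: np.ndarray  # (2,) metres
    observed_fraction: float  # elapsed / estimated duration, in [0, 1]
    estimated_duration: float  # seconds (inf for a stationary prefix)
    covariance: np.ndarray | None = None  # (2, 2) m^2

    def with_covariance(self, cov: np.ndarray) -> "EndpointEstimate":
        return EndpointEstimate(self.mean, self.observed_fraction, self.estimated_duration, cov)


@dataclass(frozen=True)
class EndpointSearchConfig:
    """Duration-grid search settings for the minimum-jerk fit."""

    duration_min: float = 0.4
    duration_max: float = 2.4
    duration_step: float = 0.05
    refine: bool = True  # parabolic refinement of the duration around the grid optimum

    @property
    def durations(self) -> np.ndarray:
        n = int(round((self.duration_max - self.duration_min) / self.duration_step)) + 1
        return self.duration_min + self.duration_step * np.arange(n)


def _fit_prefixes(times: np.ndarray, positions: np.ndarray, durations: np.ndarray):
    """Vectorized minimum-jerk fits for every prefix of a sampled path.

    For a candidate duration T the model is p_i = p_0 + a * s(t_i / T) with the
    amplitude ``a`` (2-vector) closed-form in least squares; the duration is
    chosen per prefix by residual minimization over the grid.

    Returns (means, T_hat, fractions, resid) with leading dimension n; entries
    for prefixes shorter than 3 samples fall back to the current position with
    fraction 0.
    """
    t = times - times[0]
    d = positions - positions[0]
    n = len(t)
    s = min_jerk_profile(t[None, :] / durations[:, None])  # (nT, n)
    cum_s2 = np.cumsum(s * s, axis=1)  # (nT, n)
    cum_sd = np.cumsum(s[:, :, None] * d[None, :, :], axis=1)  # (nT, n, 2)
    cum_dd = np.cumsum(np.sum(d * d, axis=1))  # (n,)
    den = np.maximum(cum_s2, 1e-12)
    resid = cum_dd[None, :] - np.sum(cum_sd**2, axis=2) / den  # (nT, n)
    best = np.argmin(resid, axis=0)  # (n,)
    idx = np.arange(n)
    amp = cum_sd[best, idx, :] / den[best, idx][:, None]  # (n, 2)
    means = positions[0] + amp
    T_hat = durations[best]
    fractions = np.clip(t / T_hat, 0.0, 1.0)
    # degenerate prefixes: too short, or no displacement observed yet
    moved = np.maximum.accumulate(np.max(np.abs(d), axis=1)) > 1e-12
    ok = (idx >= 2) & moved
    means[~ok] = positions[~ok]
    fractions[~ok] = 0.0
    T_hat = np.where(ok, T_hat, np.inf)
    return means, T_hat, fractions, resid[best, idx]


def fit_endpoint(partial: Trajectory, config: EndpointSearchConfig | None = None) -> EndpointEstimate:
    """Fit the best minimum-jerk extrapolation to a movement prefix.

    Least squares over a grid of candidate durations (endpoint closed-form per
    duration), optionally refined by parabolic interpolation of the residual
    around the grid optimum.  A stationary prefix returns the current position
    with observed fraction 0 (maximal uncertainty by convention).
    """
    if partial.n_samples < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to fit an endpoint, got {partial.n_samples}"
        )
    config = config or EndpointSearchConfig()
    durations = config.durations
    t = partial.times - partial.times[0]
    d = partial.positions - partial.positions[0]
    if np.max(np.abs(d)) <= 1e-12:
        return EndpointEstimate(partial.positions[-1].copy(), 0.0, np.inf)

    s = min_jerk_profile(t[None, :] / durations[:, None])
    den = np.maximum(np.sum(s * s, axis=1), 1e-12)
    num = s @ d  # (nT, 2)
    resid = np.sum(d * d) - np.sum(num**2, axis=1) / den
    j = int(np.argmin(resid))
    T = durations[j]
    if config.refine and 0 < j < len(durations) - 1:
        r0, r1, r2 = resid[j - 1], resid[j], resid[j + 1]
        denom = r0 - 2 * r1 + r2
        if denom > 0:
            T = T + 0.5 * config.duration_step * (r0 - r2) / denom
    sT = min_jerk_profile(t / T)
    denT = max(float(sT @ sT), 1e-12)
    amp = (sT @ d) / denT
    mean = partial.positions[0] + amp
    elapsed = float(t[-1])
    frac = float(np.clip(elapsed / T, 0.0, 1.0))
    return EndpointEstimate(mean, frac, float(T))


@dataclass(frozen=True)
class CalibrationConfig:
    """Monte-Carlo setup that the uncertainty table is calibrated on.

    Endpoints are randomized uniformly over the workspace rectangle (the
    ignorance case the table must serve); delivery movements are minimum-jerk
    from a fixed start with additive observation noise.
    """

    start: tuple[float, float] = (0.0, -0.25)
    support: tuple[float, float, float, float] = (-0.375, 0.375, -0.25, 0.25)
    duration: float = 1.0
    rate: float = 100.0
    family: str = "min_jerk"


@dataclass(frozen=True)
class UncertaintyTable:
    """Endpoint-error covariance versus observed fraction of the movement.

    ``covariances[i]`` is the empirical covariance of (estimate - true
    endpoint) at ``fractions[i]``; averaged variance (trace/2) is enforced
    non-increasing along the grid by isotonic adjustment.
    """

    fractions: np.ndarray  # increasing grid in (0, 1]
    covariances: np.ndarray  # (k, 2, 2) m^2, each positive-definite
    generator_tag: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        c = np.asarray(self.covariances, dtype=float)
        if len(f) == 0:
            raise ValueError("uncertainty table must not be empty")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fraction grid must be strictly increasing")
        if c.shape != (len(f), 2, 2):
            raise ValueError("need one 2x2 covariance per grid point")
        for m in c:
            if not np.allclose(m, m.T) or np.min(np.linalg.eigvalsh(m)) <= 0:
                raise ValueError("each covariance must be symmetric positive-definite")
        object.__setattr__(self, "fractions", f)
        object.__setattr__(self, "covariances", c)

    def averaged_variances(self) -> np.ndarray:
        return np.trace(self.covariances, axis1=1, axis2=2) / 2.0

    def lookup_many(self, fractions: np.ndarray) -> np.ndarray:
        """Element-wise linearly interpolated covariances, clamped at the ends."""
        f = np.asarray(fractions, dtype=float)
        out = np.empty(f.shape + (2, 2))
        for i in range(2):
            for j in range(2):
                out[..., i, j] = np.interp(f, self.fractions, self.covariances[:, i, j])
        return out

    def to_csv(self, path) -> None:
        header = "# generator: " + json.dumps(self.generator_tag, sort_keys=True)
        rows = np.column_stack(
            [
                self.fractions,
                self.covariances[:, 0, 0],
                self.covariances[:, 0, 1],
                self.covariances[:, 1, 1],
            ]
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            fh.write("fraction,c_xx_m2,c_xy_m2,c_yy_m2\n")
            for r in rows:
                fh.write(",".join(format(v, ".12g") for v in r) + "\n")

    @classmethod
    def from_csv(cls, path) -> "UncertaintyTable":
        tag: dict = {}
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].startswith("#"):
            try:
                tag = json.loads(lines[0].split(":", 1)[1])
            except (json.JSONDecodeError, IndexError):
                tag = {}
            lines = lines[1:]
        data = np.loadtxt(io.StringIO("\n".join(lines[1:])), delimiter=",", ndmin=2)
        cov = np.empty((len(data), 2, 2))
        cov[:, 0, 0] = data[:, 1]
        cov[:, 0, 1] = cov[:, 1, 0] = data[:, 2]
        cov[:, 1, 1] = data[:, 3]
        return cls(data[:, 0], cov, tag)


def lookup_covariance(table: UncertaintyTable, fraction: float) -> np.ndarray:
    """Interpolated error covariance at ``fraction`` (clamped to the grid ends)."""
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    return table.lookup_many(np.asarray(fraction, dtype=float))


def calibrate_uncertainty(
    family_config: CalibrationConfig,
    fractions,
    sigma: float,
    n_mc: int = 1000,
    seed: int = 0,
    search: EndpointSearchConfig | None = None,
) -> UncertaintyTable:
    """Build the endpoint-uncertainty lookup table by Monte-Carlo simulation.

    For each observed fraction, ``n_mc`` noisy movements with endpoints drawn
    uniformly over the workspace are generated, endpoints are fitted from the
    corresponding prefix, and the empirical covariance of the estimation error
    is stored.  Averaged variance is made non-increasing in the fraction by
    isotonic regression (scaling each matrix accordingly).
    """
    if n_mc < 100:
        raise ValueError("n_mc must be at least 100 for a stable covariance")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    if np.any(np.diff(fractions) <= 0):
        raise ValueError("fractions must be strictly increasing")
    search = search or EndpointSearchConfig()
    durations_grid = search.durations
    rng = np.random.default_rng(seed)

    x0, x1, y0, y1 = family_config.support
    ends = np.column_stack(
        [rng.uniform(x0, x1, size=n_mc), rng.uniform(y0, y1, size=n_mc)]
    )
    base = generate_min_jerk(
        family_config.start, (0.0, 0.0), family_config.duration, family_config.rate
    )
    t = base.times
    n = len(t)
    s_true = min_jerk_profile(t / family_config.duration)  # (n,)
    start = np.asarray(family_config.start, dtype=float)
    clean = start[None, None, :] + s_true[None, :, None] * (ends - start)[:, None, :]
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape)

    # batched closed-form fits: residual over the duration grid per trial
    s_grid = min_jerk_profile(t[None, :] / durations_grid[:, None])  # (nT, n)
    covs = np.empty((len(fractions), 2, 2))
    for k, f in enumerate(fractions):
        m = max(3, int(round(f * (n - 1))) + 1)
        d = noisy[:, :m, :] - noisy[:, :1, :]  # (B, m, 2)
        S = s_grid[:, :m]  # (nT, m)
        den = np.maximum(np.sum(S * S, axis=1), 1e-12)  # (nT,)
        num = np.einsum("tm,bmc->btc", S, d)  # (B, nT, 2)
        resid = np.sum(d * d, axis=(1, 2))[:, None] - np.sum(num**2, axis=2) / den[None, :]
        best = np.argmin(resid, axis=1)  # (B,)
        amp = num[np.arange(n_mc), best, :] / den[best][:, None]
        est = noisy[:, 0, :] + amp
        err = est - ends
        err = err - err.mean(axis=0)
        covs[k] = err.T @ err / (n_mc - 1) + _COV_FLOOR * np.eye(2)

    # isotonic (non-increasing) adjustment of the averaged variance
    av = np.trace(covs, axis1=1, axis2=2) / 2.0
    iso = IsotonicRegression(increasing=False)
    av_adj = iso.fit_transform(fractions, av)
    scale = np.maximum(av_adj, _COV_FLOOR) / av
    covs = covs * scale[:, None, None]

    tag = {
        "family": family_config.family,
        "sigma": sigma,
        "duration": family_config.duration,
        "rate": family_config.rate,
        "n_mc": n_mc,
        "seed": int(seed),
    }
    return UncertaintyTable(fractions, covs, tag)
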