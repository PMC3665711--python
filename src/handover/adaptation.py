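"""Trial-to-trial adaptation of the handover-position prior.

After each handover the receiver updates the prior toward the experienced
handover position with a delta rule using separate learning rates for the mean
and the covariance.  A small prediction error shifts the prior slightly and
shrinks its uncertainty; a large error shifts it strongly and inflates the
uncertainty (through the outer product of the error).  The exact update used
by the original formulation is not recoverable from its published description;
this delta rule is a reconstruction satisfying every stated behavioural
property, and it is isolated behind this single function so alternates can be
swapped.
"""

from __future__ import annotations

import numpy as np

from .bayes import GaussianBelief, ModelParams

__all__ = ["update_prior", "COV_FLOOR"]

COV_FLOOR = 1e-6  # m^2, keeps the prior covariance positive-definite


def update_prior(prior: GaussianBelief, x_real, params: ModelParams) -> GaussianBelief:
    """Delta-rule update of the prior after observing the real handover position.

    mean  <- mean + pi_mu * e
    cov   <- (1 - pi_sigma) * cov + pi_sigma * (e e^T + eps I)

    with e = x_real - mean.  Learning rates (0, 0) leave the prior unchanged.
    """
    pi_mu = params.learning_rate_mean
    pi_sigma = params.learning_rate_cov
    if pi_mu == 0.0 and pi_sigma == 0.0:
        return prior
    x = np.asarray(x_real, dtype=float).reshape(2)
    e = x - prior.mean
    mean = prior.mean + pi_mu * e
    cov = (1.0 - pi_sigma) * prior.covariance + pi_sigma * (
        np.outer(e, e) + COV_FLOOR * np.eye(2)
    )
    return GaussianBelief(mean, 0.5 * (cov + cov.T))
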