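"""Fix the decision threshold Gamma against the human baseline experiment.

Simulates the six-trial natural-handover experiment over a grid of thresholds
and reports the mean reaction time of each.  The default Gamma in the package
configuration is the grid value whose simulated mean comes closest to the
empirically reported baseline mean (0.23 s) while staying below the
once-adapted prior variance (1 - pi_sigma) * sigma_prior^2 = 1.28e-3 m^2, so
that trial-to-trial adaptation remains expressible in the reaction times.

Writes results/threshold_calibration.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from handover.bayes import ModelParams
from handover.endpoint import CalibrationConfig, calibrate_uncertainty
from handover.simulator import calibrate_threshold

TARGET_MEAN_RT = 0.23  # s, reported human baseline mean


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/threshold_calibration.csv"))
    args = ap.parse_args()

    params = ModelParams()
    table = calibrate_uncertainty(
        CalibrationConfig(), np.arange(0.05, 1.001, 0.05),
        sigma=params.observation_noise, n_mc=1000, seed=args.seed,
    )
    ceiling = (1.0 - params.learning_rate_cov) * np.mean(params.prior_cov)
    grid = np.arange(2e-4, ceiling + 1e-9, 1e-4)
    best, sweep = calibrate_threshold(
        params, table, TARGET_MEAN_RT, grid, n_replicates=args.replicates, seed=args.seed
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    sweep.to_csv(args.out, index=False)

    print(sweep.to_string(index=False))
    print(f"adaptation-expressibility ceiling: {ceiling:.2e} m^2")
    print(f"selected Gamma = {best:.2e} m^2 (package default: {params.decision_threshold:.2e})")
    print(
        "finding: the simulated baseline cannot reach the 0.23 s human mean — evidence\n"
        "about the endpoint only sharpens past ~45% of the movement — so the threshold\n"
        "saturates at the ceiling; reaction-time ORDERINGS across conditions, not the\n"
        "absolute means, are the quantities the model reproduces."
    )


if __name__ == "__main__":
    main()
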