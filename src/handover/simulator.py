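"""Simulation of the five handover experiments.

Each simulated subject (replicate) receives exactly six cubes.  Per trial a
delivery movement to the commanded handover position is generated (minimum
jerk for human-like deliverers, trapezoidal joint profile for the industrial
one), observed under noise, and fed through the receiver model; if adaptation
is enabled the handover-position prior is updated with the experienced
position after the trial.

Experiment layout:

=====  ==========================  ========  ==========  ==========
name   position sequence           duration  family      adaptation
=====  ==========================  ========  ==========  ==========
exp1   M M M M M M                 1.0 s     min_jerk    on
exp2   R R R R R R                 1.0 s     min_jerk    on
exp3   R L M L R M                 1.0 s     min_jerk    on
exp4a  M M M M M M                 1.2 s     min_jerk    off
exp4b  M M M M M M                 1.2 s     trapezoid   off
exp5a  like exp4a, lower Gamma     1.2 s     min_jerk    off
exp5b  like exp4b, lower Gamma     1.2 s     trapezoid   off
=====  ==========================  ========  ==========  ==========
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adaptation import update_prior
from .bayes import ModelParams, run_trial
from .endpoint import EndpointSearchConfig, UncertaintyTable
from .trajectories import (
    ArmGeometry,
    add_observation_noise,
    generate_min_jerk,
    generate_trapezoid_joint,
    inverse_kinematics,
)

__all__ = [
    "POSITIONS",
    "ExperimentConfig",
    "make_experiment_config",
    "run_experiment",
    "summarize",
    "replicate_slopes",
    "calibrate_threshold",
    "estimate_threshold",
]

# workspace coordinates: origin at the table-centre handover point M, +y from
# deliverer toward receiver, +x toward the deliverer's right; cube pickup row
# at y = -0.25 m
POSITIONS: dict[str, tuple[float, float]] = {
    "M": (0.0, 0.0),
    "R": (0.20, 0.0),
    "L": (-0.20, 0.0),
}

_EXPERIMENT_NAMES = ("exp1", "exp2", "exp3", "exp4a", "exp4b", "exp5a", "exp5b")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: six commanded handover positions plus delivery settings."""

    name: str
    position_sequence: tuple[str, ...]
    movement_duration: float = 1.0
    trajectory_family: str = "min_jerk"  # or "trapezoid"
    adaptation_enabled: bool = True
    threshold_scale: float = 1.0
    sampling_rate: float = 100.0
    noise_sigma: float = 0.005
    arm: ArmGeometry = field(default_factory=ArmGeometry)
    accel_fraction: float = 0.15
    # robot deliveries start from a midair rest pose rather than the cube row
    start_override: tuple[float, float] | None = None

    def __post_init__(self):
        if len(self.position_sequence) != 6:
            raise ValueError("an experiment consists of exactly 6 handovers")
        unknown = set(self.position_sequence) - set(POSITIONS)
        if unknown:
            raise ValueError(f"unknown position labels: {sorted(unknown)}")
        if self.movement_duration <= 0:
            raise ValueError("movement_duration must be positive")
        if self.trajectory_family not in ("min_jerk", "trapezoid"):
            raise ValueError("trajectory_family must be 'min_jerk' or 'trapezoid'")


def make_experiment_config(name: str, threshold_scale_low: float = 0.5) -> ExperimentConfig:
    """Canonical configuration of one of the seven simulated conditions."""
    if name not in _EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {name!r}; expected one of {_EXPERIMENT_NAMES}")
    if name == "exp1":
        return ExperimentConfig("exp1", ("M",) * 6, movement_duration=1.0)
    if name == "exp2":
        return ExperimentConfig("exp2", ("R",) * 6, movement_duration=1.0)
    if name == "exp3":
        return ExperimentConfig("exp3", ("R", "L", "M", "L", "R", "M"), movement_duration=1.0)
    family = "trapezoid" if name.endswith("b") else "min_jerk"
    scale = threshold_scale_low if name.startswith("exp5") else 1.0
    return ExperimentConfig(
        name,
        ("M",) * 6,
        movement_duration=1.2,
        trajectory_family=family,
        adaptation_enabled=False,
        threshold_scale=scale,
        start_override=(-0.05, -0.45),
    )


def _delivery(config: ExperimentConfig, label: str, rng: np.random.Generator):
    """Noisy delivery trajectory to the commanded position and its true endpoint."""
    target = np.asarray(POSITIONS[label], dtype=float)
    if config.start_override is not None:
        start = np.asarray(config.start_override, dtype=float)
    else:
        start = np.array([target[0], -0.25])  # cube row below the commanded x
    if config.trajectory_family == "min_jerk":
        clean = generate_min_jerk(start, target, config.movement_duration, config.sampling_rate)
    else:
        q0 = inverse_kinematics(config.arm, start)
        q1 = inverse_kinematics(config.arm, target)
        clean = generate_trapezoid_joint(
            config.arm, q0, q1, config.movement_duration, config.accel_fraction,
            config.sampling_rate,
        )
    return add_observation_noise(clean, config.noise_sigma, rng), target


def run_experiment(
    config: ExperimentConfig,
    params: ModelParams,
    table: UncertaintyTable,
    n_replicates: int = 500,
    seed: int = 0,
    search: EndpointSearchConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` six-trial subjects; returns the reaction-time table.

    Columns: replicate, trial, rt_s, case, crossed.  Each replicate starts from
    the natural-handover prior; the prior is updated between trials only when
    adaptation is enabled.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    search = search or EndpointSearchConfig()
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        prior = params.natural_prior()
        for i, label in enumerate(config.position_sequence, start=1):
            delivery, target = _delivery(config, label, rng)
            result = run_trial(
                delivery, prior, params, table, target,
                search=search, threshold_scale=config.threshold_scale, trial_index=i,
            )
            rows.append(
                (r, i, result.reaction_time, result.decided_case, result.threshold_crossed)
            )
            if config.adaptation_enabled:
                prior = update_prior(prior, target, params)
    return pd.DataFrame(rows, columns=["replicate", "trial", "rt_s", "case", "crossed"])


def replicate_slopes(table: pd.DataFrame) -> np.ndarray:
    """Per-replicate ordinary least-squares slope of reaction time vs trial number."""
    wide = table.pivot(index="replicate", columns="trial", values="rt_s")
    trials = wide.columns.to_numpy(dtype=float)
    x = trials - trials.mean()
    return (wide.to_numpy() @ x) / float(x @ x)


def summarize(table: pd.DataFrame) -> dict:
    """Per-trial mean/SD of reaction times plus per-replicate regression slopes."""
    if table.empty:
        raise ValueError("empty reaction-time table")
    per_trial = (
        table.groupby("trial")["rt_s"].agg(mean="mean", sd="std").reset_index()
    )
    slopes = replicate_slopes(table)
    return {
        "per_trial": per_trial,
        "slopes": slopes,
        "mean_rt": float(table["rt_s"].mean()),
        "mean_slope": float(np.mean(slopes)),
    }


# ---------------------------------------------------------------------------
# threshold calibration / recovery

def calibrate_threshold(
    params: ModelParams,
    table: UncertaintyTable,
    target_mean_rt: float,
    gammas,
    n_replicates: int = 100,
    seed: int = 0,
    experiment: str = "exp1",
) -> tuple[float, pd.DataFrame]:
    """Pick the decision threshold whose simulated mean reaction time is closest
    to ``target_mean_rt`` on the given experiment.

    Returns (best gamma, grid DataFrame with columns gamma, mean_rt).
    """
    config = make_experiment_config(experiment)
    rows = []
    for g in np.asarray(gammas, dtype=float):
        p = replace(params, decision_threshold=float(g))
        rt = run_experiment(config, p, table, n_replicates, seed)["rt_s"].mean()
        rows.append((float(g), float(rt)))
    grid = pd.DataFrame(rows, columns=["gamma", "mean_rt"])
    best = grid.loc[(grid["mean_rt"] - target_mean_rt).abs().idxmin(), "gamma"]
    return float(best), grid


def estimate_threshold(
    observed: pd.DataFrame,
    params: ModelParams,
    table: UncertaintyTable,
    gammas,
    n_replicates: int = 100,
    seed: int = 0,
    experiment: str = "exp1",
) -> float:
    """Recover the decision threshold generating an observed reaction-time table.

    Grid search minimizing the mean squared difference of per-trial mean
    reaction times between observation and simulation.
    """
    config = make_experiment_config(experiment)
    target = observed.groupby("trial")["rt_s"].mean().to_numpy()
    best_g, best_err = None, np.inf
    for g in np.asarray(gammas, dtype=float):
        p = replace(params, decision_threshold=float(g))
        sim = run_experiment(config, p, table, n_replicates, seed)
        mean_rts = sim.groupby("trial")["rt_s"].mean().to_numpy()
        err = float(np.mean((mean_rts - target) ** 2))
        if err < best_err:
            best_g, best_err = float(g), err
    return best_g
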