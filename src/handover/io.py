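"""CSV / YAML input-output for trajectories, recordings and configuration.

Formats
-------
Trajectory CSV      header ``time_s,x_m,y_m``, one row per sample.
Recording CSV       header ``actor,time_s,x_m,y_m`` (actor: deliverer/receiver)
                    plus a sidecar ``<stem>.events.csv`` with ``event,time_s``.
Config YAML         flat sections per module; every under-specified constant of
                    the model lives here and can be overridden in one place.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import ModelParams
from .kinematics import HandoverRecording
from .simulator import ExperimentConfig
from .trajectories import ArmGeometry, Trajectory

__all__ = [
    "FormatError",
    "read_trajectory",
    "write_trajectory",
    "read_recording",
    "write_recording",
    "params_to_dict",
    "params_from_dict",
    "experiment_to_dict",
    "experiment_from_dict",
    "load_config",
    "save_config",
    "default_config",
]

_TRAJ_COLUMNS = ["time_s", "x_m", "y_m"]


class FormatError(ValueError):
    """A file does not conform to the documented CSV layout."""


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {"time_s": traj.times, "x_m": traj.positions[:, 0], "y_m": traj.positions[:, 1]}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def _check_times(times: np.ndarray, path) -> None:
    bad = np.flatnonzero(np.diff(times) <= 0)
    if len(bad):
        # +2: one for the diff offset, one for the header line
        raise FormatError(f"{path}: non-monotone time at data row {bad[0] + 2}")


def read_trajectory(path) -> Trajectory:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    times = df["time_s"].to_numpy(dtype=float)
    _check_times(times, path)
    rate = 1.0 / float(np.median(np.diff(times)))
    return Trajectory(times, df[["x_m", "y_m"]].to_numpy(dtype=float), rate)


def write_recording(rec: HandoverRecording, path) -> None:
    path = Path(path)
    frames = []
    for actor, traj in (("deliverer", rec.deliverer), ("receiver", rec.receiver)):
        frames.append(
            pd.DataFrame(
                {
                    "actor": actor,
                    "time_s": traj.times,
                    "x_m": traj.positions[:, 0],
                    "y_m": traj.positions[:, 1],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.9f")
    events = pd.DataFrame(
        sorted(rec.annotations.items()), columns=["event", "time_s"]
    )
    events.to_csv(path.with_suffix(".events.csv"), index=False, float_format="%.9f")


def read_recording(path) -> HandoverRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["actor"] + _TRAJ_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    trajs = {}
    for actor, sub in df.groupby("actor"):
        times = sub["time_s"].to_numpy(dtype=float)
        _check_times(times, path)
        rate = 1.0 / float(np.median(np.diff(times)))
        trajs[actor] = Trajectory(times, sub[["x_m", "y_m"]].to_numpy(dtype=float), rate)
    if set(trajs) != {"deliverer", "receiver"}:
        raise FormatError(f"{path}: expected actors deliverer and receiver, got {sorted(trajs)}")
    annotations = {}
    sidecar = path.with_suffix(".events.csv")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        annotations = dict(zip(ev["event"], ev["time_s"].astype(float)))
    return HandoverRecording(trajs["deliverer"], trajs["receiver"], annotations)


# ---------------------------------------------------------------------------
# configuration round trip

def params_to_dict(params: ModelParams) -> dict:
    d = asdict(params)
    d["uniform_support"] = list(params.uniform_support)
    d["prior_mean"] = list(params.prior_mean)
    d["prior_cov"] = list(params.prior_cov)
    return d


def params_from_dict(d: dict) -> ModelParams:
    d = dict(d)
    for key in ("uniform_support", "prior_mean", "prior_cov"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelParams(**d)


def experiment_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["position_sequence"] = list(config.position_sequence)
    d["arm"] = {"base": list(config.arm.base), "link_lengths": list(config.arm.link_lengths)}
    return d


def experiment_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    d["position_sequence"] = tuple(d["position_sequence"])
    if "arm" in d:
        arm = d["arm"]
        d["arm"] = ArmGeometry(tuple(arm["base"]), tuple(arm["link_lengths"]))
    return ExperimentConfig(**d)


def default_config() -> dict:
    """The package's one config file, as a dict (see data/defaults.yaml)."""
    from importlib.resources import files

    with (files("handover") / "data" / "defaults.yaml").open(encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
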