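"""Delimited-table serialization for trajectories, protocols and gain tables.

Trajectories write one row per time step with the deterministic column
order ``t, true_<state>..., pred_<state>..., hat_<state>..., sense_<sensor>...,
sensepred_<sensor>..., err_<sensor>..., fb_<state>__<sensor>...``. Numbers
are written with 17 significant digits so a round trip reproduces every
value bit-identically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import GainTable, Params
from .protocols import Protocol
from .simulate import Trajectory

__all__ = [
    "trajectory_to_frame",
    "frame_to_trajectory",
    "write_trajectory",
    "read_trajectory",
    "write_protocol",
    "read_protocol",
    "write_gain_table",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"t": traj.t}
    for prefix, arr in (("true", traj.X_true), ("pred", traj.X_pred), ("hat", traj.X_hat)):
        for i, st in enumerate(traj.state_labels):
            cols[f"{prefix}_{st}"] = arr[:, i]
    for prefix, arr in (("sense", traj.S), ("sensepred", traj.S_pred), ("err", traj.dS)):
        for j, se in enumerate(traj.sensor_labels):
            cols[f"{prefix}_{se}"] = arr[:, j]
    for i, st in enumerate(traj.state_labels):
        for j, se in enumerate(traj.sensor_labels):
            cols[f"fb_{st}__{se}"] = traj.feedback[:, i, j]
    return pd.DataFrame(cols)


def frame_to_trajectory(df: pd.DataFrame) -> Trajectory:
    state_labels = tuple(c[len("true_"):] for c in df.columns if c.startswith("true_"))
    sensor_labels = tuple(c[len("sense_"):] for c in df.columns
                          if c.startswith("sense_") and not c.startswith("sensepred_"))
    n = len(df)
    stack_states = lambda p: np.column_stack([df[f"{p}_{s}"].to_numpy() for s in state_labels])
    stack_sensors = lambda p: np.column_stack([df[f"{p}_{s}"].to_numpy() for s in sensor_labels])
    fb = np.zeros((n, len(state_labels), len(sensor_labels)))
    for i, st in enumerate(state_labels):
        for j, se in enumerate(sensor_labels):
            fb[:, i, j] = df[f"fb_{st}__{se}"].to_numpy()
    return Trajectory(
        t=df["t"].to_numpy(),
        X_true=stack_states("true"),
        X_pred=stack_states("pred"),
        X_hat=stack_states("hat"),
        S=stack_sensors("sense"),
        S_pred=stack_sensors("sensepred"),
        dS=stack_sensors("err"),
        feedback=fb,
        state_labels=state_labels,
        sensor_labels=sensor_labels,
        metadata={"source": "file"},
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: str | Path) -> Trajectory:
    return frame_to_trajectory(pd.read_csv(path, float_precision="round_trip"))


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    cols = {"t": protocol.t, **protocol.active, **protocol.passive}
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_protocol(path: str | Path, mode: str, name: str | None = None) -> Protocol:
    df = pd.read_csv(path, float_precision="round_trip")
    active = {c: df[c].to_numpy() for c in df.columns if c.endswith("_u")}
    passive = {c: df[c].to_numpy() for c in df.columns if c.endswith("_eps")}
    return Protocol(
        t=df["t"].to_numpy(), active=active, passive=passive, mode=mode,
        name=name or Path(path).stem,
    )


def write_gain_table(table: GainTable, path: str | Path) -> None:
    Path(path).write_text(table.report())


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration; parameter overrides under ``params:``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    overrides = cfg.get("params", {}) or {}
    cfg["params_obj"] = Params(**overrides)
    return cfg
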