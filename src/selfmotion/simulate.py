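"""World + filter simulation over a motion protocol.

The *world* model generates the true state and sensor series (perturbations
enter through E; sensor noise is off by default, matching the convention
that noise-free runs represent the average over noisy ones). The *filter*
model — normally identical to the world, possibly ablated — sees only the
motor commands and the sensor series, and runs the constant-gain Kalman
recursion. Every internal signal is recorded: predictions, sensory errors,
and the per-(state, sensor) feedback contributions, because distinct
feedback pathways map onto distinct neuron classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kalman import GainMatrix, LinearModel, steady_state_gain
from .models import Params, make_neck_model, make_rotation_tilt_model
from .protocols import Protocol

__all__ = ["Trajectory", "generate_truth", "run_filter", "simulate", "default_world"]


@dataclass
class Trajectory:
    """Per-time-step record of a simulation.

    Arrays are (n_steps, n_states) or (n_steps, n_sensors); ``feedback``
    is (n_steps, n_states, n_sensors) holding K[i, j] * dS[j] so that
    canal-driven and otolith-driven corrections stay separable. The exact
    bookkeeping identity X_hat = X_pred + sum_j feedback[:, :, j] holds at
    every step.
    """

    t: np.ndarray
    X_true: np.ndarray
    X_pred: np.ndarray
    X_hat: np.ndarray
    S: np.ndarray
    S_pred: np.ndarray
    dS: np.ndarray
    feedback: np.ndarray
    state_labels: tuple[str, ...]
    sensor_labels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def state(self, label: str, which: str = "hat") -> np.ndarray:
        i = self.state_labels.index(label)
        return {"true": self.X_true, "pred": self.X_pred, "hat": self.X_hat}[which][:, i]

    def sensor(self, label: str, which: str = "s") -> np.ndarray:
        j = self.sensor_labels.index(label)
        return {"s": self.S, "pred": self.S_pred, "err": self.dS}[which][:, j]

    def feedback_series(self, state: str, sensor: str | None = None) -> np.ndarray:
        """Feedback onto one state, from one sensor or summed over all."""
        i = self.state_labels.index(state)
        if sensor is None:
            return self.feedback[:, i, :].sum(axis=1)
        return self.feedback[:, i, self.sensor_labels.index(sensor)]

    def __add__(self, other: "Trajectory") -> "Trajectory":
        if self.state_labels != other.state_labels or self.sensor_labels != other.sensor_labels:
            raise ValueError("trajectories come from different models")
        return Trajectory(
            t=self.t,
            X_true=self.X_true + other.X_true,
            X_pred=self.X_pred + other.X_pred,
            X_hat=self.X_hat + other.X_hat,
            S=self.S + other.S,
            S_pred=self.S_pred + other.S_pred,
            dS=self.dS + other.dS,
            feedback=self.feedback + other.feedback,
            state_labels=self.state_labels,
            sensor_labels=self.sensor_labels,
            metadata={"sum_of": [self.metadata, other.metadata]},
        )


def _match_grid(model: LinearModel, protocol: Protocol) -> None:
    if abs(model.dt - protocol.dt) > 1e-12:
        raise ValueError(f"model dt {model.dt} != protocol dt {protocol.dt}")


def generate_truth(
    world: LinearModel, protocol: Protocol, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate the true state and sensor series from rest.

    Sensor noise is drawn (SDs from the diagonal of R) only when ``seed``
    is given; the default is the noise-free convention.
    """
    _match_grid(world, protocol)
    unknown = [k for k in protocol.active if k not in world.input_labels]
    unknown += [k for k in protocol.passive if k not in world.noise_labels]
    if unknown:
        raise ValueError(
            f"protocol channels {unknown} not among model inputs "
            f"{world.input_labels} / noise {world.noise_labels}"
        )
    u = protocol.series(world.input_labels, "active")
    eps = protocol.series(world.noise_labels, "passive")
    n_steps = protocol.n_steps
    X = np.zeros((n_steps, world.n_states))
    x = np.zeros(world.n_states)
    for k in range(n_steps):
        x = world.D @ x + world.M @ u[k] + world.E @ eps[k]
        X[k] = x
    S = X @ world.T.T
    if seed is not None:
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, np.sqrt(np.diag(world.R)), size=S.shape)
    return X, S


def run_filter(
    filter_model: LinearModel,
    K: GainMatrix,
    commands: np.ndarray,
    S: np.ndarray,
    t: np.ndarray | None = None,
    X_true: np.ndarray | None = None,
    metadata: dict | None = None,
) -> Trajectory:
    """Run the constant-gain Kalman recursion over given sensor series.

    The filter sees only ``commands`` (n_steps, n_inputs) and ``S``
    (n_steps, n_sensors) — never the perturbations. ``X_true`` is optional
    bookkeeping copied into the trajectory (zeros if absent).
    """
    commands = np.atleast_2d(np.asarray(commands, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n_steps = commands.shape[0]
    if S.shape[0] != n_steps:
        raise ValueError(f"commands ({n_steps}) and sensors ({S.shape[0]}) grids differ")
    if commands.shape[1] != filter_model.n_inputs or S.shape[1] != filter_model.n_sensors:
        raise ValueError("channel counts do not match the filter model")
    n, m = filter_model.n_states, filter_model.n_sensors
    X_pred = np.zeros((n_steps, n))
    X_hat = np.zeros((n_steps, n))
    S_pred = np.zeros((n_steps, m))
    dS = np.zeros((n_steps, m))
    fb = np.zeros((n_steps, n, m))
    x_hat = np.zeros(n)
    D, M, T, Kmat = filter_model.D, filter_model.M, filter_model.T, K.K
    for k in range(n_steps):
        x_pred = D @ x_hat + M @ commands[k]
        s_pred = T @ x_pred
        err = S[k] - s_pred
        contrib = Kmat * err  # (n_states, n_sensors) broadcast
        x_hat = x_pred + contrib.sum(axis=1)
        X_pred[k], S_pred[k], dS[k], fb[k], X_hat[k] = x_pred, s_pred, err, contrib, x_hat
    if t is None:
        t = np.arange(1, n_steps + 1) * filter_model.dt
    return Trajectory(
        t=np.asarray(t, dtype=float),
        X_true=np.zeros((n_steps, n)) if X_true is None else np.asarray(X_true, dtype=float),
        X_pred=X_pred,
        X_hat=X_hat,
        S=S,
        S_pred=S_pred,
        dS=dS,
        feedback=fb,
        state_labels=filter_model.state_labels,
        sensor_labels=filter_model.sensor_labels,
        metadata=metadata or {},
    )


def default_world(protocol: Protocol, params: Params | None = None) -> LinearModel:
    """Model variant matching a protocol's mode."""
    p = params or Params()
    if protocol.mode == "neck":
        return make_neck_model(p)
    if protocol.mode == "evar":
        return make_rotation_tilt_model(p, gravity_coupled=False, include_otolith=False)
    # tilt and translation both need gravity coupling and the otoliths
    return make_rotation_tilt_model(p, gravity_coupled=True, include_otolith=True)


def simulate(
    world: LinearModel,
    protocol: Protocol,
    filter_model: LinearModel | None = None,
    seed: int | None = None,
    K: GainMatrix | None = None,
) -> Trajectory:
    """Generate truth through ``world`` and estimate it with ``filter_model``.

    When ``filter_model`` is omitted the filter uses the world model itself
    (a correct internal model). The steady-state gain is computed on the
    filter model unless supplied.
    """
    fm = filter_model if filter_model is not None else world
    if fm.sensor_labels != world.sensor_labels:
        raise ValueError("filter and world must share sensor channels")
    X_true, S = generate_truth(world, protocol, seed=seed)
    if K is None:
        K = steady_state_gain(fm)
    commands = protocol.series(fm.input_labels, "active")
    return run_filter(
        fm,
        K,
        commands,
        S,
        t=protocol.t,
        X_true=X_true,
        metadata={
            "world": world.name,
            "filter": fm.name,
            "protocol": protocol.name,
            "seed": seed,
            "noise": seed is not None,
        },
    )
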