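"""Linear-Gaussian state estimation engine.

The generative model is the standard discrete linear state space

    X(t) = D X(t-1) + M Xu(t) + E Xeps(t),      Xeps ~ N(0, Q)
    S(t) = T X(t) + Seta(t),                    Seta ~ N(0, R)

where ``Xu`` are motor commands known to the estimator and ``Xeps`` are
unpredicted perturbations (passive motion, motor error). The estimator runs
the textbook predict / innovate / update cycle with a *constant* feedback
gain ``K`` obtained from the steady state of the discrete Riccati recursion:
these small, well-conditioned sensorimotor models converge to a fixed gain
within a fraction of a second of simulated time, and a single constant gain
matrix is what is reported throughout.

State vectors are column-ordered per ``state_labels``; all matrices act on
the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinearModel",
    "GainMatrix",
    "validate_model",
    "predict",
    "innovate",
    "update",
    "steady_state_gain",
]


@dataclass(frozen=True)
class LinearModel:
    """Container for one discrete linear-Gaussian model.

    Parameters
    ----------
    D, M, E, T
        State transition, command input, perturbation input and observation
        matrices. ``D`` is (n_states, n_states); ``M`` is
        (n_states, n_inputs); ``E`` is (n_states, n_noise); ``T`` is
        (n_sensors, n_states).
    Q, R
        Perturbation covariance (n_noise, n_noise) and sensor-noise
        covariance (n_sensors, n_sensors).
    dt
        Simulation time step in seconds.
    state_labels, input_labels, noise_labels, sensor_labels
        Ordered names fixing the meaning of each row/column.
    """

    D: np.ndarray
    M: np.ndarray
    E: np.ndarray
    T: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    dt: float
    state_labels: tuple[str, ...]
    input_labels: tuple[str, ...]
    noise_labels: tuple[str, ...]
    sensor_labels: tuple[str, ...]
    name: str = "linear_model"

    def __post_init__(self) -> None:
        for attr in ("D", "M", "E", "T", "Q", "R"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        object.__setattr__(self, "input_labels", tuple(self.input_labels))
        object.__setattr__(self, "noise_labels", tuple(self.noise_labels))
        object.__setattr__(self, "sensor_labels", tuple(self.sensor_labels))

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_inputs(self) -> int:
        return len(self.input_labels)

    @property
    def n_noise(self) -> int:
        return len(self.noise_labels)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_labels)

    def replace(self, **changes) -> "LinearModel":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass
class GainMatrix:
    """Steady-state Kalman gain with convergence metadata.

    ``K[i, j]`` maps the sensory error of sensor ``j`` onto the correction
    of state ``i`` (the feedback ``Xk = K dS``). ``P_steady`` is the
    converged *prior* covariance.
    """

    K: np.ndarray
    P_steady: np.ndarray
    iterations: int
    converged: bool
    state_labels: tuple[str, ...] = field(default_factory=tuple)
    sensor_labels: tuple[str, ...] = field(default_factory=tuple)

    def entry(self, state: str, sensor: str) -> float:
        return float(
            self.K[self.state_labels.index(state), self.sensor_labels.index(sensor)]
        )

    def zeroed(self) -> "GainMatrix":
        """Copy with all feedback gains set to zero (open-loop estimator)."""
        return GainMatrix(
            K=np.zeros_like(self.K),
            P_steady=self.P_steady.copy(),
            iterations=self.iterations,
            converged=self.converged,
            state_labels=self.state_labels,
            sensor_labels=self.sensor_labels,
        )

    def report(self) -> str:
        lines = [
            "# steady-state Kalman gain",
            f"# converged: {self.converged}  iterations: {self.iterations}",
            "state\tsensor\tgain",
        ]
        for i, st in enumerate(self.state_labels):
            for j, se in enumerate(self.sensor_labels):
                lines.append(f"{st}\t{se}\t{self.K[i, j]:.17g}")
        return "\n".join(lines) + "\n"


def _symmetric(a: np.ndarray, tol: float = 1e-10) -> bool:
    return bool(np.max(np.abs(a - a.T)) <= tol * max(1.0, np.max(np.abs(a))))


def validate_model(model: LinearModel) -> list[str]:
    """Return a human-readable message for every violated invariant.

    An empty list means the model is usable by every other operation in
    this module. Diagnoses rather than throws.
    """
    v: list[str] = []
    n, m, p, s = model.n_states, model.n_inputs, model.n_noise, model.n_sensors
    if model.D.shape != (n, n):
        v.append(f"D has shape {model.D.shape}, expected ({n}, {n}) from state_labels")
    if model.M.shape != (n, m):
        v.append(f"M has shape {model.M.shape}, expected ({n}, {m})")
    if model.E.shape != (n, p):
        v.append(f"E has shape {model.E.shape}, expected ({n}, {p})")
    if model.T.shape != (s, n):
        v.append(
            f"T has shape {model.T.shape}, expected ({s}, {n}): "
            "sensor rows must match sensor_labels and columns match state_labels"
        )
    if model.Q.shape != (p, p):
        v.append(f"Q has shape {model.Q.shape}, expected ({p}, {p})")
    if model.R.shape != (s, s):
        v.append(f"R has shape {model.R.shape}, expected ({s}, {s})")
    if not (model.dt > 0):
        v.append(f"dt must be > 0, got {model.dt}")
    if model.Q.shape == (p, p):
        if not _symmetric(model.Q):
            v.append("Q is not symmetric")
        else:
            if np.min(np.linalg.eigvalsh(model.Q)) < -1e-12:
                v.append("Q is not positive semi-definite")
    if model.R.shape == (s, s):
        if not _symmetric(model.R):
            v.append("R is not symmetric")
        else:
            if np.min(np.linalg.eigvalsh(model.R)) <= 0:
                v.append("R is not positive definite (a sensor has zero noise)")
    return v


def _check_len(vec: np.ndarray, n: int, what: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float).reshape(-1)
    if vec.shape[0] != n:
        raise ValueError(f"{what} has length {vec.shape[0]}, expected {n}")
    return vec


def predict(model: LinearModel, x_hat_prev: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Preliminary state estimate ``x_pred = D x_hat_prev + M u``."""
    x = _check_len(x_hat_prev, model.n_states, "x_hat_prev")
    u = _check_len(u, model.n_inputs, "u")
    return model.D @ x + model.M @ u


def innovate(
    model: LinearModel, x_pred: np.ndarray, s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted sensory signal and sensory error: ``(T x_pred, s - T x_pred)``."""
    x = _check_len(x_pred, model.n_states, "x_pred")
    s = _check_len(s, model.n_sensors, "s")
    s_pred = model.T @ x
    return s_pred, s - s_pred


def update(x_pred: np.ndarray, K: GainMatrix | np.ndarray, dS: np.ndarray) -> np.ndarray:
    """Corrected estimate ``x_hat = x_pred + K dS``."""
    Kmat = K.K if isinstance(K, GainMatrix) else np.asarray(K, dtype=float)
    x = np.asarray(x_pred, dtype=float).reshape(-1)
    dS = np.asarray(dS, dtype=float).reshape(-1)
    if Kmat.shape != (x.shape[0], dS.shape[0]):
        raise ValueError(
            f"gain shape {Kmat.shape} incompatible with state {x.shape[0]} "
            f"and error {dS.shape[0]}"
        )
    return x + Kmat @ dS


def steady_state_gain(
    model: LinearModel, tol: float = 1e-12, max_iter: int = 10**6
) -> GainMatrix:
    """Iterate the discrete Kalman covariance recursion to its fixed point.

    Starting from zero posterior covariance, repeat

        P_prior = D P_post D' + E Q E'
        K       = P_prior T' (T P_prior T' + R)^-1
        P_post  = (I - K T) P_prior

    until the max-abs change in ``K`` falls below ``tol``. The innovation
    covariance is handled with a linear solve (never an explicit inverse):
    with sensor noises as disparate as 0.175 rad/s and 0.002 g the system
    is poorly scaled. The posterior covariance is re-symmetrised every step.

    Raises ``numpy.linalg.LinAlgError`` if the innovation covariance is
    singular; returns ``converged=False`` (without raising) if ``max_iter``
    is exhausted first.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    problems = validate_model(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))

    n = model.n_states
    D, E, T, Q, R = model.D, model.E, model.T, model.Q, model.R
    EQE = E @ Q @ E.T
    P_post = np.zeros((n, n))
    K_prev: np.ndarray | None = None
    K = np.zeros((n, model.n_sensors))
    P_prior = EQE
    iterations = max_iter
    converged = False
    for i in range(1, max_iter + 1):
        P_prior = D @ P_post @ D.T + EQE
        innov = T @ P_prior @ T.T + R
        # K = P_prior T' innov^-1, via solve on the transposed system
        K = np.linalg.solve(innov.T, (P_prior @ T.T).T).T
        P_post = (np.eye(n) - K @ T) @ P_prior
        P_post = (P_post + P_post.T) / 2.0
        if K_prev is not None and np.max(np.abs(K - K_prev)) < tol:
            iterations = i
            converged = True
            break
        K_prev = K
    return GainMatrix(
        K=K,
        P_steady=P_prior,
        iterations=iterations,
        converged=converged,
        state_labels=model.state_labels,
        sensor_labels=model.sensor_labels,
    )
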