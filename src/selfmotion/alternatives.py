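"""Alternative processing schemes and extra-filter nonlinearities.

Two rejected architectures are simulated for side-by-side comparison with
the Kalman filter: (1) *sensory suppression*, where all feedback pathways
are inactivated during motion so estimates follow motor commands alone,
and (2) a *parallel scheme*, where a motor-only internal model and a
sensory-only estimator run independently and their difference plays the
role of a motion prediction error. Two nonlinearities that live outside
the linear filter are also provided: a proprioceptive-mismatch gate on the
motor-command input, and a static neck-offset modulation of proprioceptive
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .analysis import sinusoid_gain_phase
from .kalman import LinearModel, steady_state_gain
from .models import Params, make_neck_model
from .protocols import Protocol, sinusoid_protocol
from .simulate import Trajectory, generate_truth, run_filter, simulate

__all__ = [
    "ParallelSchemeResult",
    "simulate_sensory_suppression",
    "simulate_parallel_scheme",
    "mismatch_gate",
    "neck_offset_gain_modulation",
    "default_offset_scale",
    "DEFAULT_GATE_THRESHOLD",
]


@dataclass
class ParallelSchemeResult:
    """Outputs of the parallel motor/sensory scheme.

    ``merged = w_motor * motor_prediction + (1 - w_motor) * sensory_estimate``
    holds exactly by construction.
    """

    t: np.ndarray
    motor_prediction: np.ndarray  # (n_steps, n_states)
    sensory_estimate: np.ndarray
    prediction_error: np.ndarray
    merged: np.ndarray
    w_motor: float
    state_labels: tuple[str, ...]

    def state(self, label: str, which: str = "prediction_error") -> np.ndarray:
        i = self.state_labels.index(label)
        return getattr(self, {"motor": "motor_prediction", "sensory": "sensory_estimate",
                              "prediction_error": "prediction_error", "merged": "merged"}[which])[:, i]


def simulate_sensory_suppression(
    world: LinearModel, protocol: Protocol, seed: int | None = None
) -> Trajectory:
    """Run the filter with every feedback gain zeroed.

    Estimates then follow motor commands only: passive motion goes entirely
    undetected, which is the behaviour this scheme is rejected on.
    """
    K = steady_state_gain(world).zeroed()
    return simulate(world, protocol, seed=seed, K=K)


def simulate_parallel_scheme(
    world: LinearModel, protocol: Protocol, w_motor: float = 0.5, seed: int | None = None
) -> ParallelSchemeResult:
    """Independent motor and sensory branches compared by subtraction.

    The motor branch integrates commands through the true kinematics with
    no sensors; the sensory branch is the Kalman filter deprived of the
    commands. Their difference is a *motion* prediction error (as opposed
    to the sensory prediction error of the unified filter), and the final
    estimate is a ``w_motor``-weighted average of the two branches.
    """
    if not 0.0 <= w_motor <= 1.0:
        raise ValueError("w_motor must lie in [0, 1]")
    motor_protocol = Protocol(
        t=protocol.t.copy(),
        active={k: v.copy() for k, v in protocol.active.items()},
        passive={},
        mode=protocol.mode,
        name=protocol.name + "_motor_branch",
    )
    motor_prediction, _ = generate_truth(world, motor_protocol)
    _, S = generate_truth(world, protocol, seed=seed)
    K = steady_state_gain(world)
    commands = np.zeros((protocol.n_steps, world.n_inputs))
    sensory = run_filter(world, K, commands, S, t=protocol.t)
    err = motor_prediction - sensory.X_hat
    merged = w_motor * motor_prediction + (1.0 - w_motor) * sensory.X_hat
    return ParallelSchemeResult(
        t=protocol.t,
        motor_prediction=motor_prediction,
        sensory_estimate=sensory.X_hat,
        prediction_error=err,
        merged=merged,
        w_motor=w_motor,
        state_labels=world.state_labels,
    )


#: default proprioceptive-mismatch threshold (rad); about 6 proprioceptive
#: noise SDs, so the gate never trips on sensor noise alone.
DEFAULT_GATE_THRESHOLD = 0.01


def mismatch_gate(
    dP_series: np.ndarray,
    commands: np.ndarray,
    threshold: float = DEFAULT_GATE_THRESHOLD,
) -> np.ndarray:
    """Gate motor commands off while the proprioceptive error is large.

    Returns a copy of ``commands`` zeroed on every step where
    ``|dP| > threshold`` (from the first crossing until the error returns
    below threshold). Single threshold, no refractory period. The gated
    series is meant to be fed back into ``run_filter`` for re-simulation.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    dP = np.asarray(dP_series, dtype=float).reshape(-1)
    out = np.array(commands, dtype=float, copy=True)
    mask = np.abs(dP) > threshold
    out[mask] = 0.0
    return out


def default_offset_scale(offset: float) -> float:
    """Proprioceptive noise multiplier for a static neck offset.

    1 + 2|offset|: a 0.5 rad (~29 degree) offset doubles sigma_P. Stretched
    or slackened neck muscles report position less reliably; the exact
    mapping is a package convention (see the methods note).
    """
    return 1.0 + 2.0 * abs(offset)


def neck_offset_gain_modulation(
    params: Params | None = None,
    offset: float = 0.0,
    scale_fn: Callable[[float], float] = default_offset_scale,
    freq: float = 0.5,
    n_cycles: int = 10,
) -> dict[str, float]:
    """Response gains of simulated unimodal/bimodal units under a neck offset.

    Rebuilds the head-neck model with ``sigma_p * scale_fn(offset)`` and
    probes it with two passive sinusoids: whole-body rotation (vestibular
    stimulation: trunk and head move together) and trunk-under-head
    rotation (proprioceptive stimulation: the head stays earth-fixed). The
    "bimodal" gain is the trunk-velocity feedback amplitude relative to the
    trunk-velocity stimulus in each condition; the "unimodal" gain is the
    head-velocity feedback relative to head velocity during the
    whole-body condition (the head does not move in the other one).
    """
    p = params or Params()
    if not np.isclose(scale_fn(0.0), 1.0):
        raise ValueError("scale_fn(0) must be 1")
    p_mod = p.replace(sigma_p=p.sigma_p * float(scale_fn(offset)))
    model = make_neck_model(p_mod)
    K = steady_state_gain(model)
    duration = n_cycles / freq
    out: dict[str, float] = {"offset": float(offset), "sigma_p_scale": float(scale_fn(offset))}

    whole_body = sinusoid_protocol(p, freq, duration, mode="neck", channel="OmegaTS")
    traj = simulate(model, whole_body, K=K)
    stim = traj.state("OmegaTS", "true")
    trunk_fb = traj.feedback_series("OmegaTS")
    head_fb = traj.feedback_series("OmegaTS") + traj.feedback_series("OmegaHT")
    head_vel = traj.state("OmegaTS", "true") + traj.state("OmegaHT", "true")
    skip = traj.t > duration / 2  # steady-state window
    g, _ = sinusoid_gain_phase(trunk_fb[skip], stim[skip], freq, dt=p.dt)
    out["bimodal_gain_vestibular"] = g
    g, _ = sinusoid_gain_phase(head_fb[skip], head_vel[skip], freq, dt=p.dt)
    out["unimodal_gain"] = g

    trunk_under_head = sinusoid_protocol(
        p, freq, duration, mode="neck", channel="OmegaTS", mirror_channel="OmegaHT"
    )
    traj = simulate(model, trunk_under_head, K=K)
    stim = traj.state("OmegaTS", "true")
    trunk_fb = traj.feedback_series("OmegaTS")
    g, _ = sinusoid_gain_phase(trunk_fb[skip], stim[skip], freq, dt=p.dt)
    out["bimodal_gain_proprioceptive"] = g
    return out
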