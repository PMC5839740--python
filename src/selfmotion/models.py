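"""Model builders for the vestibular / proprioceptive estimation variants.

All variants share one parameter set (`Params`). The head-only model tracks
angular velocity Omega, the hidden canal state C, tilt G and linear
acceleration A; the semicircular canals report V = Omega - C (high-pass
dynamics with time constant tau_c) and the otoliths report F = G + A
(gravito-inertial ambiguity: tilt and small translations are expressed in
the same g-equivalent units, so the otoliths cannot tell them apart). The
head-neck variant tracks trunk-in-space velocity OmegaTS, head-on-trunk
velocity OmegaHT and neck position N = integral of OmegaHT; the canals
sense total head velocity OmegaTS + OmegaHT - C and neck proprioceptors
sense N.

Discretisation: angular velocity and acceleration have no persistence
(each step they equal command + perturbation), and the freshly drawn
velocity feeds the C and G (or N) integrators within the same step — the
couplings are carried in the M and E columns, not in D. This keeps
G = integral(Omega dt) lag-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .kalman import GainMatrix, LinearModel, steady_state_gain, validate_model

__all__ = [
    "Params",
    "GainTable",
    "GainEntry",
    "make_canal_model",
    "make_rotation_tilt_model",
    "make_neck_model",
    "add_visual_sensor",
    "ablate_canal_internal_model",
    "gain_table",
    "NEGLIGIBLE_COEFFICIENT",
    "SCALING_CLASSES",
]


@dataclass(frozen=True)
class Params:
    """Noise and dynamics parameters shared by every model variant.

    Units: velocities rad/s, accelerations and tilt g, neck position rad,
    times s. Defaults are the simulation values used throughout: priors
    sigma_omega / sigma_a on unpredicted rotation and acceleration, sensor
    noises sigma_v (canals), sigma_f (otoliths), sigma_vis (vision),
    sigma_p (neck proprioceptors), trunk / neck perturbation priors
    sigma_ts / sigma_ht, canal time constant tau_c and time step dt.
    """

    sigma_omega: float = 0.7
    sigma_a: float = 0.3
    sigma_v: float = 0.175
    sigma_f: float = 0.002
    sigma_vis: float = 0.12
    sigma_ts: float = 0.7
    sigma_ht: float = 3.5
    sigma_p: float = 0.0017
    tau_c: float = 4.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def replace(self, **changes) -> "Params":
        return replace(self, **changes)


def make_canal_model(params: Params | None = None) -> LinearModel:
    """Two-state rotation model (Omega, C) sensed by the canals only.

    This is the earth-vertical-axis rotation (EVAR) configuration used for
    gain reporting: rotation never tilts the head, so the otoliths carry
    no rotation information and are omitted.
    """
    p = params or Params()
    dt, tau = p.dt, p.tau_c
    D = np.array([[0.0, 0.0], [0.0, 1.0 - dt / tau]])
    M = np.array([[1.0], [dt / tau]])
    return LinearModel(
        D=D,
        M=M,
        E=M.copy(),
        T=np.array([[1.0, -1.0]]),
        Q=np.array([[p.sigma_omega**2]]),
        R=np.array([[p.sigma_v**2]]),
        dt=dt,
        state_labels=("Omega", "C"),
        input_labels=("Omega_u",),
        noise_labels=("Omega_eps",),
        sensor_labels=("V",),
        name="canal_evar",
    )


def make_rotation_tilt_model(
    params: Params | None = None,
    gravity_coupled: bool = True,
    include_otolith: bool = True,
) -> LinearModel:
    """Four-state head-motion model (Omega, C, G, A).

    Per step: Omega = command + perturbation (no persistence);
    C decays by (1 - dt/tau_c) and integrates dt/tau_c of the current
    Omega; G integrates dt * Omega when ``gravity_coupled`` (rotation about
    an earth-horizontal axis) and is frozen otherwise (EVAR); A = command +
    perturbation. Sensors: canals V = Omega - C always; otoliths F = G + A
    when ``include_otolith``.
    """
    p = params or Params()
    dt, tau = p.dt, p.tau_c
    D = np.zeros((4, 4))
    D[1, 1] = 1.0 - dt / tau
    D[2, 2] = 1.0
    M = np.zeros((4, 2))
    M[0, 0] = 1.0
    M[1, 0] = dt / tau
    if gravity_coupled:
        M[2, 0] = dt
    M[3, 1] = 1.0
    T_rows = [np.array([1.0, -1.0, 0.0, 0.0])]
    sensors = ["V"]
    R_diag = [p.sigma_v**2]
    if include_otolith:
        T_rows.append(np.array([0.0, 0.0, 1.0, 1.0]))
        sensors.append("F")
        R_diag.append(p.sigma_f**2)
    return LinearModel(
        D=D,
        M=M,
        E=M.copy(),
        T=np.vstack(T_rows),
        Q=np.diag([p.sigma_omega**2, p.sigma_a**2]),
        R=np.diag(R_diag),
        dt=dt,
        state_labels=("Omega", "C", "G", "A"),
        input_labels=("Omega_u", "A_u"),
        noise_labels=("Omega_eps", "A_eps"),
        sensor_labels=tuple(sensors),
        name="tilt_translation" if gravity_coupled else "evar",
    )


def make_neck_model(params: Params | None = None) -> LinearModel:
    """Head-neck model (OmegaTS, OmegaHT, N, C).

    Trunk-in-space and head-on-trunk velocities are independently
    commanded/perturbed; neck position N integrates OmegaHT; the canal
    state C integrates total head velocity OmegaTS + OmegaHT. Sensors:
    canals V = OmegaTS + OmegaHT - C and neck proprioceptors P = N
    (position coding).
    """
    p = params or Params()
    dt, tau = p.dt, p.tau_c
    D = np.zeros((4, 4))
    D[2, 2] = 1.0
    D[3, 3] = 1.0 - dt / tau
    M = np.zeros((4, 2))
    M[0, 0] = 1.0
    M[1, 1] = 1.0
    M[2, 1] = dt
    M[3, 0] = dt / tau
    M[3, 1] = dt / tau
    return LinearModel(
        D=D,
        M=M,
        E=M.copy(),
        T=np.array([[1.0, 1.0, 0.0, -1.0], [0.0, 0.0, 1.0, 0.0]]),
        Q=np.diag([p.sigma_ts**2, p.sigma_ht**2]),
        R=np.diag([p.sigma_v**2, p.sigma_p**2]),
        dt=dt,
        state_labels=("OmegaTS", "OmegaHT", "N", "C"),
        input_labels=("OmegaTS_u", "OmegaHT_u"),
        noise_labels=("OmegaTS_eps", "OmegaHT_eps"),
        sensor_labels=("V", "P"),
        name="head_neck",
    )


def add_visual_sensor(model: LinearModel, params: Params | None = None) -> LinearModel:
    """Append a visual rotation-velocity sensor (Vis = Omega, noise sigma_vis).

    On the head-neck model the visual sensor reads total head velocity
    OmegaTS + OmegaHT. Raises ``ValueError`` if the model has no rotation
    state.
    """
    p = params or Params()
    row = np.zeros(model.n_states)
    if "Omega" in model.state_labels:
        row[model.state_labels.index("Omega")] = 1.0
    elif "OmegaTS" in model.state_labels and "OmegaHT" in model.state_labels:
        row[model.state_labels.index("OmegaTS")] = 1.0
        row[model.state_labels.index("OmegaHT")] = 1.0
    else:
        raise ValueError("model has no rotation-velocity state to observe visually")
    T = np.vstack([model.T, row])
    s = model.n_sensors
    R = np.zeros((s + 1, s + 1))
    R[:s, :s] = model.R
    R[s, s] = p.sigma_vis**2
    return model.replace(
        T=T,
        R=R,
        sensor_labels=model.sensor_labels + ("Vis",),
        name=model.name + "+vis",
    )


def ablate_canal_internal_model(model: LinearModel) -> LinearModel:
    """Filter-side model with the canal dynamics removed.

    The canal sensor row becomes V = Omega (the internal C no longer enters
    the observation) and the C state is fully decoupled from dynamics and
    inputs, so the filter believes the canals are perfect velocity sensors.
    Intended to be used as the *filter* model while the world keeps true
    canal dynamics.
    """
    if "C" not in model.state_labels:
        raise ValueError("model has no canal state C to ablate")
    c = model.state_labels.index("C")
    D = model.D.copy()
    D[c, :] = 0.0
    D[:, c] = 0.0
    M = model.M.copy()
    M[c, :] = 0.0
    E = model.E.copy()
    E[c, :] = 0.0
    T = model.T.copy()
    T[:, c] = 0.0
    return model.replace(D=D, M=M, E=E, T=T, name=model.name + "_no_canal_im")


SCALING_CLASSES = ("constant", "proportional_to_dt", "proportional_to_inv_dt")
_CLASS_POWER = {"constant": 0, "proportional_to_dt": 1, "proportional_to_inv_dt": -1}
NEGLIGIBLE_COEFFICIENT = 0.05


@dataclass
class GainEntry:
    state: str
    sensor: str
    value: float  # raw gain at the reference dt
    scaling_class: str
    coefficient: float  # value normalised by its dt power at the reference dt
    spread: float  # relative spread of the coefficient across the dt sweep
    stable: bool  # spread <= 5%
    negligible: bool  # judged by influence: raw gain for memoryless states,
    # normalised coefficient for persistent (integrator) states


@dataclass
class GainTable:
    """Steady-state gains classified by their time-step scaling.

    Some feedback gains are genuinely dimensionless (e.g. the canal-error
    to velocity gain near 0.94); others represent an integration per step
    and scale with dt (e.g. the tilt feedback), or a differentiation and
    scale with 1/dt (the proprioceptive velocity feedbacks). Each entry is
    assigned the scaling class whose normalised coefficient varies least
    across the dt sweep; ``stable`` records whether that variation is
    within 5%.
    """

    entries: list[GainEntry]
    dts: tuple[float, ...]
    reference_dt: float
    model_name: str = ""

    def entry(self, state: str, sensor: str) -> GainEntry:
        for e in self.entries:
            if e.state == state and e.sensor == sensor:
                return e
        raise KeyError((state, sensor))

    def coefficient(self, state: str, sensor: str) -> float:
        return self.entry(state, sensor).coefficient

    def report(self) -> str:
        lines = [
            f"# steady-state Kalman feedback gains: {self.model_name}",
            f"# dt sweep: {list(self.dts)}  reference dt: {self.reference_dt}",
            "state\tsensor\tcoefficient\tscaling_class\tstable\tnegligible",
        ]
        for e in self.entries:
            lines.append(
                f"{e.state}\t{e.sensor}\t{e.coefficient:.2f}\t{e.scaling_class}"
                f"\t{e.stable}\t{e.negligible}"
            )
        return "\n".join(lines) + "\n"


def _classify(values_by_dt: dict[float, float], reference_dt: float) -> tuple[str, float, float]:
    """Pick the dt-power normalisation with the least relative spread."""
    best = None
    for cls, power in _CLASS_POWER.items():
        coeffs = np.array([v / dt**power for dt, v in values_by_dt.items()])
        scale = max(np.max(np.abs(coeffs)), 1e-30)
        spread = float((np.max(coeffs) - np.min(coeffs)) / scale)
        if best is None or spread < best[2]:
            ref = values_by_dt[reference_dt] / reference_dt**power
            best = (cls, float(ref), spread)
    return best


def gain_table(
    build: Callable[[Params], LinearModel],
    params: Params | None = None,
    dts: Sequence[float] = (0.005, 0.01, 0.02),
    reference_dt: float | None = None,
) -> GainTable:
    """Compute and classify steady-state gains across a dt sweep.

    ``build`` rebuilds the model from continuous-time parameters at each
    dt (e.g. ``make_rotation_tilt_model`` or a ``functools.partial`` of
    it), holding everything but the time step fixed.
    """
    p = params or Params()
    reference_dt = reference_dt if reference_dt is not None else p.dt
    if reference_dt not in dts:
        dts = tuple(dts) + (reference_dt,)
    gains: dict[float, GainMatrix] = {}
    for dt in dts:
        model = build(p.replace(dt=dt))
        gains[dt] = steady_state_gain(model)
    ref_model = build(p.replace(dt=reference_dt))
    entries: list[GainEntry] = []
    for i, state in enumerate(ref_model.state_labels):
        for sensor in ref_model.sensor_labels:
            values = {dt: g.entry(state, sensor) for dt, g in gains.items()}
            cls, coeff, spread = _classify(values, reference_dt)
            # A dt-sized gain onto a memoryless state (no diagonal persistence)
            # never accumulates, so its influence is its raw value; onto an
            # integrator state it compounds, so the normalised coefficient is
            # what matters.
            persistent = abs(ref_model.D[i, i]) >= 0.5
            influence = coeff if persistent else values[reference_dt]
            entries.append(
                GainEntry(
                    state=state,
                    sensor=sensor,
                    value=values[reference_dt],
                    scaling_class=cls,
                    coefficient=coeff,
                    spread=spread,
                    stable=spread <= 0.05,
                    negligible=abs(influence) <= NEGLIGIBLE_COEFFICIENT,
                )
            )
    return GainTable(
        entries=entries,
        dts=tuple(dts),
        reference_dt=reference_dt,
        model_name=ref_model.name,
    )
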