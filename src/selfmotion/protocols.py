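"""Motion protocol library: active commands and passive perturbations.

Every preset exists in an ``_active`` and a ``_passive`` variant carrying
the same velocity (or acceleration) profile on the command or the
perturbation channel respectively, so the true motion is identical and
only the estimator's information differs. Amplitudes default to 1 (rad/s
or g): the model is linear, so every downstream claim is scale-invariant.

Profiles: trapezoids (ramps of one-tenth the stimulus duration on each
side) for the short 0.2-s and 2-s stimuli, Gaussian velocity bumps
(SD = duration / 6) for the superposition paradigms, and plain steps for
the long-duration stimuli, which do not return to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .models import Params

__all__ = [
    "Protocol",
    "make_preset",
    "combine",
    "random_protocol",
    "sinusoid_protocol",
    "step_protocol",
    "PRESETS",
    "preset_names",
]

#: channels (base names) per protocol mode
MODE_CHANNELS = {
    "evar": ("Omega", "A"),
    "tilt": ("Omega", "A"),
    "translation": ("Omega", "A"),
    "neck": ("OmegaTS", "OmegaHT"),
}


@dataclass
class Protocol:
    """Time-indexed active commands and passive perturbations.

    ``active`` maps command labels (``<channel>_u``) and ``passive`` maps
    perturbation labels (``<channel>_eps``) to series on the shared grid
    ``t``. ``mode`` selects the model variant the protocol is meant for.
    """

    t: np.ndarray
    active: dict[str, np.ndarray]
    passive: dict[str, np.ndarray]
    mode: str
    name: str = "protocol"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        for d in (self.active, self.passive):
            for k in d:
                d[k] = np.asarray(d[k], dtype=float)
                if d[k].shape != (n,):
                    raise ValueError(f"channel {k} length {d[k].shape} != grid {n}")
        if self.mode not in MODE_CHANNELS:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_steps(self) -> int:
        return self.t.shape[0]

    def series(self, labels: tuple[str, ...], which: str) -> np.ndarray:
        """Stack the named channels into an (n_steps, len(labels)) array.

        Missing channels are zero-filled, so a protocol that only specifies
        rotation drives a model with an acceleration input cleanly.
        """
        d = self.active if which == "active" else self.passive
        out = np.zeros((self.n_steps, len(labels)))
        for j, lab in enumerate(labels):
            if lab in d:
                out[:, j] = d[lab]
        return out


def _grid(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt))
    return np.arange(1, n + 1) * dt


def _trapezoid(t: np.ndarray, start: float, duration: float, ramp_fraction: float = 0.1) -> np.ndarray:
    ramp = ramp_fraction * duration
    up, plateau_end, end = start + ramp, start + duration - ramp, start + duration
    v = np.zeros_like(t)
    rising = (t > start) & (t < up)
    v[rising] = (t[rising] - start) / ramp
    v[(t >= up) & (t <= plateau_end)] = 1.0
    falling = (t > plateau_end) & (t < end)
    v[falling] = (end - t[falling]) / ramp
    return v


def _gaussian(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    mu = start + duration / 2.0
    sd = duration / 6.0
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def _step(t: np.ndarray, start: float) -> np.ndarray:
    return (t >= start).astype(float)


@dataclass(frozen=True)
class _Preset:
    mode: str
    channel: str  # base channel carrying the profile
    profile: str  # trapezoid | gaussian | step
    stim_duration: float
    total_duration: float
    lead_in: float
    mirror_channel: str | None = None  # set for trunk-under-head: gets -profile
    returns_to_zero: bool = True


PRESETS: dict[str, _Preset] = {
    "rotation_0p2s": _Preset("evar", "Omega", "trapezoid", 0.2, 1.0, 0.1),
    "rotation_2s": _Preset("evar", "Omega", "trapezoid", 2.0, 6.0, 0.5),
    "rotation_60s": _Preset("evar", "Omega", "step", 60.0, 60.0, 0.0, returns_to_zero=False),
    "rotation_gaussian": _Preset("evar", "Omega", "gaussian", 2.0, 6.0, 0.5),
    "tilt_0p2s": _Preset("tilt", "Omega", "trapezoid", 0.2, 1.0, 0.1),
    "tilt_2s": _Preset("tilt", "Omega", "trapezoid", 2.0, 6.0, 0.5),
    "tilt_gaussian": _Preset("tilt", "Omega", "gaussian", 2.0, 6.0, 0.5),
    "translation_0p2s": _Preset("translation", "A", "trapezoid", 0.2, 1.0, 0.1),
    "translation_2s": _Preset("translation", "A", "trapezoid", 2.0, 6.0, 0.5),
    "translation_20s": _Preset("translation", "A", "step", 20.0, 20.0, 0.0, returns_to_zero=False),
    "translation_gaussian": _Preset("translation", "A", "gaussian", 2.0, 6.0, 0.5),
    "whole_body": _Preset("neck", "OmegaTS", "trapezoid", 2.0, 6.0, 0.5),
    "head_on_trunk": _Preset("neck", "OmegaHT", "trapezoid", 2.0, 6.0, 0.5),
    "trunk_under_head": _Preset(
        "neck", "OmegaTS", "trapezoid", 2.0, 6.0, 0.5, mirror_channel="OmegaHT"
    ),
}

_PROFILE_FN: dict[str, Callable] = {
    "trapezoid": lambda t, pr: _trapezoid(t, pr.lead_in, pr.stim_duration),
    "gaussian": lambda t, pr: _gaussian(t, pr.lead_in, pr.stim_duration),
    "step": lambda t, pr: _step(t, pr.lead_in),
}


def preset_names() -> list[str]:
    """All valid preset names (each base name in _active and _passive form)."""
    return sorted(f"{base}_{var}" for base in PRESETS for var in ("active", "passive"))


def make_preset(name: str, params: Params | None = None, amplitude: float = 1.0) -> Protocol:
    """Build a named stimulus protocol.

    ``name`` is ``<base>_active`` or ``<base>_passive``; the profile goes
    on the command channels in the first case and on the perturbation
    channels in the second, leaving the true motion identical.
    """
    p = params or Params()
    for suffix, which in (("_active", "active"), ("_passive", "passive")):
        if name.endswith(suffix):
            base = name[: -len(suffix)]
            break
    else:
        raise ValueError(
            f"unknown preset {name!r}: names end in _active/_passive; "
            f"registry: {preset_names()}"
        )
    if base not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; registry: {preset_names()}")
    pr = PRESETS[base]
    t = _grid(pr.total_duration, p.dt)
    profile = amplitude * _PROFILE_FN[pr.profile](t, pr)
    channels = {pr.channel: profile}
    if pr.mirror_channel is not None:
        channels[pr.mirror_channel] = -profile
    suffix_map = {"active": "_u", "passive": "_eps"}
    series = {ch + suffix_map[which]: v for ch, v in channels.items()}
    active = series if which == "active" else {}
    passive = series if which == "passive" else {}
    return Protocol(t=t, active=active, passive=passive, mode=pr.mode, name=name)


def step_protocol(
    params: Params,
    duration: float,
    mode: str = "evar",
    channel: str = "Omega",
    amplitude: float = 1.0,
    which: str = "passive",
    stim_duration: float | None = None,
) -> Protocol:
    """Constant-amplitude stimulus from t=0 (optionally ending early)."""
    t = _grid(duration, params.dt)
    v = np.full_like(t, amplitude)
    if stim_duration is not None:
        v = np.where(t <= stim_duration, amplitude, 0.0)
    key = channel + ("_u" if which == "active" else "_eps")
    return Protocol(
        t=t,
        active={key: v} if which == "active" else {},
        passive={key: v} if which == "passive" else {},
        mode=mode,
        name=f"step_{channel}_{which}",
    )


def sinusoid_protocol(
    params: Params,
    freq: float,
    duration: float,
    mode: str = "neck",
    channel: str = "OmegaTS",
    amplitude: float = 1.0,
    which: str = "passive",
    mirror_channel: str | None = None,
) -> Protocol:
    """Sinusoidal velocity stimulus, optionally with a counter-rotating channel."""
    t = _grid(duration, params.dt)
    v = amplitude * np.sin(2 * np.pi * freq * t)
    channels = {channel: v}
    if mirror_channel is not None:
        channels[mirror_channel] = -v
    suffix = "_u" if which == "active" else "_eps"
    series = {ch + suffix: s for ch, s in channels.items()}
    return Protocol(
        t=t,
        active=series if which == "active" else {},
        passive=series if which == "passive" else {},
        mode=mode,
        name=f"sine_{channel}_{freq}Hz_{which}",
    )


def combine(a: Protocol, b: Protocol) -> Protocol:
    """Channel-wise sum of two protocols on the same grid and mode."""
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode} vs {b.mode}")
    if a.n_steps != b.n_steps or abs(a.dt - b.dt) > 1e-12:
        raise ValueError("time grids do not match")
    active = {k: v.copy() for k, v in a.active.items()}
    passive = {k: v.copy() for k, v in a.passive.items()}
    for k, v in b.active.items():
        active[k] = active.get(k, 0.0) + v
    for k, v in b.passive.items():
        passive[k] = passive.get(k, 0.0) + v
    return Protocol(
        t=a.t.copy(), active=active, passive=passive, mode=a.mode,
        name=f"{a.name}+{b.name}",
    )


def random_protocol(
    params: Params, seed: int, duration: float, mode: str = "evar"
) -> Protocol:
    """Perturbations drawn i.i.d. per step from the model's own priors.

    Passive channels are white Gaussian with the prior SDs (sigma_omega /
    sigma_a, or sigma_ts / sigma_ht for the neck mode); active channels are
    zero. Reproducible from ``seed``.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    p = params or Params()
    rng = np.random.default_rng(seed)
    t = _grid(duration, p.dt)
    sds = {
        "Omega": p.sigma_omega,
        "A": p.sigma_a,
        "OmegaTS": p.sigma_ts,
        "OmegaHT": p.sigma_ht,
    }
    passive = {
        ch + "_eps": rng.normal(0.0, sds[ch], size=t.shape[0])
        for ch in MODE_CHANNELS[mode]
    }
    return Protocol(t=t, active={}, passive=passive, mode=mode, name=f"random_{mode}_{seed}")
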