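"""Derived metrics: decay time constants, sinusoidal gain/phase, attenuation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricReport",
    "fit_exponential_time_constant",
    "sinusoid_gain_phase",
    "attenuation_index",
]


@dataclass
class MetricReport:
    name: str
    value: float
    units: str
    residual_rms: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"metric {self.name} is not finite")


def fit_exponential_time_constant(
    t: np.ndarray, series: np.ndarray, window: tuple[float, float], name: str = "tau"
) -> MetricReport:
    """Least-squares fit of log(series) vs t on the window; returns tau (s).

    The series must be strictly positive on the window (flip the sign
    beforehand for decaying negative signals).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(series, dtype=float)
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 3:
        raise ValueError("window contains fewer than 3 samples")
    yw = y[mask]
    if np.any(yw <= 0):
        raise ValueError("series must be strictly positive on the fit window")
    slope, intercept = np.polyfit(t[mask], np.log(yw), 1)
    if slope >= 0:
        raise ValueError("series does not decay on the fit window")
    resid = np.log(yw) - (slope * t[mask] + intercept)
    return MetricReport(
        name=name,
        value=float(-1.0 / slope),
        units="s",
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        window=(float(t0), float(t1)),
    )


def sinusoid_gain_phase(
    series: np.ndarray, stimulus: np.ndarray, freq: float, dt: float
) -> tuple[float, float]:
    """Amplitude ratio and phase lead (deg) of ``series`` re ``stimulus`` at ``freq``.

    Both series are projected onto sin/cos at the stimulus frequency by
    least squares (a constant term absorbs offsets). Requires at least
    three full cycles.
    """
    series = np.asarray(series, dtype=float).reshape(-1)
    stimulus = np.asarray(stimulus, dtype=float).reshape(-1)
    if series.shape != stimulus.shape:
        raise ValueError("series and stimulus must share a grid")
    n = series.shape[0]
    if n * dt * freq < 3.0:
        raise ValueError("need at least 3 cycles at the requested frequency")
    t = np.arange(1, n + 1) * dt
    X = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t), np.ones(n)]
    )
    def phasor(y: np.ndarray) -> complex:
        a, b, _ = np.linalg.lstsq(X, y, rcond=None)[0]
        # y ~ a sin + b cos = Re[(b + i a) e^{-i w t}] convention: amplitude/phase
        return complex(a, b)
    zr, zs = phasor(series), phasor(stimulus)
    if abs(zs) == 0:
        raise ValueError("stimulus has no component at the requested frequency")
    ratio = zr / zs
    gain = abs(ratio)
    phase = float(np.degrees(np.angle(ratio)))
    return float(gain), phase


def attenuation_index(active_peak_source, passive_peak_source, signal: str | None = None) -> float:
    """1 - (peak |signal| active / peak |signal| passive), in [0, 1] typically.

    Accepts either two 1-D arrays, or two trajectories plus a ``signal``
    label resolved against sensory errors (a sensor label) or feedback
    series (``"state__sensor"``).
    """

    def resolve(src) -> np.ndarray:
        if isinstance(src, np.ndarray):
            return src
        if signal is None:
            raise ValueError("signal label required when passing trajectories")
        if signal in src.sensor_labels:
            return src.sensor(signal, "err")
        if "__" in signal:
            state, sensor = signal.split("__", 1)
            return src.feedback_series(state, sensor)
        raise ValueError(f"cannot resolve signal {signal!r}")

    a = np.abs(resolve(active_peak_source)).max()
    p = np.abs(resolve(passive_peak_source)).max()
    if p == 0:
        raise ValueError("passive peak is zero; attenuation undefined")
    return float(1.0 - a / p)
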