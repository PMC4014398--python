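"""Stimulus protocols: suprathreshold current pulses and filtered-noise drive.

The naturalistic drive used for spike trains is zero-mean Gaussian white
noise passed through a first-order low-pass filter (−3 dB corner frequency in
kHz) and scaled so its stationary standard deviation equals the request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["StimulusProtocol", "make_filtered_noise", "make_pulse", "realize_stimulus"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative stimulus description.

    kind ``single_pulse``: rectangular pulse of ``amplitude`` nA for
    ``duration`` ms from t = 0.  kind ``filtered_white_noise``: zero-mean
    noise current with standard deviation ``amplitude`` nA low-passed at
    ``corner_frequency`` kHz.
    """

    kind: str  # {"single_pulse", "filtered_white_noise"}
    amplitude: float  # nA (pulse amplitude, or noise SD)
    duration: float  # ms
    corner_frequency: float = 1.0  # kHz, noise only
    injection_site: float = 0.0  # fraction of axon length
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("single_pulse", "filtered_white_noise"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")


def make_pulse(amplitude: float, pulse_duration: float, dt: float,
               t_end: float) -> np.ndarray:
    """Rectangular current pulse (nA) sampled at dt over [0, t_end)."""
    n = int(round(t_end / dt))
    stim = np.zeros(n)
    stim[: int(round(pulse_duration / dt))] = amplitude
    return stim


def make_filtered_noise(sd: float, corner: float, dt: float, duration: float,
                        rng: np.random.Generator, state: float | None = None):
    """Zero-mean low-pass-filtered Gaussian noise current.

    Parameters
    ----------
    sd
        Target stationary standard deviation, nA.
    corner
        −3 dB corner frequency, kHz (must be below the Nyquist rate 1/(2·dt)).
    dt, duration
        Sample interval and length, ms.
    rng
        Source of randomness; reproducible from its seed.
    state
        Filter output at the preceding sample, to continue a stream across
        chunks seamlessly.  ``None`` draws the initial value from the
        stationary distribution.

    Returns
    -------
    (series, state) — the noise samples and the final filter state.

    The filter is first-order (exponential smoothing), y_k = y_{k-1} +
    a·(x_k − y_{k-1}) with a = 1 − exp(−2π·f_c·dt); the white-noise input SD
    is pre-scaled analytically so the *stationary output* SD equals ``sd``,
    which keeps chunked streams statistically continuous.
    """
    if corner >= 0.5 / dt:
        raise ValueError(f"corner {corner} kHz at or above Nyquist for dt={dt} ms")
    n = int(round(duration / dt))
    a = 1.0 - np.exp(-2.0 * np.pi * corner * dt)
    sd_in = sd * np.sqrt((2.0 - a) / a)
    x = rng.normal(0.0, sd_in, size=n)
    if state is None:
        y0 = rng.normal(0.0, sd)
    else:
        y0 = float(state)
    y, zf = signal.lfilter([a], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * y0])
    return y, float(y[-1]) if n else y0


def realize_stimulus(proto: StimulusProtocol, dt: float, t_end: float,
                     rng: np.random.Generator | None = None,
                     state: float | None = None):
    """Sample a stimulus protocol onto a dt grid; returns (series, state)."""
    if proto.kind == "single_pulse":
        return make_pulse(proto.amplitude, proto.duration, dt, t_end), None
    if rng is None:
        rng = np.random.default_rng(proto.seed)
    return make_filtered_noise(proto.amplitude, proto.corner_frequency, dt,
                               t_end, rng, state=state)
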