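"""Shared analytic waveforms."""

from __future__ import annotations

import numpy as np

__all__ = ["biexp_kernel", "biexp_peak_time", "biexp_peak_value", "biexp_charge"]


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the peak of exp(-t/tau_decay) - exp(-t/tau_rise)."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    return np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def biexp_peak_value(tau_rise: float, tau_decay: float) -> float:
    t_star = biexp_peak_time(tau_rise, tau_decay)
    return np.exp(-t_star / tau_decay) - np.exp(-t_star / tau_rise)


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Peak-normalised difference-of-exponentials, zero for t < 0."""
    w = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    return w / biexp_peak_value(tau_rise, tau_decay)


def biexp_charge(amplitude: float, tau_rise: float, tau_decay: float) -> float:
    """Integral of the peak-normalised kernel scaled to ``amplitude``.

    With time constants in ms and amplitude in pA the result is pA*ms
    (1 pA*ms = 1e-3 pC).
    """
    return amplitude * (tau_decay - tau_rise) / biexp_peak_value(tau_rise, tau_decay)
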