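"""Low-pass filtering shared by the generators and the amperometric analysis.

The acquisition chain is emulated with a Gaussian FIR low-pass whose -3 dB
point sits at the stated cutoff.  For a Gaussian kernel with time-domain
standard deviation ``sigma_t`` the amplitude response is
``H(f) = exp(-2 pi^2 f^2 sigma_t^2)``; requiring ``|H(fc)| = 1/sqrt(2)``
gives ``sigma_t = sqrt(ln 2) / (2 pi fc)``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["gaussian_lowpass", "gaussian_sigma_samples"]


def gaussian_sigma_samples(sample_rate_hz: float, cutoff_hz: float) -> float:
    """Kernel SD in samples for a -3 dB point at ``cutoff_hz``."""
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    return sigma_t * sample_rate_hz


def gaussian_lowpass(x: np.ndarray, sample_rate_hz: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass with -3 dB at ``cutoff_hz``."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    sigma = gaussian_sigma_samples(sample_rate_hz, cutoff_hz)
    if sigma < 1e-3:
        return np.asarray(x, dtype=float).copy()
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma, mode="nearest")
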