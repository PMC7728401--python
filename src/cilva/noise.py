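"""Per-neuron imaging-noise variance from the high-frequency power spectrum.

Calcium transients are slow relative to typical imaging rates, so the power
spectral density (PSD) of a trace above fs/4 is dominated by the flat floor of
the additive imaging noise.  Averaging the PSD over the open band
(fs/4, fs/2) and rescaling by fs/2 yields an estimator that is unbiased for
the variance of white Gaussian noise, since a one-sided density for white
noise of variance v is flat at 2 v / fs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .core import FluorescenceMatrix

__all__ = ["NoiseEstimate", "estimate_noise_variance"]

_MIN_FRAMES = 64


@dataclass
class NoiseEstimate:
    """Estimated imaging-noise variances and the frequency band used."""

    sigma2: np.ndarray
    band: tuple[float, float]


def estimate_noise_variance(F: FluorescenceMatrix) -> NoiseEstimate:
    """Estimate sigma_n^2 as the scaled mean PSD over (fs/4, fs/2).

    Welch's method with Hann-tapered, 50%-overlapping segments of length
    min(256, T // 4).  Frequencies strictly inside the open interval
    (fs/4, fs/2) are averaged; the endpoint bins are excluded.
    """
    T = F.n_frames
    if T < _MIN_FRAMES:
        raise ValueError(f"need at least {_MIN_FRAMES} frames for spectral estimation, got {T}")
    fs = F.fs
    nperseg = min(256, T // 4)
    freqs, psd = welch(
        F.values, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant", scaling="density", axis=1,
    )
    band = (freqs > fs / 4) & (freqs < fs / 2)
    if not band.any():
        raise ValueError("no PSD bins strictly inside (fs/4, fs/2); increase T")
    sigma2 = psd[:, band].mean(axis=1) * fs / 2.0
    return NoiseEstimate(sigma2=sigma2, band=(fs / 4, fs / 2))
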