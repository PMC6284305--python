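"""Gaussian display smoothing with edge renormalisation.

The kernel spans +/- window/2 with sigma = window/4; at series edges and
around missing points the kernel is renormalised over the available mass, so
a constant series is exactly preserved.
"""

from __future__ import annotations

import warnings

import numpy as np


def gaussian_kernel(window: int) -> np.ndarray:
    if window <= 0:
        raise ValueError("window must be positive")
    half = max(int(window // 2), 1)
    x = np.arange(-half, half + 1, dtype=float)
    sigma = window / 4.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(series, window: int) -> np.ndarray:
    """Smooth a 1-D series; NaNs are excluded from the kernel mass."""
    values = np.asarray(series, dtype=float)
    if window >= len(values):
        warnings.warn("smoothing window exceeds series length; returning the "
                      "global weighted mean everywhere")
    kernel = gaussian_kernel(window)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    if window >= len(values):
        if finite.any():
            out[:] = np.average(values[finite])
        else:
            out[:] = np.nan
    return out
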