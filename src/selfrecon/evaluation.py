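"""Reconstruction quality metrics: k-space NMSE, RSS images, SSIM.

NMSE is computed in k-space, ``||yhat - y0||^2 / ||y0||^2`` over all coils
and locations.  Because the package uses the unitary centred FFT throughout,
Parseval's identity makes this equal to the coil-image NMSE.  SSIM follows
the common fastMRI evaluation convention (7x7 uniform window, K1 = 0.01,
K2 = 0.03, data range set by the reference maximum) on magnitude images.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

from ._fft import ifft2c

__all__ = ["nmse", "rss_image", "ssim"]


def nmse(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Normalized mean squared error ``||yhat - y0||^2 / ||y0||^2``."""
    est = np.asarray(getattr(estimate, "array", estimate))
    ref = np.asarray(getattr(reference, "array", reference))
    if est.shape != ref.shape:
        raise ValueError("estimate and reference shapes differ")
    denom = float(np.sum(np.abs(ref) ** 2))
    if denom == 0:
        raise ValueError("reference has zero energy")
    return float(np.sum(np.abs(est - ref) ** 2)) / denom


def rss_image(y: np.ndarray, crop: Optional[int] = 320) -> np.ndarray:
    """Root-sum-of-squares image ``(sum_c |F^H y_c|^2)^(1/2)``.

    Centrally crops to ``crop x crop`` when the grid is at least that
    large; otherwise the full image is returned with a warning (synthetic
    grids are usually smaller than the 320-pixel evaluation crop used for
    scanner data).
    """
    arr = np.asarray(getattr(y, "array", y))
    if arr.ndim != 3:
        raise ValueError("expected (coils, H, W) k-space")
    img = np.sqrt(np.sum(np.abs(ifft2c(arr)) ** 2, axis=0))
    H, W = img.shape
    if crop is None:
        return img
    if crop > H or crop > W:
        warnings.warn(
            f"crop {crop} exceeds grid {H}x{W}; returning uncropped image",
            RuntimeWarning,
            stacklevel=2,
        )
        return img
    r0 = H // 2 - crop // 2
    c0 = W // 2 - crop // 2
    return img[r0 : r0 + crop, c0 : c0 + crop]


def ssim(estimate_image: np.ndarray, reference_image: np.ndarray) -> float:
    """Structural similarity between magnitude images.

    Data range is the reference maximum; window and stabilisation constants
    follow the standard evaluation convention (7x7, K1=0.01, K2=0.03).
    """
    est = np.abs(np.asarray(estimate_image, dtype=float))
    ref = np.abs(np.asarray(reference_image, dtype=float))
    if est.shape != ref.shape:
        raise ValueError("image shapes differ")
    data_range = float(ref.max())
    if data_range == 0:
        data_range = 1.0
    return float(
        structural_similarity(
            ref, est, data_range=data_range, win_size=7, K1=0.01, K2=0.03
        )
    )
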