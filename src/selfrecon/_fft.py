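"""Centered, unitary 2D Fourier transforms.

The whole package uses the orthonormal ("ortho") convention with the
zero-frequency component at the grid centre ``(H//2, W//2)``.  Under this
convention Parseval's identity holds exactly, so squared-error metrics agree
between k-space and the image domain.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c"]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(y: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(y, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )
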