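"""Reconstruction estimators: data-consistency wrappers and a compact
unrolled network.

The trainable estimator is a small physics-guided unrolled architecture in
the spirit of gradient-descent unrolling: each block moves between k-space
and the coil-combined image domain, applies a learned image-domain
refinement, and takes a soft data-consistency step toward the acquired
samples.  Keeping the refinement *linear* (a complex convolution kernel per
block) makes every operation complex-linear, so exact gradients follow from
Wirtinger calculus and the whole model trains with a plain numpy Adam — no
autograd framework is involved.

Given the encoding operator ``E x = F (S_c x)`` (coil-wise sensitivity
modulation followed by the centred unitary FFT) one block maps the k-space
state ``kappa`` to

    x      = E^H kappa                            (coil-combined image)
    kappa' = kappa + E conv(x, w_b) + c_b . kappa  (learned refinement)
    kappa  <- kappa' - eta_b M (kappa' - y)        (soft data consistency)

where ``conv(., w_b)`` is a small complex image-domain kernel and ``c_b``
is a learnable complex per-column k-space scaling — a density-compensation
term matched to column-wise sampling, whose ideal linear correction is a
per-column reweighting of the zero-filled data.  ``kappa`` is initialised
to the zero-filled input; with all refinement parameters at zero the
network is exactly the identity on its input, so the untrained model
returns the dc-filled measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._fft import fft2c, ifft2c
from .masks import Mask

__all__ = [
    "SupportMask",
    "dc_wrap",
    "apply_support",
    "UnrolledReconstructor",
    "AdamState",
]


@dataclass
class SupportMask:
    """Binary indicator of valid (non-zero-padded) k-space."""

    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("support indicator must be binary")
        self.indicator = ind.astype(np.uint8)


def dc_wrap(g_out: np.ndarray, y_tilde: np.ndarray, combined_mask: Mask) -> np.ndarray:
    """Hard data-consistency wrapper ``(1 - M) g + ytilde``.

    ``combined_mask`` is the elementwise product mask of the acquisition and
    partition masks; on its support the output equals ``y_tilde`` exactly,
    elsewhere it is the raw network output.  Wrapping guarantees the
    consistency precondition of the loss decomposition.
    """
    g = np.asarray(g_out)
    yt = np.asarray(y_tilde)
    if g.shape != yt.shape:
        raise ValueError("shapes do not match")
    m = combined_mask.astype(float)
    return (1.0 - m) * g + yt


def apply_support(f_out: np.ndarray, support: SupportMask) -> np.ndarray:
    """Zero the estimate outside the valid k-space support."""
    return np.asarray(f_out) * support.indicator


def _kernel_pad(w: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed a centred (kh, kw) kernel into an (H, W) circular-convolution array."""
    kh, kw = w.shape
    H, W = shape
    pad = np.zeros((H, W), dtype=complex)
    rows = (np.arange(kh) - kh // 2) % H
    cols = (np.arange(kw) - kw // 2) % W
    pad[np.ix_(rows, cols)] = w
    return pad


def _cconv(x: np.ndarray, w_pad_hat: np.ndarray) -> np.ndarray:
    """Circular convolution via the (plain) FFT, kernel given in Fourier form."""
    return np.fft.ifft2(np.fft.fft2(x) * w_pad_hat)


class UnrolledReconstructor:
    """Compact unrolled k-space reconstruction network (numpy, linear blocks).

    Parameters
    ----------
    n_blocks : int
        Number of unrolled refinement/data-consistency blocks.
    kernel_size : int
        Side of the complex image-domain convolution kernel per block
        (the "refinement width").
    seed : int, optional
        Seed for (tiny) random initialisation; with ``init_scale=0`` the
        kernels start at exactly zero and the untrained network is the
        identity on its input.
    """

    def __init__(
        self,
        n_blocks: int = 4,
        kernel_size: int = 5,
        init_scale: float = 0.0,
        seed: Optional[int] = None,
        grid_width: Optional[int] = None,
    ) -> None:
        if n_blocks < 1:
            raise ValueError("need at least one block")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        rng = np.random.default_rng(seed)
        k = kernel_size
        self.kernels = [
            init_scale * (rng.standard_normal((k, k)) + 1j * rng.standard_normal((k, k)))
            for _ in range(n_blocks)
        ]
        self.etas = [1.0 for _ in range(n_blocks)]
        # per-column k-space scalings; materialised lazily once the grid
        # width is known (they are grid-dependent parameters)
        self.col_scales: Optional[list[np.ndarray]] = None
        if grid_width is not None:
            self._ensure_col_scales(grid_width)

    def _ensure_col_scales(self, width: int) -> None:
        if self.col_scales is None:
            self.col_scales = [np.zeros(width, dtype=complex) for _ in range(self.n_blocks)]
        elif self.col_scales[0].size != width:
            raise ValueError("grid width changed after parameters were materialised")

    # -- parameter plumbing -------------------------------------------------
    @property
    def n_parameters(self) -> int:
        """Real parameter count (complex entries count twice, plus one step size per block)."""
        n_cols = 0 if self.col_scales is None else self.col_scales[0].size
        return self.n_blocks * (2 * self.kernel_size**2 + 2 * n_cols + 1)

    def get_flat_params(self) -> np.ndarray:
        parts = []
        scales = self.col_scales or [np.zeros(0, dtype=complex)] * self.n_blocks
        for w, c, eta in zip(self.kernels, scales, self.etas):
            parts.extend([w.real.ravel(), w.imag.ravel(), c.real, c.imag, [eta]])
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])

    def set_flat_params(self, theta: np.ndarray) -> None:
        k2 = self.kernel_size**2
        per_block = (theta.size - self.n_blocks) // self.n_blocks
        n_cols = (per_block - 2 * k2) // 2
        if n_cols and self.col_scales is None:
            self.col_scales = [np.zeros(n_cols, dtype=complex) for _ in range(self.n_blocks)]
        i = 0
        for b in range(self.n_blocks):
            re = theta[i : i + k2].reshape(self.kernel_size, self.kernel_size)
            im = theta[i + k2 : i + 2 * k2].reshape(self.kernel_size, self.kernel_size)
            self.kernels[b] = re + 1j * im
            i += 2 * k2
            if n_cols:
                self.col_scales[b] = theta[i : i + n_cols] + 1j * theta[i + n_cols : i + 2 * n_cols]
                i += 2 * n_cols
            self.etas[b] = float(theta[i])
            i += 1

    # -- forward ------------------------------------------------------------
    def _encode(self, x: np.ndarray, sens: np.ndarray) -> np.ndarray:
        return fft2c(sens * x[None, :, :])

    def _decode(self, kspace: np.ndarray, sens: np.ndarray) -> np.ndarray:
        return np.sum(np.conj(sens) * ifft2c(kspace), axis=0)

    def forward(
        self,
        y_in: np.ndarray,
        mask: Mask,
        sens: np.ndarray,
        keep_tape: bool = False,
    ):
        """Run the network on a zero-filled k-space input.

        Parameters
        ----------
        y_in : complex (C, H, W)
            Masked (zero-filled) k-space data.
        mask : Mask
            The mask that produced ``y_in`` (acquisition mask, or the
            combined mask during doubly sub-sampled training).
        sens : complex (C, H, W)
            Coil sensitivity maps.

        Returns the k-space estimate, plus a tape of intermediates when
        ``keep_tape`` (needed for :meth:`backward`).
        """
        m = mask.astype(float)
        kappa = y_in.astype(complex)
        H, W = kappa.shape[-2:]
        self._ensure_col_scales(W)
        tape = []
        for w, c, eta in zip(self.kernels, self.col_scales, self.etas):
            what = np.fft.fft2(_kernel_pad(w, (H, W)))
            x = self._decode(kappa, sens)
            r = _cconv(x, what)
            kappa1 = kappa + self._encode(r, sens) + c[None, None, :] * kappa
            kappa_next = kappa1 - eta * m * (kappa1 - y_in)
            if keep_tape:
                tape.append((kappa, x, kappa1, what))
            kappa = kappa_next
        if keep_tape:
            return kappa, tape
        return kappa

    def __call__(self, y_in: np.ndarray, mask: Mask, sens: np.ndarray) -> np.ndarray:
        return self.forward(y_in, mask, sens)

    # -- backward -----------------------------------------------------------
    def backward(
        self,
        grad_out: np.ndarray,
        y_in: np.ndarray,
        mask: Mask,
        sens: np.ndarray,
        tape,
    ) -> np.ndarray:
        """Backpropagate ``dL/d(conj(output))`` to a flat real gradient.

        ``grad_out`` follows the Wirtinger convention ``g = dL/d conj(z)``;
        for a real loss the real-parameter gradients are then
        ``dL/d Re(w) = 2 Re(g_w)`` and ``dL/d Im(w) = 2 Im(g_w)``.  All
        forward ops are complex-linear, so the backward pass is their
        adjoints applied in reverse.
        """
        m = mask.astype(float)
        H, W = y_in.shape[-2:]
        g = grad_out.astype(complex)
        grads = []
        for b in range(self.n_blocks - 1, -1, -1):
            kappa, x, kappa1, what = tape[b]
            eta = self.etas[b]
            c = self.col_scales[b]
            # kappa_next = kappa1 - eta*m*(kappa1 - y_in)
            d_eta = 2.0 * float(np.real(np.sum(np.conj(g) * (m * (y_in - kappa1)))))
            g1 = (1.0 - eta * m) * g
            # kappa1 = kappa + E(conv(x, w)) + c . kappa
            g_c = np.sum(np.conj(kappa) * g1, axis=(0, 1))
            g_r = self._decode(g1, sens)  # adjoint of encode
            g_r_hat = np.fft.fft2(g_r)
            g_x = np.fft.ifft2(np.conj(what) * g_r_hat)
            # gradient w.r.t. the padded kernel, then crop to the taps
            g_wpad = np.fft.ifft2(np.conj(np.fft.fft2(x)) * g_r_hat)
            kh = kw = self.kernel_size
            rows = (np.arange(kh) - kh // 2) % H
            cols = (np.arange(kw) - kw // 2) % W
            g_w = g_wpad[np.ix_(rows, cols)]
            # x = E^H kappa; kappa also feeds kappa1 directly and via c
            g = g1 + self._encode(g_x, sens) + np.conj(c)[None, None, :] * g1
            grads.append((g_w, g_c, d_eta))
        grads.reverse()
        flat = []
        for g_w, g_c, d_eta in grads:
            flat.extend(
                [2.0 * g_w.real.ravel(), 2.0 * g_w.imag.ravel(),
                 2.0 * g_c.real, 2.0 * g_c.imag, [d_eta]]
            )
        return np.concatenate([np.asarray(p, dtype=float).ravel() for p in flat])

    def loss_and_grad(
        self,
        y_in: np.ndarray,
        mask: Mask,
        sens: np.ndarray,
        target: np.ndarray,
        weight: np.ndarray,
    ) -> tuple[float, np.ndarray]:
        """Weighted L2 loss ``||W(f - target)||^2`` and its flat gradient."""
        f, tape = self.forward(y_in, mask, sens, keep_tape=True)
        resid = f - target
        w2 = np.asarray(weight, dtype=float) ** 2
        loss = float(np.sum(w2 * np.abs(resid) ** 2))
        g_out = w2 * resid  # dL/d conj(f)
        grad = self.backward(g_out, y_in, mask, sens, tape)
        return loss, grad


def compact_unrolled_estimator(
    n_blocks: int = 4,
    kernel_size: int = 5,
    init_scale: float = 0.0,
    seed: Optional[int] = None,
) -> UnrolledReconstructor:
    """Factory for the default trainable estimator (reports its size)."""
    est = UnrolledReconstructor(
        n_blocks=n_blocks, kernel_size=kernel_size, init_scale=init_scale, seed=seed
    )
    return est


@dataclass
class AdamState:
    """Minimal Adam optimiser over a flat real parameter vector."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None
    t: int = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(theta)
            self.v = np.zeros_like(theta)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)
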