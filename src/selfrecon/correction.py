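"""The diagonal correction matrix K and the inference-time estimators.

When k-space is sampled with a variable-density mask of density ``P`` and
further sub-sampled during training by a second mask of density ``P~``, a
network trained to map the doubly sub-sampled data to the singly sub-sampled
data learns a *shrunk* estimate of the fully sampled k-space.  The shrinkage
is captured by the diagonal matrix

    K = (1 - P~ P)^(-1) (1 - P),      k_j = (1 - p_j) / (1 - p~_j p_j),

and is undone at inference by ``(1 - K)^(-1)``.  Equivalently, in terms of
sampling probabilities,

    (1 - k_j)^(-1) = P(j not in Lambda & Omega) / P(j in Omega \\ Lambda),

the form that motivates using ``(1 - K)^(-1/2)`` as a loss weighting for
partition-based (SSDU-style) training.

This module computes K from a density pair and implements the four
inference-time k-space estimators: the corrected Noisier2Noise pair and the
SSDU pair (which needs no correction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .masks import Mask, MaskDistribution

__all__ = [
    "KMatrix",
    "compute_K",
    "n2n_correct_plain",
    "n2n_correct_dc",
    "ssdu_estimate",
]

logger = logging.getLogger(__name__)

#: clip applied to the inverse weight (1-k)^(-1); p~ -> 1 makes it blow up
DEFAULT_MAX_W1 = 1e6


@dataclass
class KMatrix:
    """Diagonal correction entries ``k_j`` and their derived weights.

    Attributes
    ----------
    k : ndarray (H, W)
        Diagonal of K.  ``0 <= k_j < 1`` wherever ``p_j > 0`` and
        ``p~_j < 1``; ``k_j = 0`` where ``p_j = 1``.
    w1 : ndarray (H, W)
        ``(1 - k)^(-1)``, the inference correction weight.
    w_half : ndarray (H, W)
        ``(1 - k)^(-1/2)``, the K-weighted SSDU loss weight.
    """

    k: np.ndarray
    w1: np.ndarray
    w_half: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.k.shape


def compute_K(
    omega_dist: MaskDistribution,
    lambda_dist: MaskDistribution,
    max_w1: float = DEFAULT_MAX_W1,
) -> KMatrix:
    """Build the diagonal correction K from an (Omega, Lambda) density pair.

    ``k_j = (1 - p_j) / (1 - p~_j p_j)`` elementwise, in double precision.
    Requires ``p_j > 0`` and ``p~_j < 1`` everywhere, the condition for
    ``1 - K`` to be invertible.  The inverse weight ``(1 - k)^(-1)`` is
    clipped at ``max_w1`` with a logged warning, since it diverges as
    ``p~ -> 1``.

    For partitioners with no closed-form density, estimate the density by
    Monte Carlo (``masks.estimate_density``) and pass the estimate here.
    """
    p = np.asarray(omega_dist.prob, dtype=np.float64)
    pt = np.asarray(lambda_dist.prob, dtype=np.float64)
    if p.shape != pt.shape:
        raise ValueError("density shapes do not match")
    bad_p = p <= 0
    bad_pt = pt >= 1
    if bad_p.any() or bad_pt.any():
        locs = np.argwhere(bad_p | bad_pt)[:5]
        raise ValueError(
            "1 - K is not invertible: requires p > 0 and p~ < 1 everywhere; "
            f"violated at locations {locs.tolist()}{' ...' if (bad_p | bad_pt).sum() > 5 else ''}"
        )
    k = (1.0 - p) / (1.0 - pt * p)
    w1 = 1.0 / (1.0 - k)
    if np.any(w1 > max_w1):
        n = int((w1 > max_w1).sum())
        logger.warning("clipping (1-k)^(-1) at %.1e for %d locations", max_w1, n)
        warnings.warn(
            f"(1-k)^(-1) clipped at {max_w1:g} for {n} locations "
            "(acquisition density near 0 or partition density near 1 there)",
            RuntimeWarning,
            stacklevel=2,
        )
        w1 = np.minimum(w1, max_w1)
    return KMatrix(k=k, w1=w1, w_half=np.sqrt(w1))


def _as_array(x) -> np.ndarray:
    arr = getattr(x, "array", x)
    return np.asarray(arr)


def n2n_correct_plain(f_out, y_in, K: KMatrix) -> np.ndarray:
    """Noisier2Noise correction with the network output used as-is.

    Returns ``(1 - K)^(-1) (f_out - K y_in)`` elementwise, broadcasting the
    diagonal over coils.  This is the estimator used when the singly
    sub-sampled data is fed to the network at inference.
    """
    f = _as_array(f_out)
    y = _as_array(y_in)
    if f.shape != y.shape:
        raise ValueError("k-space shapes do not match")
    return K.w1 * (f - K.k * y)


def n2n_correct_dc(f_out, y, omega: Mask, K: KMatrix) -> np.ndarray:
    """Data-consistent Noisier2Noise estimator.

    Returns ``(1 - M_Omega)(1 - K)^(-1) f_out + y``: unknown entries are
    corrected network output, sampled entries are overwritten with the
    acquired data so the estimate is exactly consistent with all of ``y``.
    ``f_out`` is the network output on the doubly sub-sampled input.
    """
    f = _as_array(f_out)
    yy = _as_array(y)
    if f.shape != yy.shape:
        raise ValueError("k-space shapes do not match")
    m = omega.astype(float)
    return (1.0 - m) * K.w1 * f + yy


def ssdu_estimate(f_out, y, omega: Mask, mode: str = "dc_tilde_input") -> np.ndarray:
    """SSDU inference estimators (no correction term needed).

    ``mode="dc_tilde_input"``: the network ran on the doubly sub-sampled
    input; return ``(1 - M_Omega) f_out + y`` (data consistent with all
    acquired data).  ``mode="plain_y_input"``: the network ran on the singly
    sub-sampled data; return its output unchanged.
    """
    f = _as_array(f_out)
    yy = _as_array(y)
    if mode == "plain_y_input":
        return f.copy()
    if mode != "dc_tilde_input":
        raise ValueError(f"unknown SSDU estimate mode: {mode!r}")
    if f.shape != yy.shape:
        raise ValueError("k-space shapes do not match")
    m = omega.astype(float)
    return (1.0 - m) * f + yy
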