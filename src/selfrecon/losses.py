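"""Weighted squared-error training objectives and the loss decomposition.

Every training method in this package minimises a weighted k-space L2 loss

    || W (f(ytilde) - y) ||_2^2

with a diagonal weighting ``W`` that defines the method:

* identity ``W = 1`` — unweighted Noisier2Noise (needs correction at
  inference);
* ``W = (1 - M_Lambda) M_Omega`` — SSDU: the loss is restricted to acquired
  locations withheld from the network input;
* ``W = (1 - K)^(-1/2) (1 - M_Lambda) M_Omega`` — K-weighted SSDU, which
  compensates for the variable sampling and partitioning densities;
* supervised — identity weighting against the fully sampled reference.

For a network that is consistent with its doubly sub-sampled input, the full
loss splits exactly into the SSDU term plus a complement term supported on
unsampled k-space; the complement is what causes the unweighted method to
shrink unsampled k-space and hence to need the ``(1 - K)^(-1)`` correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .correction import KMatrix
from .masks import Mask, MaskStructure

__all__ = [
    "Weighting",
    "MethodName",
    "MethodSpec",
    "METHODS",
    "get_method",
    "loss_weights",
    "weighted_l2_loss",
    "loss_decomposition",
]


class Weighting(enum.Enum):
    IDENTITY = "identity"
    SSDU_MASK = "ssdu_mask"
    K_HALF_SSDU_MASK = "k_half_ssdu_mask"
    NONE = "none"


class MethodName(enum.Enum):
    UNWEIGHTED_N2N = "unweighted_n2n"
    SSDU_2D = "ssdu_2d"
    SSDU_1D = "ssdu_1d"
    KWEIGHTED_SSDU_1D = "kweighted_ssdu_1d"
    SUPERVISED = "supervised"


@dataclass(frozen=True)
class MethodSpec:
    """One row of the method menu.

    ``weighting`` fixes the loss diagonal W, ``lambda_structure`` the type
    of the second (partitioning) mask, and the two inference fields name the
    estimator used for the doubly and singly sub-sampled network inputs.
    """

    name: MethodName
    weighting: Weighting
    lambda_structure: Optional[MaskStructure]
    inference_tilde: str  # estimator when the network input is ytilde
    inference_singly: str  # estimator when the network input is y

    @property
    def self_supervised(self) -> bool:
        return self.name is not MethodName.SUPERVISED

    @property
    def needs_K(self) -> bool:
        return self.weighting is Weighting.K_HALF_SSDU_MASK or self.name is MethodName.UNWEIGHTED_N2N


METHODS: dict[MethodName, MethodSpec] = {
    MethodName.UNWEIGHTED_N2N: MethodSpec(
        MethodName.UNWEIGHTED_N2N,
        Weighting.IDENTITY,
        MaskStructure.COLUMN_1D,
        inference_tilde="n2n_dc",
        inference_singly="n2n_plain",
    ),
    MethodName.SSDU_2D: MethodSpec(
        MethodName.SSDU_2D,
        Weighting.SSDU_MASK,
        MaskStructure.BERNOULLI_2D,
        inference_tilde="ssdu_dc",
        inference_singly="ssdu_plain",
    ),
    MethodName.SSDU_1D: MethodSpec(
        MethodName.SSDU_1D,
        Weighting.SSDU_MASK,
        MaskStructure.COLUMN_1D,
        inference_tilde="ssdu_dc",
        inference_singly="ssdu_plain",
    ),
    MethodName.KWEIGHTED_SSDU_1D: MethodSpec(
        MethodName.KWEIGHTED_SSDU_1D,
        Weighting.K_HALF_SSDU_MASK,
        MaskStructure.COLUMN_1D,
        inference_tilde="ssdu_dc",
        inference_singly="ssdu_plain",
    ),
    MethodName.SUPERVISED: MethodSpec(
        MethodName.SUPERVISED,
        Weighting.NONE,
        None,
        inference_tilde="ssdu_dc",
        inference_singly="ssdu_plain",
    ),
}


def get_method(name) -> MethodSpec:
    """Look up a method by enum or by its string name."""
    if isinstance(name, MethodSpec):
        return name
    if isinstance(name, str):
        name = MethodName(name.lower())
    return METHODS[name]


def loss_weights(
    spec: MethodSpec,
    omega: Optional[Mask] = None,
    lam: Optional[Mask] = None,
    K: Optional[KMatrix] = None,
) -> np.ndarray:
    """The diagonal loss weighting W for a method, as an (H, W) array."""
    if spec.weighting in (Weighting.IDENTITY, Weighting.NONE):
        if omega is None and lam is None:
            raise ValueError("need at least one mask to determine the grid shape")
        shape = (omega or lam).shape
        return np.ones(shape, dtype=float)
    if omega is None or lam is None:
        raise ValueError("SSDU weightings require both masks")
    w = (1.0 - lam.astype(float)) * omega.astype(float)
    if spec.weighting is Weighting.K_HALF_SSDU_MASK:
        if K is None:
            raise ValueError("K-weighted SSDU requires the K matrix")
        w = K.w_half * w
    return w


def weighted_l2_loss(
    f_out: np.ndarray,
    target: np.ndarray,
    spec: MethodSpec,
    omega: Optional[Mask] = None,
    lam: Optional[Mask] = None,
    K: Optional[KMatrix] = None,
) -> float:
    """``|| W (f_out - target) ||_2^2`` summed over coils and k-space.

    ``target`` is the singly sub-sampled data for self-supervised methods
    and the fully sampled reference for supervised training.  Residuals are
    complex; the squared magnitude ``re^2 + im^2`` is used and the diagonal
    weight broadcasts across coils.
    """
    f = np.asarray(f_out)
    t = np.asarray(target)
    if f.shape != t.shape:
        raise ValueError("output/target shapes do not match")
    w = loss_weights(spec, omega=omega, lam=lam, K=K)
    resid = f - t
    return float(np.sum((w**2) * np.abs(resid) ** 2))


def loss_decomposition(
    f_out: np.ndarray,
    y: np.ndarray,
    omega: Mask,
    lam: Mask,
    weight: np.ndarray,
    atol: float = 1e-8,
) -> tuple[float, float]:
    """Split ``||W (f - y)||^2`` into its SSDU and unsampled-complement terms.

    Requires ``f_out`` to be consistent with the doubly sub-sampled data
    (``f = y`` on ``Lambda & Omega``), which holds by construction for a
    data-consistent network.  Then

        ||W (f - y)||^2 = ||W (1 - M_L) M_O (f - y)||^2 + ||W (1 - M_O) f||^2

    exactly.  Returns ``(ssdu_term, complement_term)``.  The complement term
    is identically zero under the SSDU weighting, which is why partition
    training needs no correction at inference.
    """
    f = np.asarray(f_out)
    yy = np.asarray(y)
    mo = omega.astype(float)
    ml = lam.astype(float)
    b = ml * mo
    scale = max(np.max(np.abs(yy)), 1.0)
    if not np.allclose(b * f, b * yy, atol=atol * scale):
        raise ValueError("f_out is not consistent with the doubly sub-sampled data on Lambda & Omega")
    w2 = np.asarray(weight, dtype=float) ** 2
    ssdu_term = float(np.sum(w2 * ((1.0 - ml) * mo) * np.abs(f - yy) ** 2))
    complement_term = float(np.sum(w2 * (1.0 - mo) * np.abs(f) ** 2))
    return ssdu_term, complement_term
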