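"""Variable-density k-space sampling distributions, masks and partitions.

Cartesian MRI acquisitions sample a subset :math:`\\Omega` of the k-space
grid.  This module builds the per-location sampling probabilities (the
*density*), draws binary masks from them, partitions a sampling set into the
loss/input subsets used for self-supervised training, and estimates the
density of procedural samplers by Monte Carlo.

Two mask structures are supported:

* ``COLUMN_1D`` — whole phase-encode columns are acquired or skipped
  together; the readout (row) dimension is always fully sampled.
* ``BERNOULLI_2D`` — every location is an independent Bernoulli draw.

Densities are polynomial in the normalised distance from the k-space centre,
with a fully sampled (or ``1 - eps`` capped) central region, and are scaled
so that the expected acceleration ``R = N / sum(p)`` matches a target.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "MaskStructure",
    "MaskDistribution",
    "Mask",
    "Partition",
    "build_column_density",
    "build_bernoulli_density",
    "sample_mask",
    "partition_sets",
    "partition_ratio",
    "estimate_density",
]

#: relative tolerance on the achieved acceleration after density scaling
ACCEL_RTOL = 5e-3


class MaskStructure(enum.Enum):
    """Conditional dependence structure of a sampling mask."""

    COLUMN_1D = "column_1d"
    BERNOULLI_2D = "bernoulli_2d"


@dataclass
class MaskDistribution:
    """Per-location sampling probabilities for one mask random variable.

    Attributes
    ----------
    prob : ndarray of shape (H, W)
        Probability that each k-space location is sampled.  For
        ``COLUMN_1D`` structure the array is constant along rows of each
        column.
    structure : MaskStructure
        Whether draws are independent per location or coupled per column.
    center : int
        Width of the fully sampled central region (columns for
        ``COLUMN_1D``, side of the central square for ``BERNOULLI_2D``).
    cap : float or None
        Optional upper bound ``1 - eps`` applied to the density; used for
        partition (second-mask) distributions which must satisfy
        ``p < 1`` everywhere.
    target_accel : float
        The acceleration the density was scaled to, ``R = N / sum(p)``.
    """

    prob: np.ndarray
    structure: MaskStructure
    center: int = 0
    cap: Optional[float] = None
    target_accel: float = 1.0

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 2:
            raise ValueError("prob must be a 2D (H, W) array")
        if np.any(self.prob < 0) or np.any(self.prob > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.cap is not None and np.any(self.prob > self.cap + 1e-12):
            raise ValueError("density exceeds its cap")
        if self.structure is MaskStructure.COLUMN_1D:
            if not np.allclose(self.prob, self.prob[:1, :]):
                raise ValueError("COLUMN_1D density must be constant within columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prob.shape

    @property
    def accel(self) -> float:
        """Achieved expected acceleration ``N / sum(p)``."""
        return self.prob.size / float(self.prob.sum())


@dataclass
class Mask:
    """A binary indicator over the k-space grid."""

    indicator: np.ndarray
    structure: MaskStructure = MaskStructure.BERNOULLI_2D

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator)
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("mask indicator must be binary")
        self.indicator = ind.astype(np.uint8)
        if self.structure is MaskStructure.COLUMN_1D:
            if not (self.indicator == self.indicator[:1, :]).all():
                raise ValueError("COLUMN_1D mask columns must be all-0 or all-1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.indicator.shape

    def astype(self, dtype) -> np.ndarray:
        return self.indicator.astype(dtype)


@dataclass
class Partition:
    """Split of a sampling set into loss set ``A`` and input set ``B``.

    ``A`` and ``B`` are boolean index arrays over the grid with
    ``A | B == omega`` and ``A & B`` empty.
    """

    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=bool)
        self.B = np.asarray(self.B, dtype=bool)
        if self.A.shape != self.B.shape:
            raise ValueError("A and B must share a grid")
        if np.any(self.A & self.B):
            raise ValueError("A and B must be disjoint")


def _center_slice(size: int, extent: int) -> slice:
    """Centred block of ``extent`` cells in a length-``size`` axis.

    The block is centred on index ``size // 2`` (the zero-frequency index of
    the centred FFT convention) and left-biased on ties.
    """
    lo = size // 2 - extent // 2
    return slice(lo, lo + extent)


def _scale_to_accel(
    base: np.ndarray,
    fixed: np.ndarray,
    target_sum: float,
    hi: float,
) -> np.ndarray:
    """Scale ``base`` (clipping at ``hi``) so the total density hits ``target_sum``.

    ``fixed`` marks locations whose probability is pinned at ``hi`` (the
    central region); the remainder is ``min(m * base, hi)`` with the scalar
    ``m`` found by bisection.  The achieved sum is monotone in ``m``, so
    bisection converges; infeasible targets raise ``ValueError``.
    """
    free = ~fixed
    fixed_sum = hi * fixed.sum()
    max_sum = fixed_sum + hi * free.sum()
    if target_sum > max_sum * (1 + ACCEL_RTOL) or target_sum < fixed_sum * (1 - ACCEL_RTOL):
        raise ValueError(
            f"acceleration target infeasible: required density sum {target_sum:.2f} "
            f"outside attainable range [{fixed_sum:.2f}, {max_sum:.2f}]"
        )
    if base[free].sum() <= 0 and target_sum > fixed_sum * (1 + ACCEL_RTOL):
        raise ValueError("base density is zero outside the centre; cannot scale")
    if target_sum >= max_sum * (1 - 1e-12):
        # saturated: every location at the cap (e.g. acceleration 1)
        return np.full(base.shape, hi)

    def total(m: float) -> float:
        return fixed_sum + np.minimum(m * base[free], hi).sum()

    lo_m, hi_m = 0.0, 1.0
    while total(hi_m) < target_sum and hi_m < 1e60:
        hi_m *= 4.0
    for _ in range(400):
        mid = 0.5 * (lo_m + hi_m)
        if total(mid) < target_sum:
            lo_m = mid
        else:
            hi_m = mid
    m = 0.5 * (lo_m + hi_m)
    out = np.where(fixed, hi, np.minimum(m * base, hi))
    return out


def build_column_density(
    width: int,
    accel: float,
    order: int = 8,
    center_cols: int = 10,
    cap_epsilon: Optional[float] = None,
    height: int = 1,
) -> MaskDistribution:
    """Variable-density distribution over phase-encode columns.

    The central ``center_cols`` columns are sampled with probability 1 (or
    ``1 - cap_epsilon`` when a cap is requested, as needed for partition
    masks); the rest decay as ``(1 - |d|)**order`` in the normalised signed
    distance ``d`` from the centre column, scaled so that
    ``width / sum(p_cols)`` equals ``accel`` to within 0.5%.

    Parameters
    ----------
    width : int
        Number of phase-encode columns.
    accel : float
        Target expected acceleration ``R >= 1``.
    order : int
        Polynomial decay order (8 is a common choice for Cartesian
        variable-density sampling).
    center_cols : int
        Width of the fully sampled central band.
    cap_epsilon : float, optional
        When given, every probability (centre included) is capped at
        ``1 - cap_epsilon`` so the density is valid as a second
        (partitioning) mask, which must satisfy ``p < 1`` everywhere.
    height : int
        Number of rows of the grid the density is broadcast over.
    """
    if accel < 1:
        raise ValueError("acceleration must be >= 1")
    if center_cols > width:
        raise ValueError("central band wider than the grid")
    if cap_epsilon is not None and not 0 < cap_epsilon < 1:
        raise ValueError("cap_epsilon must lie in (0, 1)")

    hi = 1.0 if cap_epsilon is None else 1.0 - cap_epsilon
    cols = np.arange(width)
    centre = width // 2
    # normalise so |d| < 1 strictly: the density stays positive everywhere,
    # as required for the first (acquisition) mask
    half = max(width / 2.0, 1.0) + 1.0
    d = np.abs(cols - centre) / half
    base = np.clip(1.0 - d, 0.0, 1.0) ** order

    fixed = np.zeros(width, dtype=bool)
    fixed[_center_slice(width, center_cols)] = True

    p_cols = _scale_to_accel(base, fixed, width / accel, hi)
    prob = np.broadcast_to(p_cols, (height, width)).copy()
    return MaskDistribution(
        prob=prob,
        structure=MaskStructure.COLUMN_1D,
        center=center_cols,
        cap=hi if cap_epsilon is not None else None,
        target_accel=accel,
    )


def build_bernoulli_density(
    height: int,
    width: int,
    accel: float,
    order: int = 8,
    center_size: int = 10,
    cap_epsilon: Optional[float] = None,
    low_freq_high_prob: bool = True,
) -> MaskDistribution:
    """Radially symmetric density for independent (2D Bernoulli) sampling.

    A ``center_size x center_size`` central square is sampled with
    probability 1 (or ``1 - cap_epsilon``); outside it the density is a
    polynomial in the normalised radius.  ``low_freq_high_prob=True`` gives
    the usual acquisition-style decay ``(1 - d)**order``; ``False`` gives a
    density growing with radius, ``d**order``, as used by partition masks
    that sample high frequencies with higher probability.
    """
    if accel < 1:
        raise ValueError("acceleration must be >= 1")
    if center_size > min(height, width):
        raise ValueError("central region larger than the grid")
    if cap_epsilon is not None and not 0 < cap_epsilon < 1:
        raise ValueError("cap_epsilon must lie in (0, 1)")

    hi = 1.0 if cap_epsilon is None else 1.0 - cap_epsilon
    rr = (np.arange(height) - height // 2) / max(height / 2.0, 1.0)
    cc = (np.arange(width) - width // 2) / max(width / 2.0, 1.0)
    d = np.sqrt(rr[:, None] ** 2 + cc[None, :] ** 2)
    # keep d < 1 strictly so the decaying density is positive everywhere
    d = np.clip(d / (max(d.max(), 1e-12) * (1.0 + 1.0 / max(height, width))), 0.0, 1.0)
    if low_freq_high_prob:
        base = (1.0 - d) ** order
    else:
        base = d**order

    fixed = np.zeros((height, width), dtype=bool)
    fixed[_center_slice(height, center_size), _center_slice(width, center_size)] = True

    prob = _scale_to_accel(base, fixed, height * width / accel, hi)
    return MaskDistribution(
        prob=prob,
        structure=MaskStructure.BERNOULLI_2D,
        center=center_size,
        cap=hi if cap_epsilon is not None else None,
        target_accel=accel,
    )


def sample_mask(dist: MaskDistribution, rng_seed) -> Mask:
    """Draw one binary mask from a distribution.

    ``BERNOULLI_2D`` locations are independent; ``COLUMN_1D`` draws one
    Bernoulli per column and replicates it down the rows.  ``rng_seed`` may
    be an integer seed or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng_seed)
    H, W = dist.shape
    if dist.structure is MaskStructure.COLUMN_1D:
        cols = (rng.random(W) < dist.prob[0]).astype(np.uint8)
        ind = np.broadcast_to(cols, (H, W)).copy()
    else:
        ind = (rng.random((H, W)) < dist.prob).astype(np.uint8)
    return Mask(indicator=ind, structure=dist.structure)


def partition_sets(omega: Mask, lam: Mask) -> Partition:
    """Partition the sampling set: ``A = omega \\ lam``, ``B = omega & lam``.

    ``A`` is the loss set (sampled but withheld from the network input) and
    ``B`` the input set; by construction ``A | B = omega`` and they are
    disjoint.
    """
    if omega.shape != lam.shape:
        raise ValueError("masks must share one grid")
    om = omega.indicator.astype(bool)
    lm = lam.indicator.astype(bool)
    return Partition(A=om & ~lm, B=om & lm)


def partition_ratio(p: Partition) -> float:
    """The partition ratio ``rho = |A| / |B|``."""
    nb = int(p.B.sum())
    if nb == 0:
        raise ZeroDivisionError("partition has empty input set B")
    return float(p.A.sum()) / nb


def estimate_density(
    sampler: Callable[[np.random.Generator], Mask],
    n_draws: int,
    rng_seed,
    structure: MaskStructure = MaskStructure.BERNOULLI_2D,
) -> MaskDistribution:
    """Monte-Carlo estimate of the density of a procedural mask sampler.

    Calls ``sampler(rng)`` ``n_draws`` times and averages the indicators.
    This is how the density of a partitioner with no closed form (e.g. a
    third-party sampling-set splitter) is obtained before computing the
    correction matrix from it.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng_seed)
    acc = None
    for _ in range(n_draws):
        m = sampler(rng)
        a = m.indicator.astype(float)
        acc = a if acc is None else acc + a
        if m.structure is MaskStructure.COLUMN_1D:
            structure = MaskStructure.COLUMN_1D
    prob = acc / n_draws
    if structure is MaskStructure.COLUMN_1D:
        prob = np.broadcast_to(prob.mean(axis=0), prob.shape).copy()
    accel = prob.size / max(prob.sum(), 1e-300)
    return MaskDistribution(prob=prob, structure=structure, target_accel=accel)
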