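"""Synthetic multi-coil k-space data and enumerable discrete toy ensembles.

The continuous generator emulates the structure the reconstruction methods
assume: piecewise-smooth magnitude images (random ellipses on a smooth
background), smooth low-order polynomial phase, smooth complex coil
sensitivities normalised to unit root-sum-of-squares, and k-space obtained
by a centred unitary FFT so spectral energy concentrates at low frequencies
— the regime that motivates variable-density sampling.  Simulation is
noise-free by default (an optional additive-noise hook exists but is off).

The discrete generator builds tiny ensembles over a handful of k-space
locations with a finite nonzero alphabet and fully enumerable mask draws,
so conditional expectations can be computed exactly by brute force.  These
ensembles are the oracles for the expectation-identity checks in
:mod:`selfrecon.oracles`.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._fft import fft2c
from .masks import Mask, MaskDistribution, MaskStructure, sample_mask

__all__ = [
    "Role",
    "KSpaceData",
    "GroundTruthError",
    "SliceRecord",
    "SliceDataset",
    "make_phantom",
    "make_coils",
    "forward_kspace",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "read_fastmri_slice",
    "DiscreteToySpec",
    "ToyTable",
    "enumerate_toy",
]


class Role(enum.Enum):
    FULL = "full"  # y0: fully sampled reference
    SINGLY_SUB = "singly_sub"  # y = M_Omega y0
    DOUBLY_SUB = "doubly_sub"  # ytilde = M_Lambda y


@dataclass
class KSpaceData:
    """Complex multi-coil k-space with a role tag."""

    array: np.ndarray
    role: Role = Role.FULL
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=complex)
        if self.array.ndim != 3:
            raise ValueError("k-space array must be (coils, H, W)")

    @property
    def shape(self):
        return self.array.shape


class GroundTruthError(RuntimeError):
    """Raised when a self-supervised path requests fully sampled data."""


# ---------------------------------------------------------------------------
# continuous phantom simulation
# ---------------------------------------------------------------------------

def make_phantom(
    height: int,
    width: int,
    n_ellipses: int = 6,
    rng_seed: Optional[int] = None,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Random complex phantom: ellipse magnitude, low-order polynomial phase.

    The magnitude is a superposition of randomly placed, lightly smoothed
    ellipses on a smooth Gaussian background; the phase is a random 2D
    polynomial of total degree two.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    u = np.linspace(-1, 1, height)[:, None]
    v = np.linspace(-1, 1, width)[None, :]
    mag = 0.35 * np.exp(-(u**2 + v**2) / 0.9)
    for _ in range(n_ellipses):
        cu, cv = rng.uniform(-0.6, 0.6, size=2)
        au, av = rng.uniform(0.08, 0.45, size=2)
        ang = rng.uniform(0, np.pi)
        amp = rng.uniform(0.2, 1.0)
        ru = (u - cu) * np.cos(ang) + (v - cv) * np.sin(ang)
        rv = -(u - cu) * np.sin(ang) + (v - cv) * np.cos(ang)
        mag = mag + amp * ((ru / au) ** 2 + (rv / av) ** 2 <= 1.0)
    if smooth_sigma > 0:
        mag = gaussian_filter(mag, smooth_sigma)
    mag = mag / max(mag.max(), 1e-12)
    c = rng.uniform(-1.0, 1.0, size=6)
    phase = c[0] + c[1] * u + c[2] * v + c[3] * u * v + c[4] * u**2 + c[5] * v**2
    return mag * np.exp(1j * np.pi * 0.5 * phase)


def make_coils(
    n_coils: int,
    height: int,
    width: int,
    rng_seed: Optional[int] = None,
) -> np.ndarray:
    """Smooth complex coil sensitivities with ``sum_c |S_c|^2 = 1`` pointwise.

    Each coil is a broad Gaussian sensitivity bump centred outside the field
    of view (mimicking a surface coil) with a smooth linear phase; the stack
    is normalised to unit root-sum-of-squares at every pixel.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(rng_seed)
    u = np.linspace(-1, 1, height)[:, None]
    v = np.linspace(-1, 1, width)[None, :]
    maps = np.empty((n_coils, height, width), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cu, cv = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        sigma = rng.uniform(0.8, 1.4)
        mag = np.exp(-((u - cu) ** 2 + (v - cv) ** 2) / (2 * sigma**2)) + 0.05
        ph = rng.uniform(-1, 1) * u + rng.uniform(-1, 1) * v + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    return maps / rss[None, :, :]


def forward_kspace(image: np.ndarray, coils: np.ndarray) -> KSpaceData:
    """Fully sampled multi-coil k-space ``F(S_c x)`` (centred, unitary)."""
    image = np.asarray(image, dtype=complex)
    coils = np.asarray(coils, dtype=complex)
    if coils.ndim != 3 or coils.shape[1:] != image.shape:
        raise ValueError("coil maps must be (coils, H, W) matching the image")
    return KSpaceData(array=fft2c(coils * image[None, :, :]), role=Role.FULL)


# ---------------------------------------------------------------------------
# dataset container with ground-truth access control
# ---------------------------------------------------------------------------

@dataclass
class SliceRecord:
    """One slice: fully sampled k-space, frozen acquisition mask, coil maps."""

    kspace_full: np.ndarray  # (C, H, W) complex
    omega: Mask
    sens: np.ndarray  # (C, H, W) complex
    slice_id: str
    seed: int = 0


class SliceDataset:
    """A set of slices with frozen acquisition masks and guarded ground truth.

    Self-supervised training must never see the fully sampled reference, so
    :meth:`ground_truth` raises :class:`GroundTruthError` while the dataset
    is locked.  Evaluation and supervised training unlock it explicitly via
    :meth:`expose_ground_truth`.
    """

    def __init__(
        self,
        records: Sequence[SliceRecord],
        omega_dist: Optional[MaskDistribution] = None,
        locked: bool = True,
    ) -> None:
        self.records = list(records)
        self.omega_dist = omega_dist
        self._locked = locked

    def __len__(self) -> int:
        return len(self.records)

    @property
    def locked(self) -> bool:
        return self._locked

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.records[0].kspace_full.shape[-2:]

    @property
    def n_coils(self) -> int:
        return self.records[0].kspace_full.shape[0]

    def y(self, i: int) -> np.ndarray:
        """Acquired (singly sub-sampled) k-space ``M_Omega y0`` for slice i."""
        rec = self.records[i]
        return rec.kspace_full * rec.omega.astype(float)

    def omega(self, i: int) -> Mask:
        return self.records[i].omega

    def sens(self, i: int) -> np.ndarray:
        return self.records[i].sens

    def ground_truth(self, i: int) -> np.ndarray:
        """Fully sampled k-space; raises while the dataset is locked."""
        if self._locked:
            raise GroundTruthError(
                "fully sampled k-space is locked; self-supervised training "
                "may not access it (use expose_ground_truth() for "
                "evaluation or supervised training)"
            )
        return self.records[i].kspace_full

    def expose_ground_truth(self):
        """Context manager temporarily unlocking the fully sampled data."""
        ds = self

        class _Exposed:
            def __enter__(self_inner):
                ds._locked = False
                return ds

            def __exit__(self_inner, *exc):
                ds._locked = True
                return False

        return _Exposed()


def make_dataset(
    n_volumes: int,
    slices_per_volume: int,
    omega_dist: MaskDistribution,
    rng_seed: int = 0,
    n_coils: int = 4,
    n_ellipses: int = 6,
    noise_std: float = 0.0,
    path: Optional[str] = None,
) -> SliceDataset:
    """Simulate a dataset of (y0, Omega) pairs with one frozen mask per slice.

    Coil maps are drawn once per volume; phantoms and acquisition masks are
    drawn per slice from independent seeded streams, so regeneration with
    the same master seed is bit-identical.  ``noise_std`` adds complex
    Gaussian measurement noise to the fully sampled k-space (off by
    default).  When ``path`` is given the dataset is also written to an
    HDF5 container.
    """
    H, W = omega_dist.shape
    records = []
    for vol in range(n_volumes):
        vol_ss = np.random.SeedSequence([rng_seed, vol])
        coil_seed, *slice_seeds = vol_ss.spawn(1 + slices_per_volume)
        sens = make_coils(n_coils, H, W, rng_seed=np.random.default_rng(coil_seed))
        for sl, ss in enumerate(slice_seeds):
            rng = np.random.default_rng(ss)
            img = make_phantom(H, W, n_ellipses=n_ellipses, rng_seed=rng)
            y0 = forward_kspace(img, sens).array
            if noise_std > 0:
                y0 = y0 + noise_std * (
                    rng.standard_normal(y0.shape) + 1j * rng.standard_normal(y0.shape)
                ) / np.sqrt(2)
            omega = sample_mask(omega_dist, rng)
            records.append(
                SliceRecord(
                    kspace_full=y0,
                    omega=omega,
                    sens=sens,
                    slice_id=f"vol{vol:03d}_slice{sl:03d}",
                )
            )
    ds = SliceDataset(records, omega_dist=omega_dist, locked=True)
    if path is not None:
        save_dataset(ds, path)
    return ds


def save_dataset(dataset: SliceDataset, path: str) -> None:
    """Write the dataset to an HDF5 container, one group per slice.

    Each group holds datasets ``kspace`` (complex, coils x H x W), ``omega``
    (uint8 H x W) and ``sens`` (complex).  Object timestamps are disabled so
    regeneration with the same seed produces a bit-identical file.
    """
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        for rec in dataset.records:
            g = f.create_group(rec.slice_id)
            g.create_dataset("kspace", data=rec.kspace_full, track_times=False)
            g.create_dataset("omega", data=rec.omega.indicator, track_times=False)
            g.create_dataset("sens", data=rec.sens, track_times=False)
            g.attrs["structure"] = rec.omega.structure.value


def load_dataset(path: str, locked: bool = True) -> SliceDataset:
    """Read a dataset written by :func:`save_dataset`."""
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            structure = MaskStructure(g.attrs.get("structure", "bernoulli_2d"))
            records.append(
                SliceRecord(
                    kspace_full=np.asarray(g["kspace"], dtype=complex),
                    omega=Mask(np.asarray(g["omega"]), structure=structure),
                    sens=np.asarray(g["sens"], dtype=complex),
                    slice_id=name,
                )
            )
    return SliceDataset(records, locked=locked)


def read_fastmri_slice(path: str, slice_index: int = 0) -> np.ndarray:
    """Optional reader for the fastMRI multicoil HDF5 dialect.

    Returns the complex (coils, H, W) k-space of one slice from a file with
    a ``kspace`` dataset of shape (slices, coils, H, W).  Only the raw
    k-space is read; header parsing is not attempted.
    """
    import h5py

    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise KeyError("not a fastMRI multicoil file: no 'kspace' dataset")
        return np.asarray(f["kspace"][slice_index], dtype=complex)


# ---------------------------------------------------------------------------
# discrete toy ensembles for exact enumeration
# ---------------------------------------------------------------------------

@dataclass
class DiscreteToySpec:
    """Enumerable toy ensemble over ``n`` k-space locations.

    ``alphabet`` lists the (nonzero) values each location of the fully
    sampled data can take, with per-location probabilities ``value_probs``
    of shape (n, len(alphabet)).  ``p`` and ``p_tilde`` are the per-location
    sampling probabilities of the first and second masks.  ``columns``
    optionally groups locations into columns whose mask draws are fully
    coupled (column-wise sampling); sampling probabilities must then be
    constant within each column.

    Zero is excluded from the alphabet so that a zero in the doubly
    sub-sampled pattern unambiguously marks an unsampled location.
    """

    n: int
    alphabet: Sequence[float]
    p: Sequence[float]
    p_tilde: Sequence[float]
    value_probs: Optional[np.ndarray] = None
    columns: Optional[Sequence[int]] = None  # column index per location

    def __post_init__(self) -> None:
        if self.n > 8:
            raise ValueError("toy ensembles are limited to n <= 8 locations")
        self.alphabet = np.asarray(self.alphabet, dtype=float)
        if np.any(self.alphabet == 0):
            raise ValueError("alphabet must exclude 0 (zero marks 'unsampled')")
        self.p = np.asarray(self.p, dtype=float)
        self.p_tilde = np.asarray(self.p_tilde, dtype=float)
        if self.p.shape != (self.n,) or self.p_tilde.shape != (self.n,):
            raise ValueError("p and p_tilde must have length n")
        if np.any(self.p <= 0):
            raise ValueError("requires p_j > 0 for all locations")
        if np.any(self.p_tilde >= 1):
            raise ValueError("requires p_tilde_j < 1 for all locations")
        if self.value_probs is None:
            a = len(self.alphabet)
            self.value_probs = np.full((self.n, a), 1.0 / a)
        self.value_probs = np.asarray(self.value_probs, dtype=float)
        if self.value_probs.shape != (self.n, len(self.alphabet)):
            raise ValueError("value_probs must be (n, |alphabet|)")
        if not np.allclose(self.value_probs.sum(axis=1), 1.0):
            raise ValueError("value probabilities must sum to 1 per location")
        if self.columns is not None:
            self.columns = np.asarray(self.columns, dtype=int)
            if self.columns.shape != (self.n,):
                raise ValueError("columns must assign one column per location")
            for col in np.unique(self.columns):
                sel = self.columns == col
                if not (np.allclose(self.p[sel], self.p[sel][0])
                        and np.allclose(self.p_tilde[sel], self.p_tilde[sel][0])):
                    raise ValueError("coupled columns need constant p within each column")

    @property
    def coupled(self) -> bool:
        return self.columns is not None


@dataclass
class ToyTable:
    """Exhaustive outcome table of a :class:`DiscreteToySpec`.

    Rows enumerate every joint outcome of (y0, Omega, Lambda); columns are
    aligned arrays.  ``pattern_index`` maps each distinct doubly
    sub-sampled pattern to the row indices realising it.
    """

    spec: DiscreteToySpec
    y0: np.ndarray  # (n_outcomes, n)
    omega: np.ndarray  # (n_outcomes, n) bool
    lam: np.ndarray  # (n_outcomes, n) bool
    prob: np.ndarray  # (n_outcomes,)

    @property
    def y(self) -> np.ndarray:
        return self.y0 * self.omega

    @property
    def ytilde(self) -> np.ndarray:
        return self.y0 * self.omega * self.lam

    def patterns(self) -> dict[tuple, np.ndarray]:
        """Group outcome rows by their distinct doubly sub-sampled pattern."""
        yt = self.ytilde
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(yt):
            groups.setdefault(tuple(row.tolist()), []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


def _mask_outcomes(n: int, p: np.ndarray, columns) -> tuple[np.ndarray, np.ndarray]:
    """All mask indicator outcomes with probabilities, honouring coupling."""
    if columns is None:
        combos = np.array(list(itertools.product((0, 1), repeat=n)), dtype=bool)
        probs = np.prod(np.where(combos, p, 1 - p), axis=1)
        return combos, probs
    cols = np.unique(columns)
    col_p = np.array([p[columns == c][0] for c in cols])
    col_combos = np.array(list(itertools.product((0, 1), repeat=len(cols))), dtype=bool)
    probs = np.prod(np.where(col_combos, col_p, 1 - col_p), axis=1)
    combos = np.zeros((len(col_combos), n), dtype=bool)
    for j, c in enumerate(cols):
        combos[:, columns == c] = col_combos[:, [j]]
    return combos, probs


def enumerate_toy(spec: DiscreteToySpec, max_outcomes: int = 10_000_000) -> ToyTable:
    """Exhaustively enumerate (y0, Omega, Lambda) with joint probabilities.

    The total probability over all rows is 1 to within 1e-12.  Raises if the
    outcome count would exceed ``max_outcomes``.
    """
    a = len(spec.alphabet)
    n_y0 = a**spec.n
    om_combos, om_probs = _mask_outcomes(spec.n, spec.p, spec.columns)
    lm_combos, lm_probs = _mask_outcomes(spec.n, spec.p_tilde, spec.columns)
    total = n_y0 * len(om_combos) * len(lm_combos)
    if total > max_outcomes:
        raise ValueError(f"ensemble too large to enumerate ({total} outcomes)")

    y0_combos = np.array(list(itertools.product(spec.alphabet, repeat=spec.n)))
    idx_combos = np.array(list(itertools.product(range(a), repeat=spec.n)))
    y0_probs = np.prod(spec.value_probs[np.arange(spec.n), idx_combos], axis=1)

    iy, io, il = np.meshgrid(
        np.arange(n_y0), np.arange(len(om_combos)), np.arange(len(lm_combos)),
        indexing="ij",
    )
    iy, io, il = iy.ravel(), io.ravel(), il.ravel()
    prob = y0_probs[iy] * om_probs[io] * lm_probs[il]
    keep = prob > 0  # degenerate (probability-zero) outcomes carry no mass
    return ToyTable(
        spec=spec,
        y0=y0_combos[iy[keep]],
        omega=om_combos[io[keep]],
        lam=lm_combos[il[keep]],
        prob=prob[keep],
    )
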