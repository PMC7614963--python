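"""Training loops and the high-level reconstructor estimator.

Self-supervised training follows the second-mask protocol: the acquisition
mask of each slice is frozen for the whole run, while the partition mask is
redrawn for every slice at every epoch from its analytic distribution (the
per-epoch stream is seeded per (master seed, epoch, slice), so runs are
reproducible and streams are independent across slices).  The network sees
the doubly sub-sampled data and is optimised on the method's weighted
k-space L2 loss against the singly sub-sampled data; supervised training
regresses onto the fully sampled reference instead.

The public surface is the scikit-learn style
:class:`SelfSupervisedReconstructor` (``fit`` / ``predict`` /
``get_params``); :func:`train` and :func:`reconstruct` are the underlying
functional pieces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .correction import KMatrix, compute_K, n2n_correct_dc, n2n_correct_plain, ssdu_estimate
from .estimators import AdamState, UnrolledReconstructor, dc_wrap
from .losses import MethodSpec, Weighting, get_method, loss_weights
from .masks import (
    Mask,
    MaskDistribution,
    MaskStructure,
    build_bernoulli_density,
    build_column_density,
    sample_mask,
)
from .synth import SliceDataset

__all__ = [
    "TrainHistory",
    "lambda_stream_seed",
    "train",
    "reconstruct",
    "SelfSupervisedReconstructor",
]


@dataclass
class TrainHistory:
    """Per-epoch mean training loss (and optional validation loss)."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)


def lambda_stream_seed(master_seed: int, epoch: int, slice_idx: int) -> int:
    """Deterministic per-(epoch, slice) seed for partition-mask draws."""
    # small negative epochs are reserved stream ids (validation, inference)
    ss = np.random.SeedSequence([int(master_seed), int(epoch) + 65536, int(slice_idx)])
    return int(ss.generate_state(1)[0] % (2**31))


def _training_step_arrays(
    method: MethodSpec,
    dataset: SliceDataset,
    i: int,
    lam: Optional[Mask],
    K: Optional[KMatrix],
):
    """Assemble (input, input mask, target, loss weight) for one slice."""
    y = dataset.y(i)
    omega = dataset.omega(i)
    if method.self_supervised:
        combined = Mask(
            lam.indicator * omega.indicator, structure=MaskStructure.BERNOULLI_2D
        )
        y_in = lam.astype(float) * y
        target = y
        w = loss_weights(method, omega=omega, lam=lam, K=K)
        return y_in, combined, target, w
    target = dataset.ground_truth(i)
    w = np.ones(omega.shape)
    return y, omega, target, w


def _wrapped_loss_and_grad(
    net: UnrolledReconstructor,
    y_in: np.ndarray,
    in_mask: Mask,
    sens: np.ndarray,
    target: np.ndarray,
    weight: np.ndarray,
):
    """Loss/gradient through the hard data-consistency wrapper.

    The network output is wrapped as ``(1 - M) g + y_in`` before the loss,
    so sampled input locations contribute no residual and no gradient.
    """
    f_raw, tape = net.forward(y_in, in_mask, sens, keep_tape=True)
    m = in_mask.astype(float)
    f = (1.0 - m) * f_raw + y_in
    resid = f - target
    w2 = np.asarray(weight, dtype=float) ** 2
    loss = float(np.sum(w2 * np.abs(resid) ** 2))
    g_out = (1.0 - m) * (w2 * resid)
    grad = net.backward(g_out, y_in, in_mask, sens, tape)
    return loss, grad


def train(
    method,
    dataset: SliceDataset,
    estimator: UnrolledReconstructor,
    lambda_dist: Optional[MaskDistribution] = None,
    epochs: int = 50,
    lr: float = 1e-3,
    rng_seed: int = 0,
    K: Optional[KMatrix] = None,
    val_dataset: Optional[SliceDataset] = None,
    batch_size: int = 8,
) -> tuple[np.ndarray, TrainHistory]:
    """Train an estimator with a method's weighted k-space loss.

    For self-supervised methods the partition mask is redrawn per slice at
    every epoch from ``lambda_dist`` (which must satisfy ``p < 1``
    everywhere); supervised training uses the singly sub-sampled data as
    input and the fully sampled reference as target, and requires the
    dataset's ground truth to be exposed.  Gradients are averaged over
    mini-batches of ``batch_size`` slices before each Adam step, which
    keeps the gradient variance of the randomly re-partitioned (and
    density-weighted) self-supervised losses manageable at a fixed
    learning rate.  Epoch losses are summed over k-space and coils and
    averaged over slices.

    Returns the flat trained parameter vector and the loss history.
    """
    method = get_method(method)
    if method.self_supervised:
        if lambda_dist is None:
            raise ValueError("self-supervised training requires a partition-mask distribution")
        if np.any(lambda_dist.prob >= 1.0):
            raise ValueError(
                "partition-mask density must satisfy p < 1 everywhere "
                "(apply a cap, e.g. cap_epsilon=1e-3)"
            )
        if method.needs_K and K is None:
            if dataset.omega_dist is None:
                raise ValueError("need the acquisition density (dataset.omega_dist) to compute K")
            K = compute_K(dataset.omega_dist, lambda_dist)
    history = TrainHistory()
    # materialise grid-dependent parameters before flattening
    estimator._ensure_col_scales(dataset.grid_shape[1])
    theta = estimator.get_flat_params()
    opt = AdamState(lr=lr)
    # frozen validation partition masks for comparable validation losses
    val_lams = None
    if val_dataset is not None and method.self_supervised:
        val_lams = [
            sample_mask(lambda_dist, lambda_stream_seed(rng_seed, -1, i))
            for i in range(len(val_dataset))
        ]
    for epoch in range(epochs):
        losses = []
        grad_acc = np.zeros_like(theta)
        n_acc = 0
        for i in range(len(dataset)):
            lam = None
            if method.self_supervised:
                lam = sample_mask(lambda_dist, lambda_stream_seed(rng_seed, epoch, i))
            y_in, in_mask, target, w = _training_step_arrays(method, dataset, i, lam, K)
            estimator.set_flat_params(theta)
            loss, grad = _wrapped_loss_and_grad(
                estimator, y_in, in_mask, dataset.sens(i), target, w
            )
            grad_acc += grad
            n_acc += 1
            if n_acc == batch_size or i == len(dataset) - 1:
                theta = opt.step(theta, grad_acc / n_acc)
                grad_acc[:] = 0.0
                n_acc = 0
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)) if losses else math.nan)
        if val_dataset is not None:
            estimator.set_flat_params(theta)
            vlosses = []
            for i in range(len(val_dataset)):
                lam = val_lams[i] if val_lams is not None else None
                y_in, in_mask, target, w = _training_step_arrays(
                    method, val_dataset, i, lam, K
                )
                f_raw = estimator.forward(y_in, in_mask, val_dataset.sens(i))
                m = in_mask.astype(float)
                f = (1.0 - m) * f_raw + y_in
                vlosses.append(float(np.sum(w**2 * np.abs(f - target) ** 2)))
            history.val_loss.append(float(np.mean(vlosses)))
    estimator.set_flat_params(theta)
    return theta, history


def reconstruct(
    method,
    estimator: UnrolledReconstructor,
    y: np.ndarray,
    omega: Mask,
    sens: np.ndarray,
    K: Optional[KMatrix] = None,
    input_mode: str = "singly",
    lam: Optional[Mask] = None,
    lambda_dist: Optional[MaskDistribution] = None,
    rng_seed: int = 0,
) -> np.ndarray:
    """Estimate fully sampled k-space from acquired data with a trained net.

    ``input_mode="tilde"`` feeds the doubly sub-sampled data (a partition
    mask is drawn from ``lambda_dist`` unless ``lam`` is given) and applies
    the method's data-consistent estimator; ``"singly"`` feeds the acquired
    data directly and applies the method's plain estimator.  Unweighted
    Noisier2Noise requires the correction matrix ``K`` in both modes.
    """
    method = get_method(method)
    if input_mode not in ("tilde", "singly"):
        raise ValueError(f"unknown input mode {input_mode!r}")
    route = method.inference_tilde if input_mode == "tilde" else method.inference_singly
    if route.startswith("n2n") and K is None:
        raise ValueError("unweighted Noisier2Noise inference requires K")
    if input_mode == "tilde":
        if lam is None:
            if lambda_dist is None:
                raise ValueError("tilde input mode needs a partition mask or its distribution")
            lam = sample_mask(lambda_dist, rng_seed)
        combined = Mask(lam.indicator * omega.indicator)
        y_tilde = lam.astype(float) * y
        f = dc_wrap(estimator.forward(y_tilde, combined, sens), y_tilde, combined)
        if route == "n2n_dc":
            return n2n_correct_dc(f, y, omega, K)
        return ssdu_estimate(f, y, omega, mode="dc_tilde_input")
    f = dc_wrap(estimator.forward(y, omega, sens), y, omega)
    if route == "n2n_plain":
        return n2n_correct_plain(f, y, K)
    return ssdu_estimate(f, y, omega, mode="plain_y_input")


class SelfSupervisedReconstructor(BaseEstimator):
    """Scikit-learn style self-supervised k-space reconstruction estimator.

    Parameters
    ----------
    method : str
        One of ``"unweighted_n2n"``, ``"ssdu_2d"``, ``"ssdu_1d"``,
        ``"kweighted_ssdu_1d"``, ``"supervised"``.
    lambda_accel : float
        Acceleration of the partition-mask distribution (``R_Lambda``).
    lambda_order : int
        Polynomial order of the partition-mask density.
    lambda_center : int
        Central fully sampled extent of the partition mask (capped at
        ``1 - cap_epsilon``).
    cap_epsilon : float
        Cap on the partition density so ``p < 1`` everywhere.
    epochs, lr : training schedule (Adam, fixed learning rate).
    n_blocks, kernel_size : architecture of the unrolled network.
    random_state : int
        Master seed for initialisation and the per-epoch partition streams.

    Attributes (after ``fit``)
    --------------------------
    network_ : the trained :class:`UnrolledReconstructor`
    K_ : the correction matrix (when the method uses one)
    lambda_dist_ : the partition-mask distribution
    history_ : per-epoch loss history
    n_parameters_ : real parameter count of the network
    """

    def __init__(
        self,
        method: str = "kweighted_ssdu_1d",
        lambda_accel: float = 2.0,
        lambda_order: int = 8,
        lambda_center: int = 10,
        cap_epsilon: float = 1e-3,
        epochs: int = 50,
        lr: float = 1e-3,
        n_blocks: int = 4,
        kernel_size: int = 5,
        batch_size: int = 8,
        random_state: int = 0,
    ) -> None:
        self.method = method
        self.lambda_accel = lambda_accel
        self.lambda_order = lambda_order
        self.lambda_center = lambda_center
        self.cap_epsilon = cap_epsilon
        self.epochs = epochs
        self.lr = lr
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.batch_size = batch_size
        self.random_state = random_state

    def _build_lambda_dist(self, grid_shape) -> Optional[MaskDistribution]:
        spec = get_method(self.method)
        H, W = grid_shape
        if spec.lambda_structure is None:
            return None
        if spec.lambda_structure is MaskStructure.COLUMN_1D:
            return build_column_density(
                width=W,
                accel=self.lambda_accel,
                order=self.lambda_order,
                center_cols=self.lambda_center,
                cap_epsilon=self.cap_epsilon,
                height=H,
            )
        return build_bernoulli_density(
            height=H,
            width=W,
            accel=self.lambda_accel,
            order=self.lambda_order,
            center_size=self.lambda_center,
            cap_epsilon=self.cap_epsilon,
            low_freq_high_prob=False,
        )

    def fit(self, dataset: SliceDataset, val_dataset: Optional[SliceDataset] = None):
        """Train on a slice dataset (frozen acquisition masks required)."""
        spec = get_method(self.method)
        self.method_spec_ = spec
        self.lambda_dist_ = self._build_lambda_dist(dataset.grid_shape)
        self.K_ = None
        if spec.needs_K or spec.weighting is Weighting.K_HALF_SSDU_MASK:
            if dataset.omega_dist is None:
                raise ValueError("dataset must carry its acquisition density to compute K")
            self.K_ = compute_K(dataset.omega_dist, self.lambda_dist_)
        self.network_ = UnrolledReconstructor(
            n_blocks=self.n_blocks,
            kernel_size=self.kernel_size,
            seed=self.random_state,
            grid_width=dataset.grid_shape[1],
        )
        self.n_parameters_ = self.network_.n_parameters
        if spec.self_supervised:
            self.params_, self.history_ = train(
                spec,
                dataset,
                self.network_,
                lambda_dist=self.lambda_dist_,
                epochs=self.epochs,
                lr=self.lr,
                rng_seed=self.random_state,
                K=self.K_,
                val_dataset=val_dataset,
                batch_size=self.batch_size,
            )
        else:
            # supervised training reads the reference; the caller must have
            # exposed the ground truth explicitly or a GroundTruthError is
            # raised by the dataset
            self.params_, self.history_ = train(
                spec,
                dataset,
                self.network_,
                epochs=self.epochs,
                lr=self.lr,
                rng_seed=self.random_state,
                val_dataset=None,
                batch_size=self.batch_size,
            )
        return self

    def predict(
        self,
        y: np.ndarray,
        omega: Mask,
        sens: np.ndarray,
        input_mode: str = "singly",
        lam: Optional[Mask] = None,
        rng_seed: int = 0,
    ) -> np.ndarray:
        """Reconstruct fully sampled k-space for one slice."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        return reconstruct(
            self.method_spec_,
            self.network_,
            y,
            omega,
            sens,
            K=self.K_,
            input_mode=input_mode,
            lam=lam,
            lambda_dist=self.lambda_dist_,
            rng_seed=rng_seed,
        )

    def predict_dataset(self, dataset: SliceDataset, input_mode: str = "singly"):
        """Reconstruct every slice of a dataset; yields (slice_id, estimate)."""
        for i in range(len(dataset)):
            yield dataset.records[i].slice_id, self.predict(
                dataset.y(i),
                dataset.omega(i),
                dataset.sens(i),
                input_mode=input_mode,
                rng_seed=lambda_stream_seed(self.random_state, -2, i),
            )
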