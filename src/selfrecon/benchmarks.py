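"""Desk-scale end-to-end study: self-supervised vs supervised training.

Runs the full pipeline — simulate a multi-coil dataset with frozen
variable-density column masks, train the compact unrolled network under
identical budgets with each method, and measure test-set k-space NMSE —
at a size a single CPU handles in minutes.  The default conditions are
column-wise acquisition at acceleration 4 with 10 fully sampled central
columns, a column-wise partition mask at acceleration 2 capped at
``1 - 1e-3``, a 64 x 64 grid, 4 coils and 200 training slices; the
training budget is 100 epochs of Adam at the fixed default learning rate,
with gradients accumulated over 8 slices per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import nmse, rss_image, ssim
from .masks import build_column_density
from .synth import SliceDataset, make_dataset
from .training import SelfSupervisedReconstructor

__all__ = ["DeskStudyResult", "desk_study", "lambda_robustness_sweep"]


@dataclass
class DeskStudyResult:
    """Mean test NMSE (and SSIM) per method, plus study metadata."""

    nmse: dict
    ssim: dict
    n_train_slices: int
    n_test_slices: int
    epochs: int


def _mean_metrics(model: SelfSupervisedReconstructor, test_ds: SliceDataset, input_mode: str):
    nmses, ssims = [], []
    crop = min(test_ds.grid_shape)
    with test_ds.expose_ground_truth():
        for i in range(len(test_ds)):
            est = model.predict(
                test_ds.y(i), test_ds.omega(i), test_ds.sens(i), input_mode=input_mode
            )
            ref = test_ds.ground_truth(i)
            nmses.append(nmse(est, ref))
            ssims.append(ssim(rss_image(est, crop=crop), rss_image(ref, crop=crop)))
    return float(np.mean(nmses)), float(np.mean(ssims))


def desk_study(
    seed: int = 0,
    methods: Sequence[str] = ("supervised", "kweighted_ssdu_1d", "unweighted_n2n"),
    height: int = 64,
    width: int = 64,
    n_coils: int = 4,
    r_omega: float = 4.0,
    r_lambda: float = 2.0,
    n_train_volumes: int = 40,
    slices_per_volume: int = 5,
    n_test_volumes: int = 4,
    test_slices_per_volume: int = 4,
    epochs: int = 100,
    input_mode: str = "singly",
) -> DeskStudyResult:
    """Train each method under an identical budget and measure test NMSE.

    Every method sees the same dataset (same frozen acquisition masks), the
    same network architecture and initialisation, and the same optimizer
    budget; only the loss weighting, partition distribution and inference
    estimator differ.
    """
    omega_dist = build_column_density(width, r_omega, order=8, center_cols=10, height=height)
    train_ds = make_dataset(
        n_train_volumes, slices_per_volume, omega_dist, rng_seed=seed, n_coils=n_coils
    )
    test_ds = make_dataset(
        n_test_volumes,
        test_slices_per_volume,
        omega_dist,
        rng_seed=seed + 10_000,
        n_coils=n_coils,
    )
    out_nmse, out_ssim = {}, {}
    for method in methods:
        model = SelfSupervisedReconstructor(
            method=method,
            lambda_accel=r_lambda,
            epochs=epochs,
            random_state=seed,
        )
        if method == "supervised":
            with train_ds.expose_ground_truth():
                model.fit(train_ds)
        else:
            model.fit(train_ds)
        out_nmse[method], out_ssim[method] = _mean_metrics(model, test_ds, input_mode)
    return DeskStudyResult(
        nmse=out_nmse,
        ssim=out_ssim,
        n_train_slices=len(train_ds),
        n_test_slices=len(test_ds),
        epochs=epochs,
    )


def lambda_robustness_sweep(
    seed: int = 0,
    r_lambdas: Sequence[float] = (1.2, 1.6, 2.0, 4.0, 6.0),
    method: str = "kweighted_ssdu_1d",
    epochs: int = 10,
    n_train_volumes: int = 10,
    slices_per_volume: int = 5,
    **kwargs,
) -> dict:
    """Test NMSE of one method across partition accelerations (reduced size).

    A smaller, faster variant of :func:`desk_study` used to log how
    sensitive a method is to the tuning of the partition acceleration.
    """
    out = {}
    for rl in r_lambdas:
        res = desk_study(
            seed=seed,
            methods=(method,),
            r_lambda=rl,
            epochs=epochs,
            n_train_volumes=n_train_volumes,
            slices_per_volume=slices_per_volume,
            n_test_volumes=2,
            test_slices_per_volume=4,
            **kwargs,
        )
        out[rl] = res.nmse[method]
    return out
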