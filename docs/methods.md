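# Methods

## Problem setting

Accelerated Cartesian MRI acquires only a random subset Ω of the k-space
grid, with per-location sampling probabilities `p_j` that are higher at low
spatial frequencies ("variable density").  With multi-coil data
`y = M_Ω y₀`, a network `f_θ` can be trained to estimate the fully sampled
`y₀` — but fully sampled references are often unavailable.  This package
implements *self-supervised* training: during training a second random mask
Λ further sub-samples the acquired data, `ỹ = M_Λ M_Ω y₀`, and the network
learns to predict the acquired data `y` from the doubly sub-sampled `ỹ`.

Two exact expectation identities make this work, and both are verified in
this package by brute-force enumeration on discrete toy ensembles:

1. **Correction identity.**  With `P = E[M_Ω]`, `P̃ = E[M_Λ]` and the
   diagonal matrix

       K = (1 − P̃P)⁻¹(1 − P),        k_j = (1 − p_j) / (1 − p̃_j p_j),

   the conditional expectation of the fully sampled data satisfies
   `E[Y₀|Ỹ] = (1 − K)⁻¹ (E[Y|Ỹ] − K Ỹ)` whenever `p_j > 0`, `p̃_j < 1`,
   and Λ is independent of (Ω, Y₀).  A network trained with a full-rank
   weighted ℓ2 loss converges (in expectation) to `E[Y|Ỹ]`, so applying the
   `(1 − K)⁻¹` correction at inference de-biases it.  This is the
   multiplicative-noise Noisier2Noise construction generalised to variable
   density.

2. **Partition-training identity.**  Writing the acquired set as the
   disjoint union `A = Ω\Λ` (loss set) and `B = Ω∩Λ` (input set), training
   with the rank-deficient weighting `W = (1 − M_Λ)M_Ω` — i.e. computing
   the loss only on A, which is exactly the SSDU scheme — yields a network
   whose minimiser equals `E[Y₀|Ỹ]` at every location *not* sampled in ỹ,
   with no correction needed.  Locations with zero conditional loss mass
   are unconstrained (the weighting is rank deficient there).

A third identity, that any strictly positive diagonal weighting leaves the
full-rank conditional minimiser at `E[Y|Ỹ]`, is also enumerated.

The loss-decomposition identity explains the difference between the two
training schemes: for a network that is exactly consistent with its input
(`f = ỹ` on B), the identity-weighted loss splits exactly into the
partition (SSDU) term plus `‖W(1 − M_Ω)f‖²`, a pure-shrinkage penalty on
never-acquired k-space.  That second term is what biases the unweighted
scheme low and necessitates the `(1 − K)⁻¹` correction; under the partition
weighting it is identically zero.

### K-weighted partition training

With finite data the trained network only approximates the ideal
minimiser; the residual statistical error at location j is amplified by
`(1 − k_j)⁻¹ = P(j ∉ Λ∩Ω)/P(j ∈ Ω\Λ)` — large exactly where the loss set
rarely contains j.  Weighting the partition loss by `(1 − K)^(−1/2)`
cancels this amplification.  This is the "K-weighted" variant, and the
end-to-end study below compares it against the supervised ceiling and the
unweighted corrected scheme.

## Sampling distributions and masks

Two mask structures are implemented: column-wise (whole phase-encode
columns acquired together; readout fully sampled) and independent 2D
Bernoulli.  Densities are polynomial, `p(d) ∝ (1 − |d|)^order` with `d` the
distance from the centre normalised to lie strictly inside (−1, 1) (so
`p_j > 0` everywhere, as the correction identity requires), with a fully
sampled central region (10 columns / 10×10 square by default, polynomial
order 8).  Partition densities are capped at `1 − ε` everywhere
(`ε = 10⁻³` by default) so `p̃_j < 1`; the cap is applied to the whole
density rather than only the centre, which changes nothing where the
density is already below it.  A "high-frequencies-more-likely" radial
variant (`d^order`) is provided for 2D partition masks.

The density is scaled to a target acceleration `R = N/Σp` by bisection on
a scalar multiplier with clipping at the cap; the achieved acceleration is
within 0.5% of target or construction fails.  Acquisition masks are drawn
once per slice and frozen for the whole run (as for prospectively
sub-sampled data); partition masks are redrawn every epoch from per-(seed,
epoch, slice) `SeedSequence` streams, so runs are exactly reproducible.
Densities of procedural samplers with no closed form can be estimated by
Monte-Carlo averaging of mask draws (1000 draws is the convention used for
the K computation) and fed to `compute_K` like any analytic density.

`compute_K` evaluates `k_j` in double precision and clips `(1 − k_j)⁻¹` at
a configurable maximum (default 10⁶, with a warning): the weight diverges
where the acquisition density approaches 0 or the partition density
approaches 1.

## The trainable estimator

The reconstruction network is a compact physics-guided unrolled estimator
written in numpy.  Each of the (default 4) blocks maps the k-space state
κ through

    x  = E^H κ                       coil combine (adjoint encode)
    κ' = κ + E·conv(x, w_b) + c_b·κ  learned refinement
    κ  ← κ' − η_b M (κ' − y_in)      soft data consistency

where `E x = F(S_c x)` with the centred **unitary** FFT and simulator
coil sensitivities, `w_b` is a small complex image-domain kernel (default
5×5), `c_b` a complex per-column k-space scaling (a learned
density-compensation term matched to column sampling), and `η_b` a
learnable step size.  A hard data-consistency wrapper
`(1 − M) f + y_in` is applied outside the network, so the consistency
precondition of the loss decomposition holds by construction.

All operations are complex-linear, so the loss gradient follows exactly
from Wirtinger calculus (`∂L/∂Re w = 2 Re ∂L/∂w̄`, etc.); the backward
pass applies the adjoint of each forward operation in reverse and is
checked against finite differences in the test suite.  With all
refinement parameters at zero the network is the identity on its input,
so the untrained model returns the zero-filled (dc-filled) measurements.
Because the model is linear in its input, it cannot exploit image priors
the way a deep nonlinear network does; it can only learn the optimal
linear (filter + density-compensation) reconstruction, which is the
honest capacity at which the training-scheme comparison below is made.

Coil sensitivities are taken from the simulator rather than estimated:
sensitivity estimation is a separable concern and masking its input has
been reported to change results at the percent level.

## Training protocol

Adam with a fixed learning rate of 10⁻³ for 50 epochs are the config
defaults.  Gradients are averaged over mini-batches of 8 slices before
each step: with single-slice steps at a fixed learning rate, the
stochasticity of the per-epoch partition redraw plus the heavy-tailed
K-weights leaves the self-supervised runs at a noticeably higher
gradient-noise floor, and batching reduces that variance identically for
every method without touching the per-epoch redraw protocol.  Weight
initialisation is zeros (identity network); no early stopping.
Self-supervised runs can never touch the fully sampled reference: the
dataset object raises `GroundTruthError` unless evaluation or supervised
training explicitly exposes it, and the training loop is tested to leave
the dataset locked.

Method menu (each row fixes the loss weighting W, the partition-mask
structure, and the two inference estimators):

| method               | W                          | Λ structure | ỹ-input estimate              | y-input estimate        |
|----------------------|----------------------------|-------------|-------------------------------|-------------------------|
| `unweighted_n2n`     | 𝟙                          | column      | (𝟙−M_Ω)(𝟙−K)⁻¹f(ỹ) + y        | (𝟙−K)⁻¹(f(y) − Ky)      |
| `ssdu_2d`            | (𝟙−M_Λ)M_Ω                 | Bernoulli   | (𝟙−M_Ω)f(ỹ) + y               | f(y)                    |
| `ssdu_1d`            | (𝟙−M_Λ)M_Ω                 | column      | (𝟙−M_Ω)f(ỹ) + y               | f(y)                    |
| `kweighted_ssdu_1d`  | (𝟙−K)^(−1/2)(𝟙−M_Λ)M_Ω     | column      | (𝟙−M_Ω)f(ỹ) + y               | f(y)                    |
| `supervised`         | 𝟙 (target y₀)              | —           | —                             | f(y)                    |

Only the ℓ2 loss is supported: the correction identity is specific to it.

## Synthetic data

The generator produces random-ellipse phantoms (lightly smoothed, with
low-order polynomial phase), smooth complex coil maps normalised to unit
root-sum-of-squares at every pixel, and per-coil k-space via the centred
unitary FFT, so Parseval holds and k-space NMSE equals coil-image NMSE.
At least 90% of phantom spectral energy lies in the central half-band of
each dimension, the regime that justifies variable-density sampling.
Simulation is noise-free (an additive-noise hook exists but defaults off
and is untested against any claim).  What the generator does *not*
emulate: anatomical structure and contrast, measurement noise, zero-padded
asymmetric k-space, motion/phase drift between acquisitions, and realistic
coil geometries — so passing desk-scale tests demonstrates the mechanics
and statistics of the training schemes, not clinical image quality.

The discrete toy generator enumerates every joint outcome of
(y₀, Ω, Λ) for ensembles of up to 8 locations with a finite nonzero
alphabet (zero is excluded so a zero in ỹ unambiguously marks an
unsampled location) and optional column coupling; conditional
expectations are then exact sums, which is what makes the identity checks
oracles rather than approximations.

## Metrics

NMSE is `‖ŷ − y₀‖²/‖y₀‖²` over all coils and k-space locations.  RSS
images are `(Σ_c |F^H y_c|²)^{1/2}`, centrally cropped to 320×320 when the
grid is at least that large (synthetic grids are smaller; the crop is then
skipped with a warning).  SSIM uses the common evaluation convention:
7×7 uniform window, K1 = 0.01, K2 = 0.03, data range set by the reference
maximum.

## Desk-scale study configuration

The end-to-end comparison (`selfrecon.benchmarks.desk_study`) uses a
64×64 grid, 4 coils, column acquisition at R_Ω = 4 with 10 central
columns, column partition at R_Λ = 2 capped at 1 − 10⁻³, 200 training
slices (40 volumes × 5), 16 test slices, and a budget of 100 epochs with
batch-8 Adam at lr 10⁻³ — identical for every method; each run takes a
few minutes on one CPU.  Typical results (seed 101): supervised NMSE
0.0024, K-weighted partition training 0.0035 (ratio ≈ 1.44), unweighted
corrected training ≫ 1 because its `(1 − K)⁻¹` inference correction
amplifies the network's error by up to the clip value where the
acquisition density is tiny — the failure mode the K-weighted loss is
designed to avoid.  A reduced-size sweep over R_Λ ∈ {1.2, 1.6, 2, 4, 6}
is logged (not asserted) by the acceptance script.

## Numerical choices and edge cases

- Identity checks use a 10⁻¹⁰ tolerance: the claims are identities, so
  enumerated deviations sit at float precision; anything larger marks a
  logic error.
- Ties in centring: the central region of an even-sized axis is the block
  centred on index `size // 2`, left-biased.
- Masks broadcast identically across coils (physical Cartesian sampling is
  coil-independent).
- `loss_decomposition` validates its consistency precondition to a scaled
  8-digit absolute tolerance before using the identity.
- Empty partition input sets make the ratio |A|/|B| undefined
  (`ZeroDivisionError`); zero-weight coordinates in the full-rank
  minimiser check are reported unconstrained and excluded.

## Known limitations

- The estimator is linear; absolute NMSE numbers are far from what deep
  unrolled networks achieve on scanner data, and only the *relative*
  behaviour of the training schemes is meaningful at desk scale.
- Regular (equidistant) under-sampling is out of scope: the partition
  theory as implemented assumes random masks with known densities.
- The measured-data path (fastMRI-dialect reader) reads raw k-space only
  and is not exercised by any shipped experiment.
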