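"""Exact enumeration oracles for the expectation identities behind the
self-supervised training methods.

On enumerable discrete ensembles (a few k-space locations, a finite nonzero
alphabet, fully enumerable mask draws) the conditional expectations that the
theory reasons about can be computed exactly.  Three identities are checked:

1. **Correction identity** — the fully sampled data is recovered in
   expectation from the doubly sub-sampled data by the diagonal correction:
   ``E[Y0 | Ytilde] = (1 - K)^(-1) (E[Y | Ytilde] - K Ytilde)``.

2. **Partition-training identity** — the minimiser of the partition-masked
   (SSDU-style) conditional loss equals ``E[Y0 | Ytilde]`` at every k-space
   location *not* sampled in the doubly sub-sampled data, with no
   correction term.

3. **Full-rank minimiser** — for any strictly positive diagonal weighting
   the conditional L2 minimiser is ``E[Y | Ytilde]``: the weighting does not
   move a full-rank minimum.

All three are identities, so the enumerated deviations sit at floating-point
precision (<= 1e-10) for every valid ensemble; that tolerance separates
identity-level agreement from any logic error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .synth import DiscreteToySpec, ToyTable, enumerate_toy

__all__ = [
    "ConditionalTable",
    "conditional_expectations",
    "conditionals_from_table",
    "verify_claim1",
    "verify_claim2",
    "verify_fullrank_minimizer",
    "random_toy_spec",
    "sweep_random_specs",
]

IDENTITY_TOL = 1e-10


@dataclass
class ConditionalTable:
    """Exact conditionals per reachable doubly sub-sampled pattern."""

    patterns: np.ndarray  # (n_patterns, n) the distinct ytilde values
    prob: np.ndarray  # (n_patterns,) pattern probabilities (sum to 1)
    e_y: np.ndarray  # (n_patterns, n) E[Y | Ytilde = pattern]
    e_y0: np.ndarray  # (n_patterns, n) E[Y0 | Ytilde = pattern]
    table: ToyTable


def conditional_expectations(spec: DiscreteToySpec) -> ConditionalTable:
    """Brute-force ``E[Y | Ytilde]`` and ``E[Y0 | Ytilde]`` per pattern."""
    return conditionals_from_table(enumerate_toy(spec))


def conditionals_from_table(table: ToyTable) -> ConditionalTable:
    """Conditionals from an explicit outcome table.

    Accepts hand-built tables too, e.g. with statistically dependent masks,
    which is how the independence requirement on the second mask can be
    probed: a fully correlated second mask breaks the correction identity.
    """
    groups = table.patterns()
    y = table.y
    pats, probs, e_y, e_y0 = [], [], [], []
    for pat, rows in groups.items():
        w = table.prob[rows]
        mass = w.sum()
        pats.append(pat)
        probs.append(mass)
        e_y.append((w[:, None] * y[rows]).sum(axis=0) / mass)
        e_y0.append((w[:, None] * table.y0[rows]).sum(axis=0) / mass)
    return ConditionalTable(
        patterns=np.asarray(pats, dtype=float),
        prob=np.asarray(probs),
        e_y=np.asarray(e_y),
        e_y0=np.asarray(e_y0),
        table=table,
    )


def _k_diag(spec: DiscreteToySpec) -> np.ndarray:
    return (1.0 - spec.p) / (1.0 - spec.p_tilde * spec.p)


def verify_claim1(spec: DiscreteToySpec, cond: Optional[ConditionalTable] = None) -> float:
    """Max deviation of ``(1-K)^(-1)(E[Y|yt] - K yt)`` from ``E[Y0|yt]``.

    The deviation is taken over every reachable doubly sub-sampled pattern
    and every location; it is zero (to float precision) whenever the
    ensemble satisfies ``p > 0`` and ``p~ < 1`` and the second mask is
    independent of the first mask and the data.
    """
    cond = cond or conditional_expectations(spec)
    k = _k_diag(spec)
    corrected = (cond.e_y - k[None, :] * cond.patterns) / (1.0 - k)[None, :]
    return float(np.max(np.abs(corrected - cond.e_y0)))


def verify_claim2(spec: DiscreteToySpec, cond: Optional[ConditionalTable] = None) -> float:
    """Max deviation of the partition-loss minimiser from ``E[Y0|yt]``.

    For each reachable pattern the unconstrained coordinatewise minimiser of
    ``E[ || (1 - M_L) M_O (f - Y) ||^2 | Ytilde = yt ]`` is the conditional
    weighted mean ``f*_j = E[a_j Y_j | yt] / E[a_j | yt]`` with the loss-set
    indicator ``a_j = (1 - M_L,j) M_O,j``.  The deviation is measured only
    at locations not sampled in the pattern (``yt_j = 0``); locations with
    zero conditional loss mass are unconstrained by the loss and excluded.
    """
    cond = cond or conditional_expectations(spec)
    table = cond.table
    groups = table.patterns()
    a = table.omega & ~table.lam  # loss-set membership per outcome
    y = table.y
    dev = 0.0
    for pat, rows in groups.items():
        pat_arr = np.asarray(pat)
        w = table.prob[rows]
        mass_a = (w[:, None] * a[rows]).sum(axis=0)
        num = (w[:, None] * a[rows] * y[rows]).sum(axis=0)
        unsampled = pat_arr == 0.0
        constrained = unsampled & (mass_a > 0)
        if not np.any(constrained):
            continue
        f_star = num[constrained] / mass_a[constrained]
        idx = np.where(np.all(np.isclose(cond.patterns, pat_arr), axis=1))[0][0]
        dev = max(dev, float(np.max(np.abs(f_star - cond.e_y0[idx][constrained]))))
    return dev


def verify_fullrank_minimizer(
    spec: DiscreteToySpec,
    weights: Optional[np.ndarray] = None,
    cond: Optional[ConditionalTable] = None,
) -> float:
    """Max deviation of the W-weighted conditional minimiser from ``E[Y|yt]``.

    ``weights`` is a strictly positive diagonal (defaults to all ones).  The
    minimiser of ``E[||W (f - Y)||^2 | yt]`` is computed per coordinate as
    the W^2-weighted conditional mean; for full-rank W this equals
    ``E[Y|yt]`` exactly.  A zero weight leaves its coordinate unconstrained
    and it is excluded from the deviation.
    """
    cond = cond or conditional_expectations(spec)
    w = np.ones(spec.n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    table = cond.table
    groups = table.patterns()
    y = table.y
    dev = 0.0
    active = w > 0
    for pat, rows in groups.items():
        p = table.prob[rows]
        mass = p.sum()
        # W is deterministic, so the weighted minimiser is the plain mean;
        # computing it through the weighted normal equations keeps the check honest
        num = (p[:, None] * (w**2)[None, :] * y[rows]).sum(axis=0)
        den = mass * w**2
        f_star = num[active] / den[active]
        idx = np.where(np.all(np.isclose(cond.patterns, np.asarray(pat)), axis=1))[0][0]
        dev = max(dev, float(np.max(np.abs(f_star - cond.e_y[idx][active]))))
    return dev


def random_toy_spec(rng: np.random.Generator, coupled: Optional[bool] = None) -> DiscreteToySpec:
    """Draw a random valid enumerable ensemble (n <= 4).

    Probabilities are kept inside (0.05, 0.95) so both mask preconditions
    hold with margin; the alphabet is a random pair of nonzero values with
    random per-location value probabilities; roughly half the draws use
    column-coupled masks.
    """
    n = int(rng.integers(2, 5))
    if coupled is None:
        coupled = bool(rng.integers(0, 2))
    p = rng.uniform(0.05, 0.95, size=n)
    pt = rng.uniform(0.05, 0.95, size=n)
    columns = None
    if coupled:
        n_cols = max(1, n // 2)
        columns = np.sort(rng.integers(0, n_cols, size=n))
        for c in np.unique(columns):
            sel = columns == c
            p[sel] = p[sel][0]
            pt[sel] = pt[sel][0]
    vals = rng.uniform(0.5, 2.0, size=2) * rng.choice([-1.0, 1.0], size=2)
    vp = rng.uniform(0.2, 0.8, size=(n, 1))
    value_probs = np.hstack([vp, 1 - vp])
    return DiscreteToySpec(
        n=n, alphabet=vals, p=p, p_tilde=pt, value_probs=value_probs, columns=columns
    )


def sweep_random_specs(n_specs: int = 50, rng_seed: int = 0) -> dict[str, float]:
    """Run all three oracle checks over randomized ensembles.

    Returns the worst-case deviations over the sweep, each of which is at
    floating-point level for valid ensembles.
    """
    rng = np.random.default_rng(rng_seed)
    worst = {"claim1": 0.0, "claim2": 0.0, "fullrank_identity": 0.0, "fullrank_random_w": 0.0}
    for _ in range(n_specs):
        spec = random_toy_spec(rng)
        cond = conditional_expectations(spec)
        worst["claim1"] = max(worst["claim1"], verify_claim1(spec, cond))
        worst["claim2"] = max(worst["claim2"], verify_claim2(spec, cond))
        worst["fullrank_identity"] = max(
            worst["fullrank_identity"], verify_fullrank_minimizer(spec, cond=cond)
        )
        w = rng.uniform(0.1, 3.0, size=spec.n)
        worst["fullrank_random_w"] = max(
            worst["fullrank_random_w"], verify_fullrank_minimizer(spec, weights=w, cond=cond)
        )
    return worst
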