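"""Model-averaged latent entropy and latent dimension.

Every candidate latent dimension K = 1..n is fit by DBMR, scored by a
corrected Akaike information criterion

    AICc_K = N * S_K + V_K + V_K (V_K + 1) / (N - V_K - 1),

and converted to a posterior weight p_K ∝ exp(-(AICc_K - min AICc)).  The
two measures are the posterior expectations

    S_bar = sum_K p_K S_K        (latent entropy, nats)
    K_bar = sum_K p_K K          (latent dimension)

K_bar = 1 means the final state carries no memory of the initial one;
S_bar = 0 means the transition outcome is perfectly predictable.  The sum
runs over the *effective* alphabet: categories never observed in a sample
(zero row and column of C) are dropped before fitting, since they would
leave emission columns undefined and inflate V_K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ContingencyTable, PairSample, check_sample_size, contingency
from .reduction import fit_reduced_model, parameter_count

__all__ = [
    "LatentMeasures",
    "SampleSizeWarning",
    "aicc",
    "akaike_weights",
    "latent_measures",
    "latent_measures_from_table",
]


class SampleSizeWarning(UserWarning):
    """Fewer transition pairs than n²: measures computed but less accurate."""


@dataclass(frozen=True)
class LatentMeasures:
    """Posterior weights over latent dimensions and the averaged measures.

    ``p``, ``S_per_K`` and ``AICc_per_K`` have length ``n_effective`` and
    are indexed by K - 1.  ``AICc_per_K`` may contain ``+inf`` (models
    excluded for having more parameters than data, or duplicates of the
    largest feasible model); such entries carry zero weight.
    """

    p: np.ndarray
    S_bar: float
    K_bar: float
    S_per_K: np.ndarray
    AICc_per_K: np.ndarray
    n_effective: int
    sample_size_ok: bool = True


def aicc(S: float, V: int, n_pairs: int) -> float:
    """Corrected AIC of a model with cross-entropy ``S`` (nats) and ``V``
    parameters scored on ``n_pairs`` transition pairs.  Returns ``+inf``
    when the correction denominator ``N - V - 1`` is nonpositive, which
    excludes the model from averaging."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    denom = n_pairs - V - 1
    if denom <= 0 or not np.isfinite(S):
        return float("inf")
    return float(n_pairs * S + V + V * (V + 1) / denom)


def akaike_weights(aicc_values) -> np.ndarray:
    """Posterior model weights p_K ∝ exp(-(AICc_K - min_K AICc_K)).

    ``+inf`` entries receive exactly zero weight; at least one entry must
    be finite.
    """
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("all AICc values are infinite; no model can be weighted")
    w = np.zeros_like(a)
    w[finite] = np.exp(-(a[finite] - a[finite].min()))
    return w / w.sum()


def latent_measures_from_table(table: ContingencyTable, seed: int = 0) -> LatentMeasures:
    """Compute the latent measures from a precomputed contingency table.

    This is the workhorse used by the video pipeline, where the table is
    accumulated directly from category codes without materializing pairs.
    """
    C = table.C
    observed = (C.sum(axis=0) + C.sum(axis=1)) > 0
    n_eff = int(observed.sum())
    ok = table.n_pairs > n_eff ** 2
    if n_eff == 1:
        one = np.ones(1)
        a0 = aicc(0.0, parameter_count(1, 1), table.n_pairs)
        return LatentMeasures(p=one, S_bar=0.0, K_bar=1.0,
                              S_per_K=np.zeros(1), AICc_per_K=np.array([a0]),
                              n_effective=1, sample_size_ok=ok)

    sub = ContingencyTable(C=C[np.ix_(observed, observed)], n_pairs=table.n_pairs)
    S = np.full(n_eff, np.nan)
    A = np.full(n_eff, np.inf)
    for K in range(1, n_eff + 1):
        model = fit_reduced_model(sub, K, seed=seed)
        if model.capped:
            # duplicate of the largest feasible model; excluded from the average
            continue
        S[K - 1] = model.S
        A[K - 1] = aicc(model.S, model.V, table.n_pairs)
    p = akaike_weights(A)
    Ks = np.arange(1, n_eff + 1, dtype=float)
    S_bar = float(np.sum(p[p > 0] * S[p > 0]))
    K_bar = float(np.sum(p * Ks))
    return LatentMeasures(p=p, S_bar=S_bar, K_bar=K_bar, S_per_K=S,
                          AICc_per_K=A, n_effective=n_eff, sample_size_ok=ok)


def latent_measures(sample: PairSample, seed: int = 0) -> LatentMeasures:
    """Latent entropy and latent dimension of one observation sample.

    Warns (:class:`SampleSizeWarning`) when the sample has no more than n²
    pairs; the measures are still computed.
    """
    if not check_sample_size(sample):
        warnings.warn(
            f"sample has {sample.n_pairs} pairs for an alphabet of "
            f"{sample.alphabet.n} categories (need > n^2 for accuracy)",
            SampleSizeWarning,
            stacklevel=2,
        )
    return latent_measures_from_table(contingency(sample), seed=seed)
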