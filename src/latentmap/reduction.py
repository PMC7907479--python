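"""Direct Bayesian model reduction (DBMR) of categorical transition laws.

The empirical transition law of a categorical process is routed through a
latent variable with ``K`` states: ``Lambda_K = lamb_K @ gamma_K``, where
``gamma_K[k, i] = P[L = l_k | X = x_i]`` affiliates each input category
with a latent state and ``lamb_K[j, k] = P[Y = x_j | L = l_k]`` emits the
final category.  Affiliations are hard (0/1): DBMR assigns the ``n`` input
categories to ``K`` nonempty groups and gives each group the count-weighted
average of its members' empirical outgoing distributions — the
cross-entropy-optimal emission for that grouping.

The quality of a reduced model is its cross-entropy against the average
contingency table ``C``:

    S_K = -sum_ij C[j, i] * log( (lamb_K @ gamma_K)[j, i] )      (nats)

with the convention 0·log 0 = 0.  ``fit_reduced_model`` minimizes S_K by
alternating reassignment sweeps from several initializations;
``exhaustive_reduced_model`` enumerates every set partition and is the
slow, exact oracle used to validate the heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ContingencyTable

__all__ = [
    "TransitionMatrix",
    "ReducedModel",
    "model_entropy",
    "fit_reduced_model",
    "exhaustive_reduced_model",
    "compose_transition",
    "parameter_count",
]

_LOG_FLOOR = 1e-300  # keeps sweep costs finite; exact entropies use the 0·log0 rule


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic matrix ``Lambda[j, i] = P[Y = x_j | X = x_i]``."""

    Lambda: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.Lambda, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("Lambda must be square")
        if L.min() < -1e-12 or L.max() > 1 + 1e-12:
            raise ValueError("Lambda entries must lie in [0, 1]")
        if np.max(np.abs(L.sum(axis=0) - 1.0)) > 1e-12:
            raise ValueError("Lambda columns must sum to 1")
        object.__setattr__(self, "Lambda", L)

    @property
    def n(self) -> int:
        return self.Lambda.shape[0]


@dataclass
class ReducedModel:
    """A K-state reduction of an n-category transition law.

    Attributes
    ----------
    K:
        Latent dimension of this model.
    gamma:
        (K, n) hard affiliation matrix; each column has a single 1.
    lamb:
        (n, K) column-stochastic emission matrix.
    S:
        Cross-entropy of the model against the contingency table (nats).
    V:
        Effective parameter count ``(n - 1) K + n (K - 1)``.
    aicc:
        Corrected-AIC score; NaN until scored against a sample size.
    capped:
        True when the requested latent dimension exceeded the number of
        input categories that actually occur as initial states, in which
        case the returned model uses that smaller K.
    """

    K: int
    gamma: np.ndarray
    lamb: np.ndarray
    S: float
    V: int
    aicc: float = float("nan")
    capped: bool = False

    @property
    def n(self) -> int:
        return self.gamma.shape[1]


def parameter_count(n: int, K: int) -> int:
    """Effective number of free parameters V_K = (n-1)K + n(K-1)."""
    return (n - 1) * K + n * (K - 1)


def model_entropy(C: ContingencyTable, model: ReducedModel) -> float:
    """Cross-entropy  -sum_ij C_ij log[(lamb gamma)_ij]  in nats.

    Returns ``+inf`` exactly when some observed transition (C_ij > 0) has
    zero model probability.
    """
    Cm = C.C
    if model.n != C.n:
        raise ValueError(
            f"model is over {model.n} categories but table has {C.n}"
        )
    P = model.lamb @ model.gamma
    mask = Cm > 0
    if np.any(P[mask] <= 0):
        return float("inf")
    return float(-(Cm[mask] * np.log(P[mask])).sum())


def _emission_for(Csub: np.ndarray, assign: np.ndarray, K: int) -> np.ndarray:
    """Closed-form optimal emission: count-weighted average of the empirical
    conditional columns grouped into each latent state.  ``Csub`` must have
    strictly positive column sums and every state nonempty."""
    n = Csub.shape[0]
    lamb = np.zeros((n, K))
    for k in range(K):
        members = assign == k
        block = Csub[:, members]
        lamb[:, k] = block.sum(axis=1)
    lamb /= lamb.sum(axis=0, keepdims=True)
    return lamb


def _partition_entropy(Csub: np.ndarray, assign: np.ndarray, K: int) -> float:
    lamb = _emission_for(Csub, assign, K)
    P = lamb[:, assign]  # (n, m): model probability of column i's transitions
    mask = Csub > 0
    return float(-(Csub[mask] * np.log(P[mask])).sum())


def _state_cost(M: np.ndarray) -> float:
    """Entropy mass of an aggregated state column M (sum of member columns
    of C):  f(M) = -sum_j M_j log(M_j / |M|).  The cost of a partition is
    the sum of f over its states, which makes exact move deltas cheap."""
    total = M.sum()
    if total <= 0:
        return 0.0
    nz = M > 0
    return float(-(M[nz] * (np.log(M[nz]) - np.log(total))).sum())


def _sweep_fit(Csub: np.ndarray, assign: np.ndarray, K: int, max_iter: int = 500):
    """Reassignment sweeps with exact cost deltas until no move improves.

    Moving column i from state a to state b changes the partition cost by
    f(M_a - c_i) + f(M_b + c_i) - f(M_a) - f(M_b); each sweep applies, per
    column, the best strictly improving move (ties: lowest state index).
    Sole members stay put so every state remains nonempty.
    """
    m = Csub.shape[1]
    assign = assign.copy()
    M = np.stack([Csub[:, assign == k].sum(axis=1) for k in range(K)])
    f = np.array([_state_cost(M[k]) for k in range(K)])
    counts = np.bincount(assign, minlength=K)
    for _ in range(max_iter):
        changed = False
        for i in range(m):
            a = assign[i]
            if counts[a] == 1:
                continue
            c = Csub[:, i]
            f_a_without = _state_cost(M[a] - c)
            best_k, best_delta = a, -1e-15
            for b in range(K):
                if b == a:
                    continue
                delta = (f_a_without + _state_cost(M[b] + c)) - (f[a] + f[b])
                if delta < best_delta:
                    best_k, best_delta = b, delta
            if best_k != a:
                M[a] -= c
                M[best_k] += c
                f[a] = _state_cost(M[a])
                f[best_k] = _state_cost(M[best_k])
                counts[a] -= 1
                counts[best_k] += 1
                assign[i] = best_k
                changed = True
        if not changed:
            break
    return assign, _partition_entropy(Csub, assign, K)


def _expand_model(C: ContingencyTable, cols: np.ndarray, assign: np.ndarray,
                  K: int, capped: bool = False) -> ReducedModel:
    """Build the full-alphabet model from an assignment over the nonzero
    columns ``cols``.  Zero-mass columns are affiliated with state 0; they
    carry no observed transitions, so the choice does not affect S."""
    n = C.n
    Csub = C.C[:, cols]
    lamb = _emission_for(Csub, assign, K)
    gamma = np.zeros((K, n))
    full_assign = np.zeros(n, dtype=np.int64)
    full_assign[cols] = assign
    gamma[full_assign, np.arange(n)] = 1.0
    model = ReducedModel(K=K, gamma=gamma, lamb=lamb,
                         S=_partition_entropy(Csub, assign, K),
                         V=parameter_count(n, K), capped=capped)
    return model


def fit_reduced_model(C: ContingencyTable, K: int, seed: int = 0) -> ReducedModel:
    """Heuristic DBMR fit: minimize S_K over hard K-state affiliations.

    Runs alternating reassignment sweeps from 10 starts — one contiguous
    partition of the ordered categories (they are ordered intensity bins)
    plus 9 random assignments drawn from ``default_rng(seed)`` — and keeps
    the best.  If ``K`` exceeds the number of categories that occur as
    initial states, the largest feasible model is returned with
    ``capped=True``.
    """
    n = C.n
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in [1, {n}], got {K}")
    colmass = C.C.sum(axis=0)
    cols = np.flatnonzero(colmass > 0)
    m = cols.size
    if m == 0:
        raise ValueError("contingency table has no observed initial states")
    if K > m:
        model = fit_reduced_model(C, m, seed=seed)
        model.capped = True
        return model
    Csub = C.C[:, cols]
    if K == 1:
        return _expand_model(C, cols, np.zeros(m, dtype=np.int64), 1)
    if K == m:
        return _expand_model(C, cols, np.arange(m, dtype=np.int64), K)

    inits = []
    blocks = np.array_split(np.arange(m), K)
    contiguous = np.empty(m, dtype=np.int64)
    for k, b in enumerate(blocks):
        contiguous[b] = k
    inits.append(contiguous)
    rng = np.random.default_rng(seed)
    for _ in range(9):
        a = np.empty(m, dtype=np.int64)
        perm = rng.permutation(m)
        a[perm[:K]] = np.arange(K)  # guarantee every state is hit
        a[perm[K:]] = rng.integers(0, K, size=m - K)
        inits.append(a)

    best_assign, best_S = None, np.inf
    for a0 in inits:
        a, S = _sweep_fit(Csub, a0, K)
        if S < best_S - 1e-15:
            best_assign, best_S = a, S
    return _expand_model(C, cols, best_assign, K)


def exhaustive_reduced_model(C: ContingencyTable, K: int) -> ReducedModel:
    """Globally optimal hard DBMR by enumerating all set partitions of the
    observed categories into K nonempty blocks.  Exponential cost; guarded
    to n <= 10 and intended as the validation oracle for
    :func:`fit_reduced_model`."""
    from sympy.utilities.iterables import multiset_partitions

    n = C.n
    if n > 10:
        raise ValueError(
            "exhaustive enumeration is limited to n <= 10; use fit_reduced_model"
        )
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in [1, {n}], got {K}")
    colmass = C.C.sum(axis=0)
    cols = np.flatnonzero(colmass > 0)
    m = cols.size
    if K > m:
        model = exhaustive_reduced_model(C, m)
        model.capped = True
        return model
    Csub = C.C[:, cols]
    best_assign, best_S = None, np.inf
    for blocks in multiset_partitions(list(range(m)), K):
        assign = np.empty(m, dtype=np.int64)
        for k, block in enumerate(blocks):
            assign[block] = k
        S = _partition_entropy(Csub, assign, K)
        if S < best_S - 1e-15:
            best_assign, best_S = assign, S
    return _expand_model(C, cols, best_assign, K)


def compose_transition(model: ReducedModel) -> TransitionMatrix:
    """The reduced transition law ``Lambda_K = lamb_K @ gamma_K``."""
    return TransitionMatrix(Lambda=model.lamb @ model.gamma)
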