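"""Categorical encoding of scalar time series.

Every measure in this package consumes pairs of consecutive categorical
observations.  A pixel's intensity trace is first discretized into ``n``
categories (the discretized color scale), then turned into ``(initial,
final)`` transition pairs, and finally summarized by the average
contingency table ``C`` with entries

    C[j, i] = (# pairs with initial category i and final category j) / N,

where ``N`` is the number of observed transition pairs.  ``C`` sums to 1
and is the sufficient statistic for all downstream model fits.

Category indices are 1-based throughout the public API (category ``1`` is
the lowest intensity bin); matrices are 0-based numpy arrays with row =
final category, column = initial category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoryAlphabet",
    "PairSample",
    "ContingencyTable",
    "DegenerateTraceWarning",
    "discretize_series",
    "pairs_from_series",
    "contingency",
    "check_sample_size",
]


class DegenerateTraceWarning(UserWarning):
    """A constant trace was collapsed to a single-category alphabet."""


@dataclass(frozen=True)
class CategoryAlphabet:
    """An ordered set of ``n`` categories, optionally backed by intensity bins.

    Parameters
    ----------
    n:
        Number of categories, ``n >= 1``.
    labels:
        Ordered, distinct identifiers (bin indices or raw integer levels).
    bin_edges:
        Optional ``n + 1`` strictly increasing intensity thresholds, in the
        units of the input image.  The final interval is right-closed, so a
        value exactly at the upper edge falls in the last bin.
    degenerate:
        True when the alphabet was collapsed to ``n = 1`` because the trace
        it was derived from had no dynamic range.
    """

    n: int
    labels: tuple = ()
    bin_edges: np.ndarray | None = None
    degenerate: bool = False

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"alphabet needs n >= 1, got {self.n}")
        labels = tuple(self.labels) if self.labels else tuple(range(1, self.n + 1))
        object.__setattr__(self, "labels", labels)
        if len(labels) != self.n or len(set(labels)) != self.n:
            raise ValueError("labels must be n distinct identifiers")
        if self.bin_edges is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            if edges.shape != (self.n + 1,):
                raise ValueError("bin_edges must have length n + 1")
            if not np.all(np.diff(edges) > 0):
                raise ValueError("bin_edges must be strictly increasing")
            object.__setattr__(self, "bin_edges", edges)


@dataclass(frozen=True)
class PairSample:
    """A set of (initial, final) category index pairs over one alphabet.

    ``pairs`` is an ``(N, 2)`` integer array with 1-based category indices;
    column 0 holds the initial category, column 1 the final one.  The pairs
    need not come from a single chain — independent repeated experiments
    are equally valid input.
    """

    pairs: np.ndarray
    alphabet: CategoryAlphabet

    def __post_init__(self):
        pairs = np.asarray(self.pairs, dtype=np.int64)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
            raise ValueError("pairs must be a nonempty (N, 2) array")
        n = self.alphabet.n
        if pairs.min() < 1 or pairs.max() > n:
            raise ValueError(f"pair indices must lie in [1, {n}]")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class ContingencyTable:
    """Average joint-frequency matrix of (final, initial) category pairs.

    ``C[j, i]`` is the relative frequency of the transition ``i -> j``;
    entries are nonnegative and sum to 1.
    """

    C: np.ndarray
    n_pairs: int

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if C.min() < 0:
            raise ValueError("C entries must be nonnegative")
        if abs(C.sum() - 1.0) > 1e-12:
            raise ValueError("C entries must sum to 1")
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        return self.C.shape[0]


def discretize_series(values, n_bins: int = 8, edges=None):
    """Map a scalar trace to 1-based category indices.

    With ``edges=None`` the bins are uniform-width between the minimum and
    maximum of ``values``.  If the values are already integers taking at
    most ``n_bins`` distinct levels, the distinct levels themselves are
    used as categories (no re-binning, so no empty bins).  An explicit
    ``edges`` array (length ``n + 1``) overrides both rules, which is how a
    whole image stack shares one alphabet.

    Returns ``(alphabet, categories)`` with ``categories`` an int array the
    same length as ``values``.  A constant trace with ``n_bins > 1`` is
    collapsed to a single-category alphabet and flagged with a
    :class:`DegenerateTraceWarning` rather than raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        n = edges.size - 1
        alphabet = CategoryAlphabet(n=n, bin_edges=edges)
        cats = np.digitize(values, edges[1:-1]) + 1
        return alphabet, cats.astype(np.int64)
    if n_bins < 1:
        raise ValueError("n_bins must be positive")

    # integer-valued trace with few levels: the levels are the categories
    if np.all(values == np.round(values)):
        levels = np.unique(values)
        if levels.size <= n_bins:
            alphabet = CategoryAlphabet(
                n=levels.size, labels=tuple(int(v) for v in levels)
            )
            cats = np.searchsorted(levels, values) + 1
            return alphabet, cats.astype(np.int64)

    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        if n_bins > 1:
            warnings.warn(
                "constant trace collapsed to a single category",
                DegenerateTraceWarning,
                stacklevel=2,
            )
        alphabet = CategoryAlphabet(n=1, degenerate=n_bins > 1)
        return alphabet, np.ones(values.shape, dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)
    alphabet = CategoryAlphabet(n=n_bins, bin_edges=edges)
    cats = np.digitize(values, edges[1:-1]) + 1
    return alphabet, cats.astype(np.int64)


def pairs_from_series(categories, alphabet: CategoryAlphabet) -> PairSample:
    """Consecutive (X(t), X(t+1)) pairs of a categorical sequence.

    A sequence of ``T`` frames yields ``N = T - 1`` transition pairs, in
    temporal order.
    """
    cats = np.asarray(categories, dtype=np.int64)
    if cats.ndim != 1 or cats.size < 2:
        raise ValueError("need at least two time points to form transition pairs")
    pairs = np.column_stack([cats[:-1], cats[1:]])
    return PairSample(pairs=pairs, alphabet=alphabet)


def contingency(sample: PairSample) -> ContingencyTable:
    """Average contingency table ``C[j, i] = #(i -> j) / N`` of a sample."""
    n = sample.alphabet.n
    i = sample.pairs[:, 0] - 1
    j = sample.pairs[:, 1] - 1
    counts = np.bincount(j * n + i, minlength=n * n).reshape(n, n)
    return ContingencyTable(C=counts / sample.n_pairs, n_pairs=sample.n_pairs)


def check_sample_size(sample: PairSample) -> bool:
    """True when the pair count exceeds n², the accuracy condition for the
    contingency-table estimate.  A False result is a warning, not an error:
    all computations still proceed."""
    return sample.n_pairs > sample.alphabet.n ** 2
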