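"""Partition-agreement metrics: ARI, NMI, and minimum Hamming distance.

All metrics accept integer label vectors of equal length; labels need not
be contiguous, and the two partitions may use different numbers of
clusters.  The adjusted Rand index and normalized mutual information are
computed from the contingency table ``n_{k,k'}`` (the number of
observations placed in cluster k of the first partition and cluster k'
of the second); the Hamming mis-clustering rate minimizes the mismatch
fraction over all cluster-label permutations.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import linear_sum_assignment

__all__ = ["ari", "nmi", "hamming_misclustering", "contingency"]


def _as_labels(a: ArrayLike, b: ArrayLike) -> tuple[NDArray[np.int_], NDArray[np.int_]]:
    a = np.asarray(a, dtype=int).ravel()
    b = np.asarray(b, dtype=int).ravel()
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    if a.size == 0:
        raise ValueError("partitions must be non-empty")
    return a, b


def contingency(a: ArrayLike, b: ArrayLike) -> NDArray[np.int_]:
    """Contingency table n_{k,k'} between two label vectors."""
    a, b = _as_labels(a, b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=int)
    np.add.at(table, (ai, bi), 1)
    return table


def _choose2(x: NDArray) -> NDArray:
    return x * (x - 1) / 2.0


def ari(a: ArrayLike, b: ArrayLike) -> float:
    """Adjusted Rand index between two partitions.

    ``(sum_kk' C(n_kk',2) - E) / ((sum_k C(n_k,2) + sum_k' C(n_k',2))/2 - E)``
    with ``E = sum_k C(n_k,2) sum_k' C(n_k',2) / C(n,2)``; equals 1 for
    identical partitions (up to relabeling) and is near 0 for independent
    ones.
    """
    table = contingency(a, b)
    n = table.sum()
    sum_cells = _choose2(table).sum()
    sum_rows = _choose2(table.sum(axis=1)).sum()
    sum_cols = _choose2(table.sum(axis=0)).sum()
    total = _choose2(np.array(n))
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial (all-one-cluster or all-singletons)
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def nmi(a: ArrayLike, b: ArrayLike, average: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions.

    ``MI(a,b)`` divided by the arithmetic mean (default) or geometric mean
    of the two partition entropies, with ``0 log 0 = 0``.  Identical
    partitions give 1.  If either partition has a single cluster its
    entropy is zero and the index is degenerate: 1 is returned when the
    partitions are identical, otherwise a ValueError is raised.
    """
    if average not in ("arithmetic", "geometric"):
        raise ValueError("average must be 'arithmetic' or 'geometric'")
    table = contingency(a, b).astype(float)
    n = table.sum()
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pi, pj)[nz]))))
    h_a = -float(np.sum(pi * np.log(pi, where=pi > 0, out=np.zeros_like(pi))))
    h_b = -float(np.sum(pj * np.log(pj, where=pj > 0, out=np.zeros_like(pj))))
    if h_a == 0.0 or h_b == 0.0:
        if table.shape == (1, 1) or np.array_equal(
            np.unique(a, return_inverse=True)[1], np.unique(b, return_inverse=True)[1]
        ):
            return 1.0
        raise ValueError("NMI degenerate: a single-cluster partition differs from the other")
    denom = 0.5 * (h_a + h_b) if average == "arithmetic" else float(np.sqrt(h_a * h_b))
    return float(mi / denom)


def hamming_misclustering(a: ArrayLike, b: ArrayLike) -> float:
    """Minimum Hamming mis-clustering rate between two partitions.

    ``(1/n) min_tau sum_i 1{a_i != tau(b_i)}`` over permutations tau of the
    cluster labels, computed as a maximum-agreement assignment on the
    contingency table (padded with empty clusters when the cluster counts
    differ).  Always in [0, 1]; 0 iff the partitions agree up to relabeling.
    """
    a, b = _as_labels(a, b)
    table = contingency(a, b)
    m = max(table.shape)
    padded = np.zeros((m, m), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    agreement = padded[rows, cols].sum()
    return float((a.size - agreement) / a.size)
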