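"""Constrained maximum likelihood estimation for the sparse mixture.

The estimator minimizes ``||Y - mu L^T||_F^2`` over p x K center matrices
``mu`` with at most s nonzero rows (joint sparsity) and over allocation
matrices L.  The problem is nonconvex and combinatorial; this module
provides a certified-exhaustive solver for tiny instances (the oracle)
and a Lloyd-style alternating heuristic with random restarts for
practical use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "MleResult",
    "optimal_mu_given_z",
    "constrained_mle_exhaustive",
    "constrained_mle_alternating",
]

_MAX_EXHAUSTIVE = 10**6


@dataclass
class MleResult:
    """A jointly s-sparse center estimate, labels (1-based), and SSE objective."""

    mu_hat: NDArray[np.float64]
    z_hat: NDArray[np.int_]
    objective: float


def optimal_mu_given_z(
    Y: ArrayLike, z: ArrayLike, K: int, s: int
) -> tuple[NDArray[np.float64], float]:
    """Best jointly s-sparse center matrix for fixed labels.

    The unconstrained optimum is the matrix of cluster means; imposing
    joint s-sparsity amounts to keeping the s rows with the largest exact
    SSE reduction ``sum_k n_k mu_kj^2`` and zeroing the rest (ties broken
    by the smaller row index).  Empty clusters get zero columns.  Returns
    ``(mu, ||Y - mu L^T||_F^2)``.
    """
    Y = np.asarray(Y, dtype=float)
    z = np.asarray(z, dtype=int)
    p, n = Y.shape
    if z.shape != (n,):
        raise ValueError("z must have one label per observation")
    if z.size and (z.min() < 1 or z.max() > K):
        raise ValueError(f"labels must lie in {{1..{K}}}")
    if s > p:
        raise ValueError("s may not exceed p")
    counts = np.bincount(z - 1, minlength=K).astype(float)
    sums = np.zeros((p, K))
    np.add.at(sums.T, z - 1, Y.T)
    mu = np.divide(sums, counts, out=np.zeros((p, K)), where=counts > 0)
    if s < p:
        scores = np.sum(counts * mu**2, axis=1)
        # stable sort on -score keeps the smaller index first among ties
        keep = np.sort(np.argsort(-scores, kind="stable")[:s])
        sparse_mu = np.zeros_like(mu)
        sparse_mu[keep] = mu[keep]
        mu = sparse_mu
    resid = Y - mu[:, z - 1]
    return mu, float(np.sum(resid * resid))


def _canonical_labelings(n: int, K: int):
    """Yield label vectors in first-occurrence canonical order with <= K blocks.

    Restricted-growth strings: z_1 = 1 and z_i <= max(z_1..z_{i-1}) + 1,
    removing the K!-fold relabeling redundancy of plain enumeration.
    """
    z = np.ones(n, dtype=int)

    def rec(i: int, mx: int):
        if i == n:
            yield z.copy()
            return
        for lab in range(1, min(mx + 1, K) + 1):
            z[i] = lab
            yield from rec(i + 1, max(mx, lab))

    yield from rec(1, 1) if n > 1 else iter([z.copy()])


def constrained_mle_exhaustive(Y: ArrayLike, K: int, s: int) -> MleResult:
    """Globally optimal constrained MLE by exhaustive label enumeration.

    Guarded to instances with K^n <= 1e6; intended as a correctness oracle
    for the heuristic solver, not for real data.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[1]
    if K**n > _MAX_EXHAUSTIVE:
        raise ValueError(f"instance too large for exhaustive search (K^n = {K**n:g})")
    best: MleResult | None = None
    for z in _canonical_labelings(n, K):
        mu, obj = optimal_mu_given_z(Y, z, K, s)
        if best is None or obj < best.objective:
            best = MleResult(mu_hat=mu, z_hat=z, objective=obj)
    assert best is not None
    return best


def _local_search_z(
    Y: NDArray[np.float64], z: NDArray[np.int_], K: int, s: int, obj: float
) -> tuple[NDArray[np.int_], float]:
    """First-improvement single-label moves until 1-opt in z.

    Joint sparsity couples the support choice to the labels, so Lloyd
    iterations can stall one relabeling short of the optimum; this pass
    closes those gaps.
    """
    n = Y.shape[1]
    improved = True
    while improved:
        improved = False
        for i in range(n):
            for k in range(1, K + 1):
                if k == z[i]:
                    continue
                z_try = z.copy()
                z_try[i] = k
                _, obj_try = optimal_mu_given_z(Y, z_try, K, s)
                if obj_try < obj - 1e-12:
                    z, obj = z_try, obj_try
                    improved = True
    return z, obj


def constrained_mle_alternating(
    Y: ArrayLike,
    K: int,
    s: int,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> MleResult:
    """Alternating (Lloyd-style) heuristic for the constrained MLE.

    Each restart initializes centers from K distinct random observations,
    then alternates nearest-sparse-center assignment with
    :func:`optimal_mu_given_z` until the objective change drops below
    ``tol`` or ``max_iter`` iterations.  The best of ``n_starts`` seeded
    restarts is refined by first-improvement single-label moves (1-opt in
    z) before being returned; the objective is non-increasing within a
    restart and through the refinement.
    """
    Y = np.asarray(Y, dtype=float)
    p, n = Y.shape
    if K > n:
        raise ValueError("K may not exceed n")
    rng = np.random.default_rng(seed)
    best: MleResult | None = None
    for _ in range(n_starts):
        idx = rng.choice(n, size=K, replace=False)
        mu = Y[:, idx].copy()
        if s < p:  # sparsify the seed centers the same way as the update step
            scores = np.sum(mu**2, axis=1)
            keep = np.sort(np.argsort(-scores, kind="stable")[:s])
            sp = np.zeros_like(mu)
            sp[keep] = mu[keep]
            mu = sp
        prev = np.inf
        z = None
        for _ in range(max_iter):
            d2 = (
                np.sum(Y**2, axis=0)[:, None]
                - 2.0 * Y.T @ mu
                + np.sum(mu**2, axis=0)[None, :]
            )
            z = np.argmin(d2, axis=1) + 1
            # reseed emptied clusters at the worst-fit observations so a
            # restart never silently degenerates to fewer than K centers
            counts = np.bincount(z - 1, minlength=K)
            if np.any(counts == 0):
                fit = d2[np.arange(n), z - 1].copy()
                for k in np.flatnonzero(counts == 0):
                    i = int(np.argmax(fit))
                    z[i] = k + 1
                    fit[i] = -np.inf
            mu, obj = optimal_mu_given_z(Y, z, K, s)
            if prev - obj < tol:
                prev = obj
                break
            prev = obj
        assert z is not None
        result = MleResult(mu_hat=mu, z_hat=z, objective=float(prev))
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    z, obj = _local_search_z(Y, best.z_hat, K, s, best.objective)
    mu, obj = optimal_mu_given_z(Y, z, K, s)
    return MleResult(mu_hat=mu, z_hat=z, objective=obj)
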