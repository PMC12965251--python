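"""Generative model, priors, and log-density computations.

The model is a signal-plus-noise Gaussian mixture: each observation
``Y_i = mu_{z_i} + eps_i`` with ``eps_i ~ N_p(0, I_p)``.  The identity
working covariance is deliberate — the mean matrix ``mu L^T`` is the
estimand, and the posterior concentrates on it even when the true noise
covariance is merely spectrum-bounded.  Sparsity of the p x K center
matrix is row-wise and shared across clusters ("joint sparsity"): a
Bernoulli indicator ``xi_j`` gates feature j between a concentrated
Laplace "spike" (rate lambda0) and a diffuse Laplace "slab" (rate
lambda1), with inclusion probability ``theta ~ Beta(1, beta_theta)``.
Cluster labels are categorical with Dirichlet-distributed weights, and
the number of clusters K carries a truncated Poisson prior.

Labels are 1-based everywhere in the public API (``z_i`` in ``{1..K}``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import gammaln, logsumexp

LOG_2PI = math.log(2.0 * math.pi)

__all__ = [
    "DataMatrix",
    "ClusterParams",
    "Allocation",
    "Hyperparams",
    "log_likelihood",
    "laplace_log_density",
    "joint_ssl_log_prior",
    "log_prior_K",
    "log_joint",
]


@dataclass
class DataMatrix:
    """A p x n real data matrix: rows are features, columns are observations."""

    values: NDArray[np.float64]
    feature_names: list[str] | None = None
    observation_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix requires a 2-D array (features x observations)")
        if self.values.size == 0:
            raise ValueError("DataMatrix must have p >= 1 and n >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DataMatrix contains missing or non-finite entries")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusterParams:
    """Cluster centers with their shared sparsity structure.

    ``mu`` is p x K (column k is the center of cluster k), ``xi`` the binary
    row-inclusion indicator of length p, and ``theta`` the prior inclusion
    probability, strictly inside (0, 1).
    """

    mu: NDArray[np.float64]
    xi: NDArray[np.int_]
    theta: float

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.xi = np.asarray(self.xi, dtype=int)
        if self.mu.shape[1] < 1:
            raise ValueError("mu must have K >= 1 columns")
        if self.xi.shape != (self.mu.shape[0],):
            raise ValueError("xi must have length p = mu.shape[0]")
        if not np.all(np.isin(self.xi, (0, 1))):
            raise ValueError("xi entries must be 0 or 1")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie strictly inside (0, 1)")

    @property
    def K(self) -> int:
        return self.mu.shape[1]


@dataclass
class Allocation:
    """Cluster labels z (1-based), mixture weights w, and cluster count K."""

    z: NDArray[np.int_]
    w: NDArray[np.float64]
    K: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=int)
        self.w = np.asarray(self.w, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.w.shape != (self.K,):
            raise ValueError("w must have length K")
        if abs(float(self.w.sum()) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 (tolerance 1e-12)")
        if self.z.size and (self.z.min() < 1 or self.z.max() > self.K):
            raise ValueError("labels must lie in {1..K}")


def _default_beta_theta(p: int, kappa: float) -> float:
    # p^(1+kappa) * log p; for p=1 the log vanishes, floor at 1 keeps Beta proper
    return max(p ** (1.0 + kappa) * math.log(max(p, 2)), 1.0)


@dataclass
class Hyperparams:
    """Hyperparameters of the sparse mixture prior.

    lambda0 / lambda1 are the spike / slab Laplace rates (lambda0 > lambda1),
    kappa controls the default ``beta_theta = p^(1+kappa) * log p`` of the
    Beta(1, beta_theta) prior on the inclusion probability, alpha is the
    symmetric Dirichlet shape on the weights, lambda_pois the truncated
    Poisson rate on K, and Kmax the conservative cap on K.
    """

    lambda0: float = 100.0
    lambda1: float = 1.0
    kappa: float = 0.1
    beta_theta: float | None = None
    alpha: float = 1.0
    lambda_pois: float = 2.0
    Kmax: int = 20

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.lambda1 <= 0:
            raise ValueError("Laplace rates must be positive")
        if self.lambda0 <= self.lambda1:
            raise ValueError("spike rate lambda0 must exceed slab rate lambda1")
        if self.alpha < 1:
            raise ValueError("Dirichlet shape alpha must be >= 1")
        if self.lambda_pois <= 0:
            raise ValueError("lambda_pois must be positive")
        if self.Kmax < 1:
            raise ValueError("Kmax must be >= 1")
        if self.beta_theta is not None and self.beta_theta <= 0:
            raise ValueError("beta_theta must be positive")

    def beta_theta_for(self, p: int) -> float:
        """Effective Beta-prior scale for a p-feature problem."""
        if self.beta_theta is not None:
            return float(self.beta_theta)
        return _default_beta_theta(p, self.kappa)


def log_likelihood(Y: DataMatrix | ArrayLike, mu: ArrayLike, z: ArrayLike) -> float:
    """Gaussian working log-likelihood with identity covariance.

    Returns ``-np/2 log(2 pi) - (1/2) sum_i ||Y_i - mu_{z_i}||^2`` where
    ``z`` holds 1-based labels into the columns of ``mu``.
    """
    values = Y.values if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    z = np.asarray(z, dtype=int)
    p, n = values.shape
    K = mu.shape[1]
    if z.shape != (n,):
        raise ValueError("z must have one label per observation")
    if z.size and (z.min() < 1 or z.max() > K):
        raise ValueError(f"labels must lie in {{1..{K}}}")
    resid = values - mu[:, z - 1]
    return -0.5 * n * p * LOG_2PI - 0.5 * float(np.sum(resid * resid))


def laplace_log_density(x: ArrayLike, lam: float) -> float | NDArray[np.float64]:
    """Log density of the Laplace(0, rate lam) distribution: log(lam/2) - lam|x|."""
    if lam <= 0:
        raise ValueError("Laplace rate must be positive")
    out = math.log(lam / 2.0) - lam * np.abs(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def joint_ssl_log_prior(mu: ArrayLike, xi: ArrayLike, hp: Hyperparams) -> float:
    """Log density of the center matrix under the joint SSL prior, given xi.

    Conditionally on the shared indicator, row j of mu is i.i.d. Laplace
    across the K clusters with rate lambda1 if xi_j = 1 (slab) and lambda0
    otherwise (spike).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    xi = np.asarray(xi, dtype=int)
    if xi.shape != (mu.shape[0],):
        raise ValueError("xi must have length p = mu.shape[0]")
    lam = np.where(xi == 1, hp.lambda1, hp.lambda0)[:, None]
    return float(np.sum(np.log(lam / 2.0) - lam * np.abs(mu)))


def log_prior_K(K: int, hp: Hyperparams) -> float:
    """Log pmf of the truncated Poisson prior on K, normalized over {1..Kmax}."""
    if not (1 <= K <= hp.Kmax):
        raise ValueError(f"K must lie in {{1..{hp.Kmax}}}")
    ks = np.arange(1, hp.Kmax + 1)
    logs = ks * math.log(hp.lambda_pois) - gammaln(ks + 1)
    return float(logs[K - 1] - logsumexp(logs))


def _log_beta_pdf(theta: float, a: float, b: float) -> float:
    return float(
        (a - 1.0) * math.log(theta)
        + (b - 1.0) * math.log1p(-theta)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
    )


def _log_dirichlet_pdf(w: NDArray[np.float64], alpha: float) -> float:
    K = w.shape[0]
    # at alpha=1 the density is the constant (K-1)!; avoid 0*log(0) on boundary w
    shape_term = 0.0 if alpha == 1.0 else (alpha - 1.0) * float(np.sum(np.log(w)))
    return float(shape_term + gammaln(K * alpha) - K * gammaln(alpha))


def log_joint(
    Y: DataMatrix | ArrayLike,
    params: ClusterParams,
    alloc: Allocation,
    hp: Hyperparams,
) -> float:
    """Log joint density of data and all latent quantities.

    Sums the Gaussian working likelihood, the joint SSL prior on mu given
    xi, the Bernoulli(theta) prior on xi, the Beta(1, beta_theta) prior on
    theta, the categorical prior on z given w, the symmetric Dirichlet(alpha)
    prior on w, and the truncated Poisson prior on K.
    """
    values = Y.values if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    p = values.shape[0]
    if params.K != alloc.K:
        raise ValueError("params and alloc disagree on K")
    bt = hp.beta_theta_for(p)
    n_xi = int(params.xi.sum())
    total = log_likelihood(values, params.mu, alloc.z)
    total += joint_ssl_log_prior(params.mu, params.xi, hp)
    total += n_xi * math.log(params.theta) + (p - n_xi) * math.log1p(-params.theta)
    total += _log_beta_pdf(params.theta, 1.0, bt)
    if alloc.z.size:
        total += float(np.sum(np.log(alloc.w[alloc.z - 1])))
    total += _log_dirichlet_pdf(alloc.w, hp.alpha)
    total += log_prior_K(alloc.K, hp)
    return total
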