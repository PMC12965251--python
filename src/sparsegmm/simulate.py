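"""Synthetic-data generators for sparse Gaussian (and Student-t) mixtures.

Three named scenarios reproduce a standard benchmark design at p=400
features and n=200 observations, with the sparse support fixed to the
first s coordinates:

* Scenario I — homoscedastic identity-covariance Gaussian mixtures with
  K* in {3, 5} clusters and support size s in {6, 12}.
* Scenario II — K*=3 with one very small cluster (weight 0.02) and a
  heteroscedastic diagonal covariance (variance 4 on the support in
  cluster 2).
* Scenario III — the Scenario II centers and covariances, but the noise
  is multivariate Student-t with 5 degrees of freedom (same per-cluster
  covariance as Scenario II), probing robustness of the Gaussian working
  likelihood to heavy tails.

All generators are fully seeded and return 1-based true labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "SimulationConfig",
    "sample_mixture",
    "scenario1",
    "scenario2",
    "scenario3",
    "min_separation",
]


@dataclass
class SimulationConfig:
    """Fully parameterized mixture specification.

    ``support_means`` is an s x K matrix giving the cluster centers on the
    support rows ``support`` (0-based feature indices); all other rows of
    the p x K center matrix are zero.  ``cov_diags`` holds one length-p
    covariance diagonal per cluster; None means identity.  ``noise`` is
    ``"gaussian"`` or ``"student_t"`` with ``df`` degrees of freedom; for
    Student-t noise ``t_matrix`` controls whether ``cov_diags`` specify
    the true covariance (default; the scale matrix is then
    ``(df-2)/df * cov``, requiring df > 2) or the scale matrix directly.
    """

    p: int
    n: int
    K_true: int
    support: NDArray[np.int_]
    support_means: NDArray[np.float64]
    weights: NDArray[np.float64]
    cov_diags: NDArray[np.float64] | None = None
    noise: str = "gaussian"
    df: float = 5.0
    t_matrix: str = "covariance"
    seed: int = 0

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.support_means = np.atleast_2d(np.asarray(self.support_means, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if self.weights.shape != (self.K_true,) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a length-K_true vector summing to 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.support_means.shape != (self.s, self.K_true):
            raise ValueError("support_means must be s x K_true")
        if len(np.unique(self.support)) != self.s or self.support.max(initial=-1) >= self.p:
            raise ValueError("support must hold s distinct indices in [0, p)")
        if self.noise not in ("gaussian", "student_t"):
            raise ValueError("noise must be 'gaussian' or 'student_t'")
        if self.t_matrix not in ("covariance", "scale"):
            raise ValueError("t_matrix must be 'covariance' or 'scale'")
        if self.noise == "student_t" and self.t_matrix == "covariance" and self.df <= 2:
            raise ValueError("the covariance of a t distribution requires df > 2")
        if self.cov_diags is not None:
            self.cov_diags = np.asarray(self.cov_diags, dtype=float)
            if self.cov_diags.shape != (self.K_true, self.p):
                raise ValueError("cov_diags must be K_true x p")
            if np.any(self.cov_diags < 0):
                raise ValueError("variances must be nonnegative")

    @property
    def s(self) -> int:
        return int(self.support.shape[0])

    def mu_true(self) -> NDArray[np.float64]:
        """The full p x K_true center matrix (zero off the support)."""
        mu = np.zeros((self.p, self.K_true))
        mu[self.support, :] = self.support_means
        return mu

    def min_separation(self) -> float:
        """Diagnostic: minimum pairwise distance among the true centers."""
        return min_separation(self.mu_true())


def sample_mixture(
    cfg: SimulationConfig,
) -> tuple[NDArray[np.float64], NDArray[np.int_], NDArray[np.float64]]:
    """Draw (Y, z_true, mu_true) from the configured mixture.

    Labels are i.i.d. categorical with the configured weights; Gaussian
    noise is ``Sigma_k^(1/2) eps`` with diagonal Sigma_k, and Student-t
    noise divides a Gaussian draw by ``sqrt(g/df)`` with ``g ~ chi2_df``
    per observation.  Under the default ``t_matrix="covariance"`` the
    Gaussian draw uses scale ``(df-2)/df * Sigma_k`` so that the t noise
    has covariance exactly Sigma_k.
    """
    rng = np.random.default_rng(cfg.seed)
    mu = cfg.mu_true()
    z = rng.choice(cfg.K_true, size=cfg.n, p=cfg.weights) + 1
    eps = rng.standard_normal((cfg.p, cfg.n))
    diags = cfg.cov_diags
    if cfg.noise == "student_t" and cfg.t_matrix == "covariance":
        factor = (cfg.df - 2.0) / cfg.df
        diags = factor * (diags if diags is not None else np.ones((cfg.K_true, cfg.p)))
    if diags is not None:
        eps *= np.sqrt(diags[z - 1].T)
    if cfg.noise == "student_t":
        g = rng.chisquare(cfg.df, size=cfg.n)
        eps /= np.sqrt(g / cfg.df)
    Y = mu[:, z - 1] + eps
    return Y, z, mu


def _scenario1_config(K_true: int, s: int, seed: int) -> SimulationConfig:
    if K_true not in (3, 5) or s not in (6, 12):
        raise ValueError("Scenario I requires K_true in {3,5} and s in {6,12}")
    ones = np.ones(s)
    alt = np.array([(-1.0) ** (j + 1) for j in range(s)])  # (-1, 1, -1, 1, ...)
    if K_true == 3:
        centers = np.column_stack([3.0 * ones, -1.5 * ones, np.zeros(s)])
        weights = np.array([0.3, 0.3, 0.4])
    else:
        centers = np.column_stack(
            [4.0 * ones, -4.0 * ones, np.zeros(s), 4.0 * alt, 1.5 * -alt]
        )
        weights = np.full(5, 0.2)
    return SimulationConfig(
        p=400,
        n=200,
        K_true=K_true,
        support=np.arange(s),
        support_means=centers,
        weights=weights,
        seed=seed,
    )


def scenario1(
    K_true: int, s: int, seed: int = 0
) -> tuple[NDArray[np.float64], NDArray[np.int_], NDArray[np.float64]]:
    """Scenario I: identity-covariance Gaussian mixture, p=400, n=200.

    For K*=3 the support centers are 3*1, -1.5*1 and 0 with weights
    (0.3, 0.3, 0.4); for K*=5 they are 4*1, -4*1, 0, 4*(-1,1,...) and
    1.5*(1,-1,...) with uniform weights.
    """
    return sample_mixture(_scenario1_config(K_true, s, seed))


def _scenario23_config(seed: int, student_t: bool) -> SimulationConfig:
    s = 8
    pair1 = np.tile([5.0, 2.0], s // 2)
    pair2 = np.tile([10.0, 5.0], s // 2)
    pair3 = np.tile([15.0, 2.0], s // 2)
    centers = np.column_stack([pair1, pair2, pair3])
    p = 400
    cov = np.ones((3, p))
    cov[1, :s] = 4.0  # cluster 2 inflated on the support
    return SimulationConfig(
        p=p,
        n=200,
        K_true=3,
        support=np.arange(s),
        support_means=centers,
        weights=np.array([0.2, 0.4, 0.4]) if student_t else np.array([0.02, 0.48, 0.5]),
        cov_diags=cov,
        noise="student_t" if student_t else "gaussian",
        df=5.0,
        seed=seed,
    )


def scenario2(
    seed: int = 0,
) -> tuple[NDArray[np.float64], NDArray[np.int_], NDArray[np.float64]]:
    """Scenario II: K*=3, s=8, a 2%-weight small cluster, heteroscedastic noise."""
    return sample_mixture(_scenario23_config(seed, student_t=False))


def scenario3(
    seed: int = 0,
) -> tuple[NDArray[np.float64], NDArray[np.int_], NDArray[np.float64]]:
    """Scenario III: Scenario II centers/scales with Student-t(5) noise."""
    return sample_mixture(_scenario23_config(seed, student_t=True))


def min_separation(mu: NDArray[np.float64]) -> float:
    """Minimum pairwise Euclidean distance among the columns of mu (K >= 2)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    K = mu.shape[1]
    if K < 2:
        raise ValueError("min_separation requires at least two centers")
    d2 = np.sum(mu**2, axis=0)
    gram = mu.T @ mu
    pair = d2[:, None] + d2[None, :] - 2.0 * gram
    iu = np.triu_indices(K, k=1)
    return float(np.sqrt(max(pair[iu].min(), 0.0)))
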