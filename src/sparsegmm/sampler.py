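"""Trans-dimensional Gibbs sampler for the sparse Bayesian mixture.

Each sweep is a systematic scan over the full conditionals of the
weights (conjugate Dirichlet), the labels (categorical), the centers
(exact two-piece-normal draws under the Laplace spike/slab penalty), the
sparsity indicators and inclusion probability (Bernoulli / conjugate
Beta), followed by Metropolis-Hastings birth/death moves on *empty*
mixture components that let the number of clusters K change.  Births
draw the new center column from the spike-and-slab prior (which cancels
in the acceptance ratio) and a new weight from a Beta proposal matched
to the Dirichlet posterior scale, so the acceptance probability reduces
to the exact posterior odds of an additional empty component.  Occupied
components never die; clusters empty out through the label updates.

Correctness of every conditional is validated by simulation-consistency
(joint-distribution / "getting it right") tests rather than by reference
pseudocode; see the test suite and docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import linear_sum_assignment
from scipy.special import expit, gammaln, log_ndtr, ndtri_exp

from .core_model import (
    Allocation,
    ClusterParams,
    DataMatrix,
    Hyperparams,
    log_joint,
    log_prior_K,
)

__all__ = [
    "McmcConfig",
    "McmcTrace",
    "GmmState",
    "FitResult",
    "update_w",
    "update_z",
    "update_xi_theta",
    "sample_mu_entry",
    "update_mu",
    "update_K",
    "gibbs_sweep",
    "run_mcmc",
    "estimate_partition",
    "estimate_means",
    "fit",
    "sample_state_from_prior",
    "resample_data",
]


@dataclass
class McmcConfig:
    """Sampler run configuration.

    ``k_move_rate`` is the probability that each of the
    ``k_moves_per_sweep`` birth/death attempts actually fires in a sweep;
    two attempts per sweep keep trans-dimensional mixing brisk while the
    per-attempt acceptance is the (small) exact posterior odds of an
    empty extra component.
    """

    n_iter: int = 2500
    burn_in: int = 500
    seed: int = 0
    store_mu: bool = False
    k_move_rate: float = 1.0
    k_moves_per_sweep: int = 2
    init_K: int | None = None  # default: round(lambda_pois)
    kmeans_n_init: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if not (0.0 < self.k_move_rate <= 1.0):
            raise ValueError("k_move_rate must lie in (0, 1]")
        if self.k_moves_per_sweep < 0:
            raise ValueError("k_moves_per_sweep must be >= 0")


@dataclass
class GmmState:
    """Current sampler state: centers, sparsity, labels, weights, K."""

    mu: NDArray[np.float64]  # p x K
    xi: NDArray[np.int_]  # p
    theta: float
    z: NDArray[np.int_]  # n, 1-based (may be empty for prior-only chains)
    w: NDArray[np.float64]  # K

    @property
    def K(self) -> int:
        return self.mu.shape[1]

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def copy(self) -> "GmmState":
        return GmmState(self.mu.copy(), self.xi.copy(), self.theta, self.z.copy(), self.w.copy())


@dataclass
class McmcTrace:
    """Post-burn-in samples and trans-dimensional move diagnostics."""

    z: NDArray[np.int_]  # T x n
    K: NDArray[np.int_]  # T
    log_joint: NDArray[np.float64]  # T
    theta: NDArray[np.float64]  # T
    n_xi: NDArray[np.int_]  # T
    xi_mean: NDArray[np.float64]  # p, posterior mean of xi
    mu: list[NDArray[np.float64]] | None = None  # optional per-sample p x K_t
    births_proposed: int = 0
    births_accepted: int = 0
    deaths_proposed: int = 0
    deaths_accepted: int = 0

    def __len__(self) -> int:
        return int(self.K.shape[0])


@dataclass
class FitResult:
    """Point estimates extracted from a posterior sample."""

    z_hat: NDArray[np.int_]
    K_hat: int
    mu_hat: NDArray[np.float64] | None
    xi_mean: NDArray[np.float64]
    trace: McmcTrace


# ---------------------------------------------------------------------------
# full-conditional updates


def update_w(
    z: NDArray[np.int_], K: int, alpha: float, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Conjugate Dirichlet(alpha + n_1, ..., alpha + n_K) draw of the weights."""
    if K < 1:
        raise ValueError("K must be >= 1")
    counts = np.bincount(np.asarray(z, dtype=int) - 1, minlength=K)[:K]
    if K == 1:
        return np.ones(1)
    w = rng.dirichlet(alpha + counts)
    return w


def update_z(
    Y: NDArray[np.float64],
    mu: NDArray[np.float64],
    w: NDArray[np.float64],
    rng: np.random.Generator,
) -> NDArray[np.int_]:
    """Categorical label draw: P(z_i = k) proportional to w_k exp(-||Y_i - mu_k||^2 / 2).

    The per-observation squared norm of Y_i is constant across k and
    cancels; probabilities are formed in log space (Gumbel-max draw).
    """
    n = Y.shape[1]
    if n == 0:
        return np.zeros(0, dtype=int)
    with np.errstate(divide="ignore"):  # zero weights allowed: log w = -inf
        logp = np.log(w)[None, :] + Y.T @ mu - 0.5 * np.sum(mu * mu, axis=0)[None, :]
    gumbel = -np.log(-np.log(rng.random(logp.shape)))
    return np.argmax(logp + gumbel, axis=1) + 1


def update_xi_theta(
    mu: NDArray[np.float64],
    theta: float,
    hp: Hyperparams,
    rng: np.random.Generator,
) -> tuple[NDArray[np.int_], float]:
    """Draw the sparsity indicators and inclusion probability.

    ``xi_j ~ Bernoulli(q_j)`` with ``logit q_j = logit(theta) +
    sum_k [log psi(mu_kj | lambda1) - log psi(mu_kj | lambda0)]``, then
    ``theta ~ Beta(1 + sum xi, beta_theta + p - sum xi)`` by conjugacy.
    """
    p, K = mu.shape
    abs_row = np.sum(np.abs(mu), axis=1)
    log_odds = (
        math.log(theta) - math.log1p(-theta)
        + K * (math.log(hp.lambda1) - math.log(hp.lambda0))
        + (hp.lambda0 - hp.lambda1) * abs_row
    )
    q = expit(log_odds)
    xi = (rng.random(p) < q).astype(int)
    s_xi = int(xi.sum())
    theta_new = float(rng.beta(1.0 + s_xi, hp.beta_theta_for(p) + p - s_xi))
    # keep theta strictly interior; Beta draws can underflow to exactly 0
    theta_new = min(max(theta_new, 1e-300), 1.0 - 1e-16)
    return xi, theta_new


def _truncnorm_tail_std(lower: NDArray, u: NDArray) -> NDArray:
    """Standard-normal draws conditioned on Z >= lower, via the inverse log-CDF.

    Accurate far into the tail: the survival mass is carried in log space
    through ``ndtri_exp``.
    """
    log_surv = np.log1p(-u) + log_ndtr(-lower)
    return -ndtri_exp(log_surv)


def _sample_mu_twopiece(
    m: NDArray, n_k: NDArray, lam: NDArray, rng: np.random.Generator
) -> NDArray:
    """Exact draws from density prop. to exp(-n_k (mu - m)^2 / 2 - lam |mu|).

    The density is a two-component mixture of truncated normals: on
    [0, inf) a N(m - lam/n_k, 1/n_k), on (-inf, 0] a N(m + lam/n_k, 1/n_k),
    with log-space mixture weights from normal CDF terms.  All arguments
    broadcast elementwise.
    """
    m, n_k, lam = np.broadcast_arrays(m, n_k, lam)
    sd = 1.0 / np.sqrt(n_k)
    m_pos = m - lam / n_k
    m_neg = m + lam / n_k
    # branch masses (common factor lam^2 / 2 n_k dropped)
    log_w_pos = -lam * m + log_ndtr(m_pos / sd)
    log_w_neg = lam * m + log_ndtr(-m_neg / sd)
    take_pos = rng.random(m.shape) < expit(log_w_pos - log_w_neg)
    u = rng.random(m.shape)
    # positive side: Z >= -m_pos/sd ; negative side by reflection
    z_pos = _truncnorm_tail_std(-m_pos / sd, u)
    z_neg = _truncnorm_tail_std(m_neg / sd, u)
    out = np.where(take_pos, m_pos + sd * z_pos, m_neg - sd * z_neg)
    return out


def sample_mu_entry(
    resid_sum: float, n_k: int, lam: float, rng: np.random.Generator
) -> float:
    """One exact draw of a center entry given its cluster's data.

    The full conditional is proportional to
    ``exp(-n_k (mu - m)^2 / 2 - lam |mu|)`` with ``m = resid_sum / n_k``.
    """
    if not np.isfinite(resid_sum):
        raise ValueError("resid_sum must be finite")
    if n_k < 1:
        raise ValueError("n_k must be >= 1 (empty clusters are drawn from the prior)")
    if lam <= 0:
        raise ValueError("lam must be positive")
    m = np.asarray(resid_sum / n_k, dtype=float)
    return float(_sample_mu_twopiece(m, np.asarray(float(n_k)), np.asarray(lam), rng))


def update_mu(
    Y: NDArray[np.float64],
    z: NDArray[np.int_],
    xi: NDArray[np.int_],
    hp: Hyperparams,
    rng: np.random.Generator,
    K: int | None = None,
) -> NDArray[np.float64]:
    """Draw the full p x K center matrix from its conditional.

    Occupied clusters use the exact two-piece draw entrywise with the
    slab rate lambda1 on rows with xi_j = 1 and the spike rate lambda0
    elsewhere; empty clusters are refreshed from the Laplace prior.
    """
    p = Y.shape[0]
    z = np.asarray(z, dtype=int)
    if K is None:
        K = int(z.max()) if z.size else 1
    counts = np.bincount(z - 1, minlength=K)[:K]
    lam = np.where(np.asarray(xi) == 1, hp.lambda1, hp.lambda0)[:, None]  # p x 1
    mu = np.empty((p, K))
    occ = counts > 0
    if occ.any():
        sums = np.zeros((p, K))
        np.add.at(sums.T, z - 1, Y.T)
        m = sums[:, occ] / counts[occ][None, :]
        mu[:, occ] = _sample_mu_twopiece(
            m, counts[occ][None, :].astype(float), lam, rng
        )
    n_empty = int((~occ).sum())
    if n_empty:
        lam_cols = np.broadcast_to(lam, (p, n_empty))
        mu[:, ~occ] = rng.laplace(0.0, 1.0 / lam_cols)
    return mu


# ---------------------------------------------------------------------------
# trans-dimensional birth/death moves


def _k_move_once(
    state: GmmState,
    hp: Hyperparams,
    rng: np.random.Generator,
    counters: dict[str, int] | None = None,
) -> GmmState:
    """One Metropolis-Hastings birth/death attempt on empty components.

    Birth (K -> K+1): a fresh center column is drawn from the current-xi
    spike-and-slab prior (the draw cancels against the prior in the
    ratio), a weight ``b ~ Beta(alpha, n + K alpha)`` is carved out of the
    existing weights, and the component is inserted at a uniformly random
    position.  With that proposal every b-dependent term cancels and

        log r = log pi(K+1) - log pi(K)
                + lgamma((K+1)a) - lgamma(Ka)
                + lgamma(n + Ka) - lgamma(n + (K+1)a)
                + log(K+1) - log(E+1),

    where E is the number of empty components before the birth.  Death
    removes a uniformly chosen empty component with the inverse ratio.
    """
    n = state.z.shape[0]
    K = state.K
    a = hp.alpha
    counts = np.bincount(state.z - 1, minlength=K)[:K]
    empties = np.flatnonzero(counts == 0)
    E = int(empties.size)
    birth = rng.random() < 0.5

    if birth:
        if counters is not None:
            counters["births_proposed"] += 1
        if K >= hp.Kmax:
            return state
        log_r = (
            log_prior_K(K + 1, hp)
            - log_prior_K(K, hp)
            + gammaln((K + 1) * a)
            - gammaln(K * a)
            + gammaln(n + K * a)
            - gammaln(n + (K + 1) * a)
            + math.log(K + 1)
            - math.log(E + 1)
        )
        if math.log(rng.random()) >= log_r:
            return state
        b = float(rng.beta(a, n + K * a))
        b = min(max(b, 1e-300), 1.0 - 1e-12)
        pos = int(rng.integers(0, K + 1))  # 0-based insertion slot
        lam = np.where(state.xi == 1, hp.lambda1, hp.lambda0)
        new_col = rng.laplace(0.0, 1.0 / lam)
        mu = np.insert(state.mu, pos, new_col, axis=1)
        w = np.insert(state.w * (1.0 - b), pos, b)
        z = state.z + (state.z > pos)  # labels strictly above the slot shift up
        if counters is not None:
            counters["births_accepted"] += 1
        return GmmState(mu, state.xi, state.theta, z, w)

    if counters is not None:
        counters["deaths_proposed"] += 1
    if K <= 1 or E == 0:
        return state
    log_r = (
        log_prior_K(K - 1, hp)
        - log_prior_K(K, hp)
        + gammaln((K - 1) * a)
        - gammaln(K * a)
        + gammaln(n + K * a)
        - gammaln(n + (K - 1) * a)
        + math.log(E)
        - math.log(K)
    )
    if math.log(rng.random()) >= log_r:
        return state
    k0 = int(empties[rng.integers(0, E)])
    b = float(state.w[k0])
    mu = np.delete(state.mu, k0, axis=1)
    w = np.delete(state.w, k0) / max(1.0 - b, 1e-300)
    w = w / w.sum()  # guard renormalization drift
    z = state.z - (state.z > k0 + 1)
    if counters is not None:
        counters["deaths_accepted"] += 1
    return GmmState(mu, state.xi, state.theta, z, w)


def update_K(
    state: GmmState,
    hp: Hyperparams,
    rng: np.random.Generator,
    counters: dict[str, int] | None = None,
) -> GmmState:
    """Public single birth/death attempt (identity whenever Kmax = 1)."""
    if hp.Kmax == 1:
        return state
    return _k_move_once(state, hp, rng, counters)


# ---------------------------------------------------------------------------
# sweeps and the full chain


def gibbs_sweep(
    state: GmmState,
    Y: NDArray[np.float64],
    hp: Hyperparams,
    rng: np.random.Generator,
    k_move_rate: float = 1.0,
    k_moves_per_sweep: int = 2,
    counters: dict[str, int] | None = None,
) -> GmmState:
    """One systematic scan: w, z, mu, xi, theta, then the K moves."""
    w = update_w(state.z, state.K, hp.alpha, rng)
    z = update_z(Y, state.mu, w, rng)
    mu = update_mu(Y, z, state.xi, hp, rng, K=state.K)
    xi, theta = update_xi_theta(mu, state.theta, hp, rng)
    state = GmmState(mu, xi, theta, z, w)
    for _ in range(k_moves_per_sweep):
        if rng.random() < k_move_rate:
            state = _k_move_once(state, hp, rng, counters)
    return state


def _state_log_joint(state: GmmState, Y: NDArray[np.float64], hp: Hyperparams) -> float:
    params = ClusterParams(state.mu, state.xi, state.theta)
    alloc = Allocation(state.z, state.w, state.K)
    return log_joint(Y, params, alloc, hp)


def _init_state(
    Y: NDArray[np.float64], hp: Hyperparams, cfg: McmcConfig, rng: np.random.Generator
) -> GmmState:
    from sklearn.cluster import KMeans

    p, n = Y.shape
    K0 = cfg.init_K if cfg.init_K is not None else int(round(hp.lambda_pois))
    K0 = max(1, min(K0, hp.Kmax, n))
    if K0 == 1:
        z = np.ones(n, dtype=int)
    else:
        km = KMeans(
            n_clusters=K0,
            n_init=cfg.kmeans_n_init,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(Y.T)
        z = km.labels_.astype(int) + 1
    mu, _ = _cluster_means(Y, z, K0)
    xi = np.zeros(p, dtype=int)
    theta = 1.0 / (1.0 + hp.beta_theta_for(p))
    w = np.full(K0, 1.0 / K0)
    return GmmState(mu, xi, theta, z, w)


def _cluster_means(
    Y: NDArray[np.float64], z: NDArray[np.int_], K: int
) -> tuple[NDArray[np.float64], NDArray[np.int_]]:
    p = Y.shape[0]
    counts = np.bincount(z - 1, minlength=K)[:K]
    sums = np.zeros((p, K))
    np.add.at(sums.T, z - 1, Y.T)
    mu = np.divide(sums, counts, out=np.zeros((p, K)), where=counts > 0)
    return mu, counts


def run_mcmc(
    Y: DataMatrix | NDArray[np.float64], hp: Hyperparams, cfg: McmcConfig
) -> McmcTrace:
    """Run the full sampler and return the post-burn-in trace.

    Initialization: labels from K-means with K = round(lambda_pois)
    clusters, centers at the cluster means, all indicators at zero, and
    theta at its tiny prior mean; birth moves grow K from there.  Fully
    reproducible given ``cfg.seed``.
    """
    values = Y.values if isinstance(Y, DataMatrix) else np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("Y must be finite")
    p, n = values.shape
    rng = np.random.default_rng(cfg.seed)
    state = _init_state(values, hp, cfg, rng)
    T = cfg.n_iter - cfg.burn_in
    z_kept = np.zeros((T, n), dtype=np.int32)
    K_kept = np.zeros(T, dtype=np.int32)
    lj_kept = np.zeros(T)
    theta_kept = np.zeros(T)
    nxi_kept = np.zeros(T, dtype=np.int32)
    xi_sum = np.zeros(p)
    mu_kept: list[NDArray[np.float64]] | None = [] if cfg.store_mu else None
    counters = {
        "births_proposed": 0,
        "births_accepted": 0,
        "deaths_proposed": 0,
        "deaths_accepted": 0,
    }
    for it in range(cfg.n_iter):
        state = gibbs_sweep(
            state, values, hp, rng, cfg.k_move_rate, cfg.k_moves_per_sweep, counters
        )
        lj = _state_log_joint(state, values, hp)
        if not np.isfinite(lj):
            raise RuntimeError(
                f"non-finite log joint at iteration {it} (K={state.K}, "
                f"theta={state.theta:.3g}); aborting"
            )
        if it >= cfg.burn_in:
            t = it - cfg.burn_in
            z_kept[t] = state.z
            K_kept[t] = state.K
            lj_kept[t] = lj
            theta_kept[t] = state.theta
            nxi_kept[t] = int(state.xi.sum())
            xi_sum += state.xi
            if mu_kept is not None:
                mu_kept.append(state.mu.copy())
    return McmcTrace(
        z=z_kept,
        K=K_kept,
        log_joint=lj_kept,
        theta=theta_kept,
        n_xi=nxi_kept,
        xi_mean=xi_sum / T,
        mu=mu_kept,
        **counters,
    )


# ---------------------------------------------------------------------------
# label alignment and point estimation


def _alignment_map(
    z_sample: NDArray[np.int_], z_ref: NDArray[np.int_]
) -> NDArray[np.int_]:
    """Maximum-agreement label map from a sample's labels to the reference's.

    Returns an array ``perm`` with ``perm[a-1]`` the aligned (1-based)
    label for sample label ``a``; extra sample clusters map onto labels
    beyond the reference's range.
    """
    K_s = int(z_sample.max())
    K_r = int(z_ref.max())
    m = max(K_s, K_r)
    table = np.zeros((m, m), dtype=int)
    np.add.at(table, (z_sample - 1, z_ref - 1), 1)
    rows, cols = linear_sum_assignment(table, maximize=True)
    perm = np.empty(m, dtype=int)
    perm[rows] = cols + 1
    return perm


def estimate_partition(trace: McmcTrace) -> tuple[NDArray[np.int_], int]:
    """Aligned posterior-mode partition and the implied number of clusters.

    Every stored label vector is aligned to the maximum-log-joint sample
    by maximum-agreement assignment on the confusion matrix; the estimate
    takes the per-observation modal aligned label (ties to the smallest
    label) and K_hat is the number of distinct labels used.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    ref = trace.z[int(np.argmax(trace.log_joint))]
    T, n = trace.z.shape
    max_lab = int(trace.z.max())
    votes = np.zeros((n, max_lab + 1), dtype=np.int32)
    for t in range(T):
        perm = _alignment_map(trace.z[t], ref)
        aligned = perm[trace.z[t] - 1]
        votes[np.arange(n), aligned] += 1
    z_hat = np.argmax(votes[:, 1:], axis=1) + 1  # argmax takes the smallest on ties
    labels = np.unique(z_hat)
    # relabel contiguously 1..K_hat, preserving order
    relab = {int(old): i + 1 for i, old in enumerate(labels)}
    z_hat = np.array([relab[int(v)] for v in z_hat], dtype=int)
    return z_hat, int(labels.size)


def estimate_means(trace: McmcTrace, z_hat: NDArray[np.int_]) -> NDArray[np.float64]:
    """Entrywise average of label-aligned center samples.

    Each stored center matrix is permuted by the maximum-agreement map
    from its label vector to ``z_hat``; columns mapping beyond the
    estimated clusters are dropped and missing columns simply do not
    contribute to the average.
    """
    if trace.mu is None:
        raise ValueError("trace does not store mu (run with store_mu=True)")
    z_hat = np.asarray(z_hat, dtype=int)
    K_hat = int(z_hat.max())
    p = trace.mu[0].shape[0]
    acc = np.zeros((p, K_hat))
    cnt = np.zeros(K_hat)
    for z_t, mu_t in zip(trace.z, trace.mu):
        perm = _alignment_map(z_t, z_hat)
        for a in range(mu_t.shape[1]):
            target = perm[a] if a < perm.shape[0] else 0
            if 1 <= target <= K_hat:
                acc[:, target - 1] += mu_t[:, a]
                cnt[target - 1] += 1
    with np.errstate(invalid="ignore"):
        out = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return out


def fit(
    Y: DataMatrix | NDArray[np.float64],
    hp: Hyperparams | None = None,
    cfg: McmcConfig | None = None,
) -> FitResult:
    """Run the sampler and extract point estimates in one call."""
    hp = hp or Hyperparams()
    cfg = cfg or McmcConfig()
    trace = run_mcmc(Y, hp, cfg)
    z_hat, K_hat = estimate_partition(trace)
    mu_hat = estimate_means(trace, z_hat) if trace.mu is not None else None
    return FitResult(z_hat=z_hat, K_hat=K_hat, mu_hat=mu_hat, xi_mean=trace.xi_mean, trace=trace)


# ---------------------------------------------------------------------------
# prior simulation (used by the simulation-consistency validation tests)


def sample_state_from_prior(
    p: int, n: int, hp: Hyperparams, rng: np.random.Generator
) -> GmmState:
    """Joint draw of (K, w, z, theta, xi, mu) from the prior."""
    ks = np.arange(1, hp.Kmax + 1)
    logs = ks * math.log(hp.lambda_pois) - gammaln(ks + 1)
    pmf = np.exp(logs - logs.max())
    pmf /= pmf.sum()
    K = int(rng.choice(ks, p=pmf))
    w = rng.dirichlet(np.full(K, hp.alpha)) if K > 1 else np.ones(1)
    z = rng.choice(K, size=n, p=w) + 1 if n > 0 else np.zeros(0, dtype=int)
    theta = float(rng.beta(1.0, hp.beta_theta_for(p)))
    theta = min(max(theta, 1e-300), 1.0 - 1e-16)
    xi = (rng.random(p) < theta).astype(int)
    lam = np.where(xi == 1, hp.lambda1, hp.lambda0)[:, None]
    mu = rng.laplace(0.0, 1.0 / np.broadcast_to(lam, (p, K)))
    return GmmState(mu, xi, theta, z, w)


def resample_data(
    state: GmmState, rng: np.random.Generator
) -> NDArray[np.float64]:
    """Draw Y | state from the working likelihood N(mu_{z_i}, I_p)."""
    p, n = state.p, state.z.shape[0]
    return state.mu[:, state.z - 1] + rng.standard_normal((p, n))
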