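"""Full-conditional updates, two-piece-normal draws, and point estimation."""

import numpy as np
import pytest
from scipy.integrate import quad

from sparsegmm.core_model import Hyperparams
from sparsegmm.sampler import (
    GmmState,
    McmcConfig,
    McmcTrace,
    estimate_means,
    estimate_partition,
    run_mcmc,
    sample_mu_entry,
    update_K,
    update_mu,
    update_w,
    update_xi_theta,
    update_z,
)


def _hp(**kw):
    defaults = dict(lambda0=5.0, lambda1=1.0, beta_theta=3.0, alpha=1.0,
                    lambda_pois=2.0, Kmax=5)
    defaults.update(kw)
    return Hyperparams(**defaults)


class TestUpdateW:
    def test_single_cluster_returns_point_mass(self, rng):
        np.testing.assert_array_equal(update_w(np.ones(5, dtype=int), 1, 1.0, rng), [1.0])

    def test_large_alpha_concentrates_at_uniform(self, rng):
        z = np.array([1] * 8 + [2] * 2)
        draws = np.array([update_w(z, 2, 1e6, rng) for _ in range(2000)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.5, 0.5], atol=0.01)

    def test_mean_matches_conjugate_posterior(self, rng):
        z = np.array([1] * 6 + [2] * 3 + [3] * 1)
        alpha = 2.0
        expected = (alpha + np.array([6, 3, 1])) / (3 * alpha + 10)
        draws = np.array([update_w(z, 3, alpha, rng) for _ in range(20000)])
        se = np.sqrt(expected * (1 - expected) / 20000)  # conservative bound
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se)

    def test_rejects_zero_clusters(self, rng):
        with pytest.raises(ValueError):
            update_w(np.ones(2, dtype=int), 0, 1.0, rng)


class TestUpdateZ:
    def test_degenerate_weights_force_label_one(self, rng):
        Y = rng.normal(size=(3, 10))
        mu = rng.normal(size=(3, 2))
        z = update_z(Y, mu, np.array([1.0, 0.0]), rng)
        assert np.all(z == 1)

    def test_well_separated_point_goes_to_its_center(self, rng):
        mu = np.zeros((4, 2))
        mu[:, 1] = 10.0
        Y = np.tile(mu[:, [1]], (1, 2000))
        z = update_z(Y, mu, np.array([0.5, 0.5]), rng)
        assert np.mean(z == 2) >= 1 - 1e-6

    def test_frequencies_match_analytic_conditional(self, rng):
        # two-cluster toy: replicate one observation many times and compare
        # empirical allocation frequencies to the analytic softmax
        mu = np.array([[0.0, 2.0], [0.0, -1.0]])
        w = np.array([0.3, 0.7])
        y = np.array([0.8, -0.2])
        logp = np.log(w) - 0.5 * np.sum((y[:, None] - mu) ** 2, axis=0)
        p1 = np.exp(logp - logp.max())
        p1 /= p1.sum()
        n = 50000
        z = update_z(np.tile(y[:, None], (1, n)), mu, w, rng)
        freq = np.array([np.mean(z == 1), np.mean(z == 2)])
        se = np.sqrt(p1 * (1 - p1) / n)
        assert np.all(np.abs(freq - p1) < 3 * se)


class TestUpdateXiTheta:
    def test_zero_row_with_heavy_spike_stays_spike(self, rng):
        hp = _hp(lambda0=100.0, lambda1=1.0)
        mu = np.zeros((200, 2))
        xi, _ = update_xi_theta(mu, 0.01, hp, rng)
        # plug-in odds: q = theta (lam1/lam0)^K / (theta (lam1/lam0)^K + 1-theta) ~ 1e-6
        assert xi.sum() == 0

    def test_theta_posterior_with_all_spike(self, rng):
        hp = _hp(lambda0=100.0, lambda1=1.0, beta_theta=7.0)
        p = 50
        draws = [update_xi_theta(np.zeros((p, 1)), 1e-4, hp, rng)[1] for _ in range(20000)]
        # xi = 0 almost surely, so theta ~ Beta(1, beta_theta + p)
        expected_mean = 1.0 / (1.0 + 7.0 + p)
        assert np.mean(draws) == pytest.approx(expected_mean, rel=0.05)

    def test_slab_row_turns_indicator_on(self, rng):
        hp = _hp(lambda0=100.0, lambda1=1.0)
        mu = np.full((5, 2), 3.0)  # large entries: slab odds overwhelm tiny theta
        xi, _ = update_xi_theta(mu, 1e-4, hp, rng)
        assert xi.sum() == 5


def _twopiece_moments(m, n_k, lam):
    """Quadrature oracle for density prop to exp(-n_k (x-m)^2/2 - lam |x|)."""
    f = lambda x: np.exp(-0.5 * n_k * (x - m) ** 2 - lam * abs(x))
    z, _ = quad(f, -30, 30)
    mean, _ = quad(lambda x: x * f(x), -30, 30)
    second, _ = quad(lambda x: x * x * f(x), -30, 30)
    return mean / z, second / z - (mean / z) ** 2


class TestSampleMuEntry:
    def test_vanishing_penalty_recovers_normal_mean(self, rng):
        m = 1.7
        draws = [sample_mu_entry(m * 4, 4, 1e-9, rng) for _ in range(50000)]
        se = 0.5 / np.sqrt(50000)
        assert abs(np.mean(draws) - m) < 3 * se

    def test_symmetric_at_zero_mean(self, rng):
        draws = np.array([sample_mu_entry(0.0, 2, 1.5, rng) for _ in range(20000)])
        assert abs(np.median(draws)) < 0.02
        assert abs(np.mean(draws)) < 0.02

    def test_moments_match_quadrature_oracle(self, rng):
        m, n_k, lam = 2.0, 5, 1.0
        mean, var = _twopiece_moments(m, n_k, lam)
        draws = np.array([sample_mu_entry(m * n_k, n_k, lam, rng) for _ in range(50000)])
        assert np.mean(draws) == pytest.approx(mean, abs=3 * np.sqrt(var / 50000))
        assert np.var(draws) == pytest.approx(var, rel=0.05)

    def test_far_tail_spike_draw_is_finite_and_shrunk(self, rng):
        # heavy spike rate pushes the draw toward zero from a distant mean
        draws = [sample_mu_entry(3.0, 1, 100.0, rng) for _ in range(100)]
        assert np.all(np.isfinite(draws))
        assert abs(np.mean(draws)) < 0.2

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            sample_mu_entry(np.inf, 3, 1.0, rng)
        with pytest.raises(ValueError):
            sample_mu_entry(1.0, 0, 1.0, rng)


class TestUpdateMu:
    def test_single_cluster_single_coordinate_matches_entry_sampler(self, rng):
        hp = _hp()
        Y = np.array([[1.0, 2.0, 3.0]])
        z = np.ones(3, dtype=int)
        xi = np.array([1])
        draws = np.array([update_mu(Y, z, xi, hp, rng, K=1)[0, 0] for _ in range(20000)])
        mean, var = _twopiece_moments(2.0, 3, hp.lambda1)
        assert np.mean(draws) == pytest.approx(mean, abs=3 * np.sqrt(var / 20000))

    def test_empty_cluster_drawn_from_laplace_prior(self, rng):
        hp = _hp(lambda0=2.0, lambda1=1.0)
        Y = np.zeros((3, 4))
        z = np.ones(4, dtype=int)
        xi = np.zeros(3, dtype=int)
        draws = np.array([update_mu(Y, z, xi, hp, rng, K=2)[:, 1] for _ in range(20000)])
        assert np.var(draws) == pytest.approx(2.0 / hp.lambda0**2, rel=0.05)


class TestUpdateK:
    def test_identity_when_kmax_one(self, rng):
        hp = _hp(Kmax=1)
        state = GmmState(np.zeros((2, 1)), np.zeros(2, dtype=int), 0.1,
                         np.ones(3, dtype=int), np.ones(1))
        out = update_K(state, hp, rng)
        assert out.K == 1
        np.testing.assert_array_equal(out.z, state.z)

    def test_death_only_removes_empty_components(self, rng):
        hp = _hp(Kmax=3, lambda_pois=0.1)  # strong prior pull toward small K
        state = GmmState(np.zeros((2, 2)), np.zeros(2, dtype=int), 0.1,
                         np.array([1, 1, 1]), np.array([0.9, 0.1]))
        for _ in range(200):
            state = update_K(state, hp, rng)
            assert state.K >= 1
            assert np.all(np.bincount(state.z - 1, minlength=state.K)[: 1] > 0)
        # the occupied component must survive every death
        assert np.all(state.z == state.z[0])

    def test_birth_then_reversal_preserves_occupied_structure(self, rng):
        hp = _hp(Kmax=4)
        z = np.array([1, 1, 2, 2])
        state = GmmState(rng.normal(size=(3, 2)), np.zeros(3, dtype=int), 0.2,
                         z, np.array([0.5, 0.5]))
        for _ in range(300):
            state = update_K(state, hp, rng)
            counts = np.bincount(state.z - 1, minlength=state.K)
            # the two occupied clusters are never merged, split, or killed
            assert sorted(counts[counts > 0].tolist()) == [2, 2]


def _toy_trace(z_samples, log_joint=None, mu=None):
    z = np.asarray(z_samples, dtype=int)
    T = z.shape[0]
    lj = np.asarray(log_joint, dtype=float) if log_joint is not None else np.zeros(T)
    K = np.array([zz.max() for zz in z])
    return McmcTrace(z=z, K=K, log_joint=lj, theta=np.full(T, 0.1),
                     n_xi=np.zeros(T, dtype=int), xi_mean=np.zeros(1), mu=mu)


class TestEstimatePartition:
    def test_constant_trace_returned_verbatim(self):
        z = np.array([[1, 2, 2, 1]] * 5)
        z_hat, K_hat = estimate_partition(_toy_trace(z))
        np.testing.assert_array_equal(z_hat, [1, 2, 2, 1])
        assert K_hat == 2

    def test_label_switched_copies_align(self):
        base = np.array([1, 1, 2, 2, 3])
        perms = [np.array([1, 2, 3]), np.array([2, 3, 1]), np.array([3, 1, 2])]
        z = np.array([perm[base - 1] for perm in perms])
        z_hat, K_hat = estimate_partition(_toy_trace(z))
        assert K_hat == 3
        # same partition up to relabeling
        from sparsegmm.metrics import hamming_misclustering
        assert hamming_misclustering(z_hat, base) == 0.0

    def test_majority_vote_on_three_sample_toy(self):
        # reference (max log-joint) is sample 0; sample 1 agrees, sample 2
        # flips observation 3 -> majority keeps the reference's label
        z = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [1, 1, 2, 1]])
        z_hat, K_hat = estimate_partition(_toy_trace(z, log_joint=[5.0, 1.0, 1.0]))
        np.testing.assert_array_equal(z_hat, [1, 1, 2, 2])
        assert K_hat == 2

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_partition(_toy_trace(np.zeros((0, 3), dtype=int)))


class TestEstimateMeans:
    def test_constant_trace(self):
        z = np.array([[1, 2], [1, 2]])
        mu = [np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]])]
        out = estimate_means(_toy_trace(z, mu=mu), np.array([1, 2]))
        np.testing.assert_allclose(out, [[1.0, 2.0]])

    def test_column_permuted_copies_align(self):
        z = np.array([[1, 2], [2, 1]])
        mu = [np.array([[1.0, 5.0]]), np.array([[5.0, 1.0]])]
        out = estimate_means(_toy_trace(z, mu=mu), np.array([1, 2]))
        np.testing.assert_allclose(out, [[1.0, 5.0]])

    def test_average_of_two_samples(self):
        z = np.array([[1, 2], [1, 2]])
        mu = [np.array([[1.0, 3.0]]), np.array([[3.0, 5.0]])]
        out = estimate_means(_toy_trace(z, mu=mu), np.array([1, 2]))
        np.testing.assert_allclose(out, [[2.0, 4.0]])

    def test_missing_mu_rejected(self):
        with pytest.raises(ValueError, match="store_mu"):
            estimate_means(_toy_trace(np.array([[1, 2]])), np.array([1, 2]))


class TestRunMcmc:
    def test_trace_length_and_determinism(self, small_two_cluster):
        Y, z_true, _ = small_two_cluster
        hp = _hp(Kmax=6)
        cfg = McmcConfig(n_iter=300, burn_in=100, seed=5)
        t1 = run_mcmc(Y, hp, cfg)
        t2 = run_mcmc(Y, hp, cfg)
        assert len(t1) == 200
        np.testing.assert_array_equal(t1.z, t2.z)
        np.testing.assert_array_equal(t1.K, t2.K)
        np.testing.assert_allclose(t1.log_joint, t2.log_joint)

    def test_log_joint_finite_throughout(self, small_two_cluster):
        Y, _, _ = small_two_cluster
        trace = run_mcmc(Y, _hp(Kmax=6), McmcConfig(n_iter=300, burn_in=100, seed=5))
        assert np.all(np.isfinite(trace.log_joint))

    def test_recovers_well_separated_clusters(self, small_two_cluster):
        Y, z_true, _ = small_two_cluster
        trace = run_mcmc(Y, _hp(Kmax=6), McmcConfig(n_iter=400, burn_in=100, seed=9))
        z_hat, K_hat = estimate_partition(trace)
        from sparsegmm.metrics import ari
        assert K_hat == 2
        assert ari(z_true, z_hat) == 1.0

    def test_rejects_nonfinite_input(self):
        with pytest.raises(ValueError):
            run_mcmc(np.array([[np.nan, 1.0]]), _hp(), McmcConfig(n_iter=10, burn_in=1))


def test_posterior_risk_rate_stays_bounded_as_n_grows():
    """Scenario-I-style contraction sanity: the posterior-mean estimate of
    mu L^T has squared error on the order of s log p + n log Kmax."""
    from sparsegmm.sampler import estimate_means

    p, s, K = 120, 6, 3
    hp = Hyperparams(Kmax=10)
    ratios = {}
    for n in (60, 120):
        rng = np.random.default_rng(400 + n)
        mu = np.zeros((p, K))
        mu[:s, 0] = 3.0
        mu[:s, 1] = -1.5
        z = rng.integers(1, K + 1, size=n)
        Y = mu[:, z - 1] + rng.standard_normal((p, n))
        cfg = McmcConfig(n_iter=750, burn_in=150, seed=n, store_mu=True)
        trace = run_mcmc(Y, hp, cfg)
        z_hat, _ = estimate_partition(trace)
        mu_hat = estimate_means(trace, z_hat)
        err = float(np.sum((mu_hat[:, z_hat - 1] - mu[:, z - 1]) ** 2))
        ratios[n] = err / (s * np.log(p) + n * np.log(hp.Kmax))
    assert all(r < 10.0 for r in ratios.values())
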