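import itertools

import numpy as np
import pytest
from scipy.special import digamma

from scmethclust.metrics import v_measure
from scmethclust.model import (
    BernoulliMixtureModel,
    FixedParams,
    Hyperparams,
    fit_mixture,
)
from scmethclust.simulate import simulate_dataset


def _random_instance(rng, n_max=12, m_max=15, k_max=4):
    n = int(rng.integers(3, n_max))
    m = int(rng.integers(2, m_max))
    k = int(rng.integers(1, k_max + 1))
    X = rng.integers(-1, 2, size=(n, m)).astype(float)
    ridx = np.sort(rng.integers(0, 3, size=m))
    return BernoulliMixtureModel(X, k, region_index=ridx)


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------

class TestInit:
    def test_partition_init_one_hot(self):
        X = np.array([[1, 0], [1, 0], [0, 1]], dtype=float)
        m = BernoulliMixtureModel(X, 3)
        st = m.init_state(np.array([1, 1, 2]))
        np.testing.assert_array_equal(
            st.resp, [[1, 0, 0], [1, 0, 0], [0, 1, 0]]
        )
        assert np.allclose(st.resp.sum(axis=1), 1.0)

    def test_dirichlets_start_at_priors(self):
        X = np.zeros((4, 3))
        hyper = Hyperparams(alpha0=2.0, beta0=(0.5, 1.5))
        m = BernoulliMixtureModel(X, 2, hyperparams=hyper)
        st = m.init_state(np.array([0, 0, 1, 1]))
        np.testing.assert_array_equal(st.alpha_star, [2.0, 2.0])
        np.testing.assert_array_equal(st.beta_star, m._beta0)
        np.testing.assert_array_equal(st.gamma_star, m._gamma0)

    def test_random_init_cluster_count_uniform(self):
        """The initial cluster count is uniform on {1..K}.

        With 200 cells every drawn cluster is occupied with probability
        essentially 1, so the occupied count identifies the draw.
        """
        K = 4
        X = np.ones((200, 2))
        m = BernoulliMixtureModel(X, K)
        rng = np.random.default_rng(123)
        draws = 4000
        counts = np.zeros(K)
        for _ in range(draws):
            st = m.init_state("random", rng=rng)
            c0 = int((st.resp.sum(axis=0) > 0).sum())
            counts[c0 - 1] += 1
        se = np.sqrt((1 / K) * (1 - 1 / K) / draws)
        assert np.abs(counts / draws - 1 / K).max() < 3 * se

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            BernoulliMixtureModel(np.ones((2, 2)), 0)


# ----------------------------------------------------------------------
# sweeps: invariants
# ----------------------------------------------------------------------

class TestSweepInvariants:
    def test_elbo_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            m = _random_instance(rng)
            st = m.init_state("random", rng=rng)
            prev = -np.inf
            for _ in range(25):
                m.sweep(st)
                cur = m.elbo(st)
                assert cur >= prev - 1e-8
                prev = cur

    def test_normalization_and_mass_conservation(self):
        rng = np.random.default_rng(1)
        m = _random_instance(rng)
        st = m.init_state("random", rng=rng)
        for _ in range(10):
            m.sweep(st)
            assert np.abs(st.resp.sum(axis=1) - 1).max() < 1e-12
            assert np.abs(st.phi.sum(axis=2) - 1).max() < 1e-12
            assert st.alpha_star.sum() == pytest.approx(
                m._alpha0.sum() + m.N, abs=1e-9
            )
            assert (st.alpha_star > 0).all()
            assert (st.beta_star > 0).all()
            assert (st.gamma_star > 0).all()

    def test_single_observation_hand_computation(self):
        """N=M=K=1 with X=1: the hidden state favours methylated and the
        error-channel posterior absorbs the single observation."""
        X = np.array([[1.0]])
        m = BernoulliMixtureModel(X, 1)
        st = m.init_state(np.array([0]))
        m.sweep(st)
        phi1 = st.phi[0, 0, 1]
        assert phi1 > 0.5
        # gamma_*[s, t=1] = gamma0[s, 1] + resp * phi_s
        assert st.gamma_star[1, 1] == pytest.approx(
            m._gamma0[1, 1] + phi1
        )
        assert st.gamma_star[0, 1] == pytest.approx(
            m._gamma0[0, 1] + (1 - phi1)
        )
        # hand-check phi against the update equation at the prior values
        elog_mu = digamma(1.0) - digamma(2.0)  # symmetric beta prior
        g = m._gamma0
        elog_eps = digamma(g) - digamma(g.sum(axis=1, keepdims=True))
        log_w = np.array(
            [elog_mu + elog_eps[0, 1], elog_mu + elog_eps[1, 1]]
        )
        expected = np.exp(log_w[1]) / np.exp(log_w).sum()
        assert phi1 == pytest.approx(expected, rel=1e-12)

    def test_all_missing_matrix(self):
        X = np.full((3, 4), np.nan)
        m = BernoulliMixtureModel(X, 2)
        assert len(m.all_missing_cells) == 3
        st = m.init_state(np.array([0, 1, 0]))
        m.sweep(st)
        # with no likelihood terms every cell's responsibilities equal
        # the softmax of E[log pi]
        assert np.allclose(st.resp, st.resp[0])
        e = m.elbo(st)
        assert np.isfinite(e) and e <= 1e-9


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

class TestFit:
    def test_separated_clusters_recovered_exactly(self):
        ds = simulate_dataset(n_cells=24, n_loci=120, n_regions=6,
                              n_clusters=2, missing_prop=0.0,
                              error_rate=0.0, seed=5)
        res = fit_mixture(ds.observed, 2, init=ds.true_labels)
        _h, _c, v = v_measure(ds.true_labels, res.map_labels)
        assert v == pytest.approx(1.0)
        assert res.converged

    def test_single_component(self):
        ds = simulate_dataset(n_cells=10, n_loci=50, n_regions=2, seed=8)
        res = fit_mixture(ds.observed, 1, rng=0)
        assert (res.map_labels == 0).all()
        assert res.n_clusters_found == 1

    def test_region_free_variant_equals_single_region_fit(self):
        """Mapping all loci to one region and the shared-region flag give
        bit-identical fits."""
        rng = np.random.default_rng(3)
        X = rng.integers(-1, 2, size=(12, 10)).astype(float)
        init = rng.integers(0, 3, size=12)
        m1 = BernoulliMixtureModel(X, 3, region_index=np.zeros(10, int))
        m2 = BernoulliMixtureModel(
            X, 3, shared_region=True,
            region_index=np.sort(rng.integers(0, 4, size=10)),
        )
        r1 = m1.fit(init=init, max_iters=60)
        r2 = m2.fit(init=init, max_iters=60)
        np.testing.assert_array_equal(r1.state.resp, r2.state.resp)
        assert r1.elbo == r2.elbo
        assert r1.dic == r2.dic

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.integers(-1, 2, size=(9, 12)).astype(float)
        init_a = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        perm = {0: 2, 1: 0, 2: 1}
        init_b = np.array([perm[v] for v in init_a])
        m = BernoulliMixtureModel(X, 3)
        ra = m.fit(init=init_a, max_iters=40)
        rb = m.fit(init=init_b, max_iters=40)
        # permuting initial labels permutes the columns of the output
        np.testing.assert_allclose(
            ra.state.resp[:, [0, 1, 2]],
            rb.state.resp[:, [2, 0, 1]],
            atol=1e-12,
        )
        np.testing.assert_array_equal(ra.map_labels, rb.map_labels)

    def test_nonconvergence_flagged_not_fatal(self):
        ds = simulate_dataset(n_cells=20, n_loci=100, n_regions=5, seed=6)
        res = fit_mixture(ds.observed, 3, rng=1, max_iters=2)
        assert res.n_iters == 2
        assert not res.converged


# ----------------------------------------------------------------------
# exact-posterior oracle (fixed parameters)
# ----------------------------------------------------------------------

def exact_assignment_posterior(X, pi, mu, eps, ridx):
    """Marginal P(Z_n | X) by enumeration over all joint assignments,
    summing the hidden states analytically per (cluster, locus)."""
    N, M = X.shape
    K = len(pi)
    total = np.zeros((N, K))
    for Z in itertools.product(range(K), repeat=N):
        logp = sum(np.log(pi[z]) for z in Z)
        for k in range(K):
            cells = [n for n in range(N) if Z[n] == k]
            for col in range(M):
                acc = 0.0
                for s in (0, 1):
                    p = mu[k, ridx[col], s]
                    for n in cells:
                        x = X[n, col]
                        if x >= 0:
                            p *= eps[s, int(x)]
                    acc += p
                logp += np.log(acc)
        w = np.exp(logp)
        for n in range(N):
            total[n, Z[n]] += w
    return total / total.sum(axis=1, keepdims=True)


def test_vb_matches_exact_posterior_argmax_when_decisive():
    """With parameters held fixed, the variational per-cell assignment
    argmax agrees with exact enumeration whenever the exact posterior is
    decisive (margin > 0.15); near-uniform posteriors are excluded since
    mean-field solutions legitimately extremize them."""
    rng = np.random.default_rng(7)
    checked = 0
    pi = np.array([0.5, 0.5])
    eps = np.array([[0.95, 0.05], [0.05, 0.95]])
    ridx = np.array([0, 0, 1])
    while checked < 8:
        mu = np.empty((2, 2, 2))
        mu[:, :, 1] = rng.choice([0.1, 0.9], size=(2, 2))
        mu[:, :, 0] = 1 - mu[:, :, 1]
        X = rng.integers(-1, 2, size=(4, 3)).astype(float)
        post = exact_assignment_posterior(X, pi, mu, eps, ridx)
        if np.abs(post[:, 0] - 0.5).min() < 0.15:
            continue
        checked += 1
        model = BernoulliMixtureModel(
            X, 2, region_index=ridx,
            fixed_params=FixedParams(pi=pi, mu=mu, eps=eps),
        )
        best = None
        for r in range(5):
            res = model.fit(init="random", rng=r, max_iters=200)
            if best is None or res.elbo > best.elbo:
                best = res
        np.testing.assert_array_equal(
            post.argmax(axis=1), best.state.resp.argmax(axis=1)
        )


# ----------------------------------------------------------------------
# DIC
# ----------------------------------------------------------------------

class TestDic:
    def test_concentrated_posterior_collapses_to_plugin_deviance(self):
        """As q(Z), q(G) approach point masses and the error-rate
        posterior concentrates, Dbar -> Dhat so DIC -> Dhat."""
        ds = simulate_dataset(n_cells=16, n_loci=80, n_regions=4,
                              n_clusters=2, missing_prop=0.2,
                              error_rate=0.01, seed=12)
        res = fit_mixture(ds.observed, 2, init=ds.true_labels)
        st = res.state.copy()
        # concentrate every factor
        st.resp = np.eye(2)[res.state.resp.argmax(axis=1)]
        st.phi = np.eye(2)[
            (res.state.phi[:, :, 1] > res.state.phi[:, :, 0]).astype(int)
        ]
        st.gamma_star = res.state.gamma_star * 1e6
        from scmethclust.model import BernoulliMixtureResults

        conc = BernoulliMixtureResults(res.model, st, True, 1)
        dbar = -2.0 * res.model._expected_loglik(st)
        assert conc.dic == pytest.approx(dbar, rel=1e-4)

    def test_two_clusters_beat_one_on_separated_data(self):
        ds = simulate_dataset(n_cells=30, n_loci=150, n_regions=6,
                              n_clusters=2, missing_prop=0.3, seed=13)
        r2 = fit_mixture(ds.observed, 2, init=ds.true_labels)
        r1 = fit_mixture(ds.observed, 1, rng=0)
        assert np.isfinite(r1.dic) and np.isfinite(r2.dic)
        assert r2.dic < r1.dic

    def test_dic_finite_for_interior_error_rates(self, small_dataset):
        res = fit_mixture(small_dataset.observed, 4, rng=2)
        eps = res.epsilon_mean
        assert (eps > 0).all() and (eps < 1).all()
        assert np.isfinite(res.dic)


# ----------------------------------------------------------------------
# imputation
# ----------------------------------------------------------------------

class TestImpute:
    def test_naive_majority_of_cluster_mates(self):
        X = np.array(
            [[1, 1], [1, np.nan], [0, np.nan]], dtype=float
        )
        m = BernoulliMixtureModel(X, 1)
        res = m.fit(init=np.zeros(3, dtype=int), max_iters=30)
        naive = res.impute("naive")
        # column 1 observed only in cell 0 (value 1): majority is 1
        assert naive[1, 1] == 1 and naive[2, 1] == 1
        # column 0: observed values (1,1,0) pass through unchanged
        np.testing.assert_array_equal(naive[:, 0], [1, 1, 0])

    def test_one_hot_resp_makes_adjusted_equal_unadjusted(self, small_dataset):
        res = fit_mixture(small_dataset.observed, 3,
                          init=small_dataset.true_labels)
        if np.allclose(res.resp.max(axis=1), 1.0, atol=1e-9):
            np.testing.assert_array_equal(
                res.impute("adjusted"), res.impute("unadjusted")
            )
        else:
            hard = res.resp.max(axis=1) > 1 - 1e-9
            np.testing.assert_array_equal(
                res.impute("adjusted")[hard], res.impute("unadjusted")[hard]
            )

    def test_observed_entries_pass_through_all_variants(self, small_dataset):
        res = fit_mixture(small_dataset.observed, 3, rng=5)
        obs = small_dataset.observed.observed
        vals = small_dataset.observed.values
        for variant in ("unadjusted", "adjusted", "naive"):
            imp = res.impute(variant)
            np.testing.assert_array_equal(imp[obs], vals[obs])
            assert np.isin(imp, [0, 1]).all()

    def test_unknown_variant_rejected(self, small_dataset):
        res = fit_mixture(small_dataset.observed, 2, rng=0)
        with pytest.raises(ValueError):
            res.impute("something")


def test_summary_mentions_key_quantities(small_dataset):
    res = fit_mixture(small_dataset.observed, 4, rng=0)
    text = res.summary()
    assert "ELBO" in text and "DIC" in text
    assert str(res.n_clusters_found) in text
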