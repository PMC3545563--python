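import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import invwishart, multivariate_normal, multivariate_t

from motionclust import igmm
from motionclust.igmm import (ClusterStats, GibbsState, NIWHyperparams,
                              crp_finite_prior, crp_prior, fit, gibbs_sweep,
                              log_joint, niw_posterior, sample_alpha)


# ---------------------------------------------------------------------------
# CRP priors

class TestCRP:
    def test_one_prior_point(self):
        np.testing.assert_allclose(crp_prior([1], 1.0), [0.5, 0.5])

    def test_two_clusters(self):
        np.testing.assert_allclose(crp_prior([2, 1], 1.0),
                                   [2 / 4, 1 / 4, 1 / 4])

    @settings(derandomize=True, max_examples=60)
    @given(counts=st.lists(st.integers(1, 50), min_size=1, max_size=8),
           alpha=st.floats(0.01, 20))
    def test_normalization(self, counts, alpha):
        p = crp_prior(counts, alpha)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p > 0)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            crp_prior([1], 0.0)

    def test_finite_prior_example(self):
        np.testing.assert_allclose(crp_finite_prior([1], 1.0, 2),
                                   [0.75, 0.25])

    def test_finite_prior_sums_to_one(self):
        p = crp_finite_prior([3, 2, 1], 0.7, 10)
        assert p.sum() == pytest.approx(1.0)

    def test_finite_to_infinite_limit(self):
        """The finite symmetric-Dirichlet predictive converges to the CRP
        conditional as the component bound K grows."""
        counts, alpha = [2, 1], 1.0
        big_k = 10 ** 6
        finite = crp_finite_prior(counts, alpha, big_k)
        inf = crp_prior(counts, alpha)  # [2/4, 1/4, 1/4]
        # represented clusters elementwise; unrepresented mass vs new-cluster
        assert np.max(np.abs(finite[:2] - inf[:2])) < 1e-5
        assert abs(finite[2:].sum() - inf[2]) < 1e-5


# ---------------------------------------------------------------------------
# NIW conjugacy

class TestNIWPosterior:
    def test_zero_observations_is_prior(self, default_prior):
        cs = niw_posterior(default_prior, np.empty((0, 3)))
        assert cs.n == 0
        assert cs.kappa_n == default_prior.kappa0
        assert cs.nu_n == default_prior.nu0
        np.testing.assert_array_equal(cs.mu_n, default_prior.mu0)
        np.testing.assert_array_equal(cs.lambda_n, default_prior.lambda0)

    def test_count_updates(self, default_prior, rng):
        obs = rng.normal(size=(10, 3))
        cs = niw_posterior(default_prior, obs)
        assert cs.kappa_n == pytest.approx(10.1)   # kappa0=0.1 + n
        assert cs.nu_n == pytest.approx(14.0)      # nu0=4 + n

    def test_add_then_remove_restores_prior(self, default_prior, rng):
        cs = ClusterStats(default_prior)
        x = rng.normal(size=3)
        cs.add(x)
        cs.remove(x)
        assert cs.n == 0
        np.testing.assert_allclose(cs.lambda_n, default_prior.lambda0,
                                   atol=1e-9)
        np.testing.assert_allclose(cs.mu_n, default_prior.mu0, atol=1e-9)

    def test_incremental_matches_batch(self, default_prior, rng):
        pts = rng.normal(size=(30, 3)) * 2 + 1
        inc = ClusterStats(default_prior)
        for x in pts:
            inc.add(x)
        batch = niw_posterior(default_prior, pts)
        np.testing.assert_allclose(inc.lambda_n, batch.lambda_n, atol=1e-9)
        np.testing.assert_allclose(inc.mu_n, batch.mu_n, atol=1e-9)
        # remove half and compare against batch on the remainder
        for x in pts[:15]:
            inc.remove(x)
        rest = niw_posterior(default_prior, pts[15:])
        np.testing.assert_allclose(inc.lambda_n, rest.lambda_n, atol=1e-9)

    def test_posterior_mean_formula(self, rng):
        prior = NIWHyperparams(np.array([1.0, -1.0]), 2.0, 5.0, np.eye(2))
        pts = rng.normal(size=(6, 2))
        cs = niw_posterior(prior, pts)
        xbar = pts.mean(axis=0)
        expected = (2.0 * prior.mu0 + 6 * xbar) / 8.0
        np.testing.assert_allclose(cs.mu_n, expected)

    def test_nonfinite_rejected(self, default_prior):
        with pytest.raises(ValueError):
            niw_posterior(default_prior, np.array([[np.nan, 0, 0]]))


class TestPredictive:
    def test_empty_cluster_is_prior_student_t(self):
        prior = NIWHyperparams(np.array([0.5, -0.2]), 0.7, 5.0,
                               np.array([[1.2, 0.3], [0.3, 0.9]]))
        cs = ClusterStats(prior)
        df = prior.nu0 - 2 + 1
        scale = prior.lambda0 * (prior.kappa0 + 1) / (prior.kappa0 * df)
        x = np.array([0.3, 1.1])
        assert cs.predictive_logpdf(x) == pytest.approx(
            multivariate_t.logpdf(x, prior.mu0, scale, df))

    def test_matches_scipy_after_updates(self, rng):
        prior = NIWHyperparams(np.zeros(3), 0.1, 4.0, 0.3 * np.eye(3))
        cs = niw_posterior(prior, rng.normal(size=(12, 3)))
        df = cs.nu_n - 3 + 1
        scale = cs.lambda_n * (cs.kappa_n + 1) / (cs.kappa_n * df)
        for x in rng.normal(size=(4, 3)):
            assert cs.predictive_logpdf(x) == pytest.approx(
                multivariate_t.logpdf(x, cs.mu_n, scale, df))

    def test_monte_carlo_niw_integration_oracle(self, rng):
        """The closed-form Student-t predictive equals the NIW-mixture of
        Gaussian densities, estimated by Monte-Carlo integration (D=2)."""
        prior = NIWHyperparams(np.array([0.2, -0.4]), 0.8, 6.0,
                               np.array([[1.0, 0.2], [0.2, 0.7]]))
        cs = niw_posterior(prior, rng.normal(size=(8, 2)) + 0.5)
        m = 100_000
        sigmas = invwishart.rvs(df=cs.nu_n, scale=cs.lambda_n, size=m,
                                random_state=rng)
        chols = np.linalg.cholesky(sigmas)
        z = rng.normal(size=(m, 2))
        mus = cs.mu_n + np.einsum("mij,mj->mi", chols, z) / np.sqrt(cs.kappa_n)
        for x in [np.array([0.0, 0.0]), np.array([1.5, -0.5])]:
            diff = x[None, :] - mus
            w = np.linalg.solve(chols, diff[:, :, None])[:, :, 0]
            maha = np.einsum("mi,mi->m", w, w)
            logdet = np.log(chols[:, 0, 0] * chols[:, 1, 1])
            dens = np.exp(-0.5 * maha - logdet) / (2 * np.pi)
            mc = dens.mean()
            exact = math.exp(cs.predictive_logpdf(x))
            assert abs(mc - exact) / exact < 0.02

    def test_gaussian_limit_large_n(self, rng):
        """With many observations the Student-t predictive approaches the
        Gaussian with matched mean and covariance."""
        prior = NIWHyperparams(np.zeros(2), 1.0, 5.0, np.eye(2))
        cs = niw_posterior(prior, rng.normal(size=(4000, 2)))
        df = cs.nu_n - 2 + 1
        scale = cs.lambda_n * (cs.kappa_n + 1) / (cs.kappa_n * df)
        for x in rng.normal(size=(5, 2)):
            g = multivariate_normal.logpdf(x, cs.mu_n, scale)
            assert abs(cs.predictive_logpdf(x) - g) < 1e-3


# ---------------------------------------------------------------------------
# sampler

class TestGibbsSweep:
    def test_single_point_single_cluster(self, default_prior):
        X = np.array([[0.1, 0.2, 0.3]])
        state = GibbsState.init(X, default_prior, 1.0,
                                np.random.default_rng(0), mode="single")
        gibbs_sweep(state, X, default_prior)
        assert state.k_plus == 1
        state.check(1)

    def test_counts_stay_consistent(self, default_prior, rng):
        X = rng.normal(size=(40, 3))
        state = GibbsState.init(X, default_prior, 1.0,
                                np.random.default_rng(1), mode="single")
        for _ in range(5):
            gibbs_sweep(state, X, default_prior)
            state.check(40)
            assert np.array_equal(np.unique(state.assignments),
                                  np.arange(state.k_plus))

    def test_two_point_split_probability_closed_form(self, default_prior):
        """One sweep over two points starting together: the probability that
        they end in distinct clusters has a closed form built from the CRP
        weights and the Student-t predictives."""
        X = np.array([[0.0, 0.0, 0.0], [2.5, -1.0, 0.5]])
        alpha = 0.8
        lone = ClusterStats(default_prior, X[0:1])
        prior_pred = ClusterStats(default_prior)
        # after point 0 is replaced, point 1 always faces the {x0} cluster
        log_new = math.log(alpha) + prior_pred.predictive_logpdf(X[1])
        log_join = math.log(1) + lone.predictive_logpdf(X[1])
        m = max(log_new, log_join)
        p_split = math.exp(log_new - m) / (
            math.exp(log_new - m) + math.exp(log_join - m))
        reps, splits = 4000, 0
        for r in range(reps):
            state = GibbsState.init(X, default_prior, alpha,
                                    np.random.default_rng(r), mode="single")
            gibbs_sweep(state, X, default_prior)
            splits += state.k_plus == 2
        se = math.sqrt(p_split * (1 - p_split) / reps)
        assert abs(splits / reps - p_split) < 4 * se

    def test_far_separated_points_split(self, default_prior):
        """Two points many prior scales apart occupy distinct clusters."""
        X = np.array([[0.0, 0.0, 0.0], [50.0, 50.0, 50.0]])
        splits = 0
        for r in range(200):
            state = GibbsState.init(X, default_prior, 1.0,
                                    np.random.default_rng(r), mode="single")
            gibbs_sweep(state, X, default_prior)
            gibbs_sweep(state, X, default_prior)
            splits += state.k_plus == 2
        assert splits >= 198

    def test_matches_enumerated_posterior(self):
        """Long-run partition frequencies match the exactly enumerated
        collapsed posterior over all partitions of four points."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 2)) * 1.5
        prior = NIWHyperparams(np.zeros(2), 0.5, 4.0, 0.5 * np.eye(2))
        alpha = 1.3

        def all_partitions(items):
            if len(items) == 1:
                yield [items]
                return
            first, rest = items[0], items[1:]
            for smaller in all_partitions(rest):
                for i, sub in enumerate(smaller):
                    yield smaller[:i] + [[first] + sub] + smaller[i + 1:]
                yield [[first]] + smaller

        def key_of(groups):
            return "|".join(",".join(map(str, sorted(g)))
                            for g in sorted(map(sorted, groups)))

        exact = {}
        for parts in all_partitions(list(range(4))):
            lab = np.empty(4, int)
            for j, p in enumerate(parts):
                lab[p] = j
            st_ = GibbsState(lab, [ClusterStats(prior, X[np.array(p)])
                                   for p in parts], alpha,
                             np.random.default_rng(0))
            exact[key_of(parts)] = log_joint(st_, X, prior)
        mx = max(exact.values())
        z = sum(math.exp(v - mx) for v in exact.values())
        exact = {k: math.exp(v - mx) / z for k, v in exact.items()}

        state = GibbsState.init(X, prior, alpha, np.random.default_rng(3),
                                mode="single")
        counts = Counter()
        sweeps = 20000
        for _ in range(sweeps):
            gibbs_sweep(state, X, prior)
            groups = {}
            for i, c in enumerate(state.assignments):
                groups.setdefault(int(c), []).append(i)
            counts[key_of(groups.values())] += 1
        for k, p in exact.items():
            assert abs(counts.get(k, 0) / sweeps - p) < 0.02


class TestSampleAlpha:
    def test_disabled_is_identity(self, default_prior):
        state = GibbsState(np.zeros(3, int),
                           [ClusterStats(default_prior, np.zeros((3, 3)))],
                           0.7, np.random.default_rng(0))
        assert sample_alpha(state, resample=False) == 0.7

    def test_always_positive(self, default_prior, rng):
        X = rng.normal(size=(20, 3))
        state = GibbsState.init(X, default_prior, 1.0,
                                np.random.default_rng(5), mode="per-point")
        for _ in range(200):
            state.alpha = sample_alpha(state, 3.0, 2.0, n_total=20)
            assert state.alpha > 0

    def test_long_run_mean_bracketed(self, default_prior):
        """With K and N held fixed the stationary mean of alpha lies between
        the Gamma(3,2) prior mean and the CRP maximum-likelihood value."""
        k_plus, n = 5, 100
        lab = np.repeat(np.arange(5), 20)
        pts = np.repeat(np.eye(5, 3), 20, axis=0)
        state = GibbsState(lab, [ClusterStats(default_prior,
                                              pts[lab == j])
                                 for j in range(5)],
                           1.0, np.random.default_rng(11))
        draws = []
        for _ in range(4000):
            state.alpha = sample_alpha(state, 3.0, 2.0, n_total=n)
            draws.append(state.alpha)
        mean = float(np.mean(draws[500:]))
        prior_mean = 3.0 / 2.0
        mle = minimize_scalar(
            lambda a: -(k_plus * math.log(a) + gammaln(a) - gammaln(a + n)),
            bounds=(1e-3, 50), method="bounded").x
        lo, hi = sorted([prior_mean, float(mle)])
        assert lo - 0.15 < mean < hi + 0.15


class TestLogJoint:
    def test_single_point_is_marginal(self, default_prior):
        X = np.array([[0.3, -0.1, 0.2]])
        state = GibbsState(np.zeros(1, int),
                           [ClusterStats(default_prior, X)], 1.7,
                           np.random.default_rng(0))
        # the 1-partition has CRP probability 1 regardless of alpha
        cs = ClusterStats(default_prior)
        assert log_joint(state, X, default_prior) == pytest.approx(
            cs.predictive_logpdf(X[0]))

    def test_relabel_invariance(self, default_prior, rng):
        X = rng.normal(size=(12, 3))
        lab = np.array([0, 1, 2] * 4)
        perm = np.array([2, 0, 1])
        s1 = GibbsState(lab, [ClusterStats(default_prior, X[lab == j])
                              for j in range(3)], 0.9,
                        np.random.default_rng(0))
        lab2 = perm[lab]
        s2 = GibbsState(lab2, [ClusterStats(default_prior, X[lab2 == j])
                               for j in range(3)], 0.9,
                        np.random.default_rng(0))
        assert log_joint(s1, X, default_prior) == pytest.approx(
            log_joint(s2, X, default_prior))

    def test_chain_rule_over_all_orderings(self):
        """The joint of a fixed partition equals the sequential CRP x
        Student-t predictive product for every presentation order
        (exchangeability), using scipy's density as the oracle."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(5, 2))
        prior = NIWHyperparams(np.array([0.1, 0.3]), 0.6, 4.5,
                               np.array([[0.8, 0.1], [0.1, 1.1]]))
        alpha = 0.9
        lab = np.array([0, 1, 0, 1, 0])
        state = GibbsState(lab, [ClusterStats(prior, X[lab == j])
                                 for j in range(2)], alpha,
                           np.random.default_rng(0))
        joint = log_joint(state, X, prior)

        def t_params(members):
            n = len(members)
            if n == 0:
                kn, nun, mun, lam = (prior.kappa0, prior.nu0, prior.mu0,
                                     prior.lambda0)
            else:
                pts = X[members]
                xbar = pts.mean(axis=0)
                kn = prior.kappa0 + n
                nun = prior.nu0 + n
                mun = (prior.kappa0 * prior.mu0 + n * xbar) / kn
                dev = (xbar - prior.mu0)[:, None]
                sc = (pts - xbar).T @ (pts - xbar)
                lam = (prior.lambda0 + sc
                       + prior.kappa0 * n / kn * (dev @ dev.T))
            df = nun - 2 + 1
            return mun, lam * (kn + 1) / (kn * df), df

        for order in itertools.permutations(range(5)):
            total = 0.0
            members = {0: [], 1: []}
            placed = 0
            for i in order:
                c = lab[i]
                n_c = len(members[c])
                crp = (n_c if n_c > 0 else alpha) / (alpha + placed)
                mu, scale, df = t_params(members[c])
                total += math.log(crp) + multivariate_t.logpdf(
                    X[i], mu, scale, df)
                members[c].append(i)
                placed += 1
            assert total == pytest.approx(joint, abs=1e-9)


class TestFit:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 3))
        t1 = fit(X, sweeps=10, seed=99)
        t2 = fit(X, sweeps=10, seed=99)
        assert t1.log_joint == t2.log_joint
        assert all(np.array_equal(a, b)
                   for a, b in zip(t1.assignments, t2.assignments))

    def test_single_point_single_sweep(self):
        t = fit(np.array([[0.0, 0.0, 0.0]]), sweeps=1, seed=0)
        assert len(t) == 1
        assert t.map_k == 1

    def test_recovers_separated_clusters(self):
        """Parameter recovery on well-separated synthetic components."""
        from motionclust.features import FeatureMatrix
        from motionclust.recognition import type2_hit_accuracy
        from motionclust.synthetic import gen_separated_clusters
        accs, ks = [], []
        for seed in range(3):
            fm, lab = gen_separated_clusters(3, 14.0, 100, seed=seed)
            fms = FeatureMatrix.from_array(fm.X, standardize=True)
            tr = fit(fms, sweeps=60, seed=seed + 500)
            accs.append(type2_hit_accuracy(tr.map_assignments, lab))
            ks.append(tr.map_k)
        assert np.mean(accs) > 95.0
        # occasional transient singletons allowed; the bulk structure is 3
        assert all(3 <= k <= 4 for k in ks)

    def test_invalid_sweeps(self):
        with pytest.raises(ValueError):
            fit(np.zeros((2, 3)), sweeps=0)

    def test_trace_stabilization_bounds(self, rng):
        X = rng.normal(size=(20, 3))
        t = fit(X, sweeps=30, seed=1)
        s = t.stabilization_sweep()
        assert 0 < s <= 30
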