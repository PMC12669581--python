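"""Latent class engine: closed forms, oracles, EM properties, selection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

from protlca import (
    CategoricalDesign,
    LatentClassAnalysis,
    LatentProfileAnalysis,
    assign,
    blrt,
    fit_lca,
    relative_entropy,
    select_k,
    simulate_from_model,
)


def _two_class_model(pi1=0.5, hi=0.9, J=6):
    """A well-separated two-class model over J binary items."""
    m = LatentClassAnalysis(n_classes=2)
    m.weights_ = np.array([pi1, 1 - pi1])
    rho = np.zeros((J, 2, 2))
    rho[:, 0, 0] = hi
    rho[:, 1, 0] = 1 - hi
    rho[:, 0, 1] = 1 - hi
    rho[:, 1, 1] = hi
    m.rho_ = rho
    m.n_categories_ = np.full(J, 2)
    return m


class TestFitClosedForms:
    def test_one_class_is_marginal_frequencies(self):
        codes = np.array([[1, 1], [1, 2], [2, 1], [1, 1]])
        m = fit_lca(codes, n_classes=1)
        assert np.allclose(m.weights_, [1.0])
        assert np.allclose(m.rho_[0, :, 0], [0.75, 0.25])
        assert np.allclose(m.rho_[1, :, 0], [0.75, 0.25])
        expected_ll = 2 * (3 * np.log(0.75) + 1 * np.log(0.25))
        assert m.loglik_ == pytest.approx(expected_ll, abs=1e-8)

    def test_two_pure_patterns(self):
        codes = np.array([[1, 1], [1, 1], [2, 2], [2, 2]])
        m = fit_lca(codes, n_classes=2, n_starts=10, seed=0)
        assert np.allclose(np.sort(m.weights_), [0.5, 0.5], atol=1e-6)
        # each class concentrates on one pattern (up to the probability floor)
        top = m.rho_.max(axis=1)  # (J, K)
        assert np.all(top >= 1 - 2e-6)
        assert m.loglik_ == pytest.approx(4 * np.log(0.5), abs=1e-4)

    def test_k_exceeding_patterns_raises(self):
        codes = np.array([[1, 1], [1, 1], [2, 2]])
        with pytest.raises(ValueError, match="distinct response patterns"):
            fit_lca(codes, n_classes=3)


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_matches_direct_maximization(self, seed):
        """EM loglik equals multistart numerical ML on tiny 2-item designs."""
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, 3, size=(12, 2))
        if np.unique(codes, axis=0).shape[0] < 2:
            codes[0] = [1, 1]
            codes[1] = [2, 2]
        m = fit_lca(codes, n_classes=2, n_starts=20, seed=0, tol=1e-10, max_iter=2000)

        Y0 = codes - 1

        def negll(theta):
            pi1 = 1 / (1 + np.exp(-theta[0]))
            pi = np.array([pi1, 1 - pi1])
            p = 1 / (1 + np.exp(-theta[1:5]))  # P(cat 1) per item x class
            ll = 0.0
            for y in Y0:
                comp = np.log(pi).copy()
                for j in range(2):
                    for k in range(2):
                        pj = p[2 * j + k]
                        comp[k] += np.log(pj if y[j] == 0 else 1 - pj)
                ll += logsumexp(comp)
            return -ll

        best = np.inf
        for s in range(30):
            x0 = np.random.default_rng(1000 + s).normal(size=5)
            res = minimize(negll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        assert m.loglik_ == pytest.approx(-best, abs=1e-4)


class TestPosterior:
    def test_single_class_posterior_is_one(self):
        codes = np.array([[1], [2], [1]])
        m = fit_lca(codes, 1)
        assert np.allclose(m.predict_proba(codes), 1.0)

    def test_symmetric_ambiguous_pattern(self):
        m = _two_class_model(pi1=0.5, hi=0.9, J=2)
        # pattern (1, 2) is equidistant from both classes
        tau = m.predict_proba(np.array([[1, 2]]))
        assert np.allclose(tau, [[0.5, 0.5]], atol=1e-12)

    def test_worked_posterior_oracle(self):
        """tau for pattern (1,1) from direct arithmetic on pi and rho."""
        m = LatentClassAnalysis(n_classes=2)
        m.weights_ = np.array([0.6, 0.4])
        rho = np.zeros((2, 2, 2))
        rho[0, :, 0] = [0.8, 0.2]
        rho[0, :, 1] = [0.3, 0.7]
        rho[1, :, 0] = [0.7, 0.3]
        rho[1, :, 1] = [0.1, 0.9]
        m.rho_ = rho
        m.n_categories_ = np.array([2, 2])
        tau = m.predict_proba(np.array([[1, 1]]))[0]
        a = 0.6 * 0.8 * 0.7
        b = 0.4 * 0.3 * 0.1
        assert tau[0] == pytest.approx(a / (a + b), abs=1e-12)

    def test_unseen_category_raises(self):
        m = _two_class_model(J=2)
        with pytest.raises(ValueError, match="unseen"):
            m.predict_proba(np.array([[1, 3]]))


class TestRelativeEntropy:
    def test_endpoints(self):
        one_hot = np.eye(3)[np.array([0, 1, 2, 0])]
        assert relative_entropy(one_hot) == pytest.approx(1.0)
        uniform = np.full((5, 4), 0.25)
        assert relative_entropy(uniform) == pytest.approx(0.0, abs=1e-12)
        assert relative_entropy(np.ones((4, 1)), 1) == 1.0

    def test_worked_value(self):
        tau = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert relative_entropy(tau) == pytest.approx(0.4045, abs=1e-4)


class TestAssign:
    def test_tie_breaks_to_lowest_class(self):
        labels, p = assign(np.array([[0.5, 0.5], [0.2, 0.8]]))
        assert labels.tolist() == [1, 2]
        assert p.tolist() == [0.5, 0.8]

    def test_one_hot_recovery(self):
        tau = np.eye(4)[np.array([2, 0, 3])]
        labels, p = assign(tau)
        assert labels.tolist() == [3, 1, 4]
        assert np.all(p == 1.0)


class TestSimulateFromModel:
    def test_pattern_frequencies_converge(self):
        m = _two_class_model(pi1=0.7, hi=0.8, J=2)
        d = simulate_from_model(m, 20000, seed=5)
        # P(pattern (1,1)) = 0.7*0.64 + 0.3*0.04
        emp = np.mean((d.codes[:, 0] == 1) & (d.codes[:, 1] == 1))
        assert emp == pytest.approx(0.7 * 0.64 + 0.3 * 0.04, abs=0.01)

    def test_deterministic_per_seed(self):
        m = _two_class_model()
        d1 = simulate_from_model(m, 100, seed=3)
        d2 = simulate_from_model(m, 100, seed=3)
        assert np.array_equal(d1.codes, d2.codes)

    def test_roundtrip_parameter_recovery(self):
        m = _two_class_model(pi1=0.6, hi=0.85, J=8)
        d = simulate_from_model(m, 4000, seed=9)
        fit = fit_lca(d, 2, n_starts=10, seed=1)
        assert np.allclose(np.sort(fit.weights_), [0.4, 0.6], atol=0.03)
        assert np.abs(fit.rho_ - m.rho_).mean() < 0.03


class TestEMProperties:
    def test_monotone_loglik_over_random_fits(self):
        """EM never decreases the loglik across >= 100 random fits."""
        count = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            codes = rng.integers(1, 4, size=(40, 4))
            for K in (2, 3):
                m = fit_lca(codes, K, n_starts=2, seed=seed, max_iter=200)
                diffs = np.diff(m.loglik_trace_)
                assert np.all(diffs >= -1e-8)
                count += 1
        assert count >= 100

    def test_canonical_ordering_and_simplex_invariants(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(1, 4, size=(150, 5))
        m = fit_lca(codes, 3, n_starts=5, seed=0)
        assert np.all(np.diff(m.weights_) <= 1e-12)
        assert m.weights_.sum() == pytest.approx(1.0, abs=1e-10)
        for j in range(5):
            assert np.allclose(m.rho_[j, :, :].sum(axis=0), 1.0, atol=1e-10)
        tau = m.predict_proba(codes)
        assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-10)
        assert m.bic_ == pytest.approx(
            -2 * m.loglik_ + m.n_params_ * np.log(150), abs=1e-8
        )

    def test_determinism(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(1, 3, size=(60, 4))
        m1 = fit_lca(codes, 2, n_starts=4, seed=42)
        m2 = fit_lca(codes, 2, n_starts=4, seed=42)
        assert np.array_equal(m1.weights_, m2.weights_)
        assert np.array_equal(m1.rho_, m2.rho_)


class TestBLRT:
    def test_extreme_rank_gives_minimal_p(self):
        """Crisp 2-class data: observed LR beats every bootstrap LR."""
        m = _two_class_model(pi1=0.5, hi=0.95, J=6)
        d = simulate_from_model(m, 400, seed=2)
        res = blrt(d, 1, n_bootstrap=9, n_starts=6, seed=0)
        assert res.p_value == pytest.approx(1 / 10)
        assert np.all(res.lr_bootstrap < res.lr_observed)

    def test_p_matches_rank_definition(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(1, 3, size=(80, 4))
        res = blrt(codes, 1, n_bootstrap=19, n_starts=4, seed=3)
        expected = (1 + np.sum(res.lr_bootstrap >= res.lr_observed)) / (res.n_bootstrap + 1)
        assert res.p_value == expected
        assert 0 < res.p_value <= 1

    def test_power_on_three_class_data(self):
        """BLRT of 2 vs 3 classes rejects decisively on crisp 3-class data."""
        rng = np.random.default_rng(5)
        pi = np.array([0.4, 0.35, 0.25])
        labels = rng.choice(3, size=400, p=pi)
        codes = np.empty((400, 6), dtype=np.int64)
        for j in range(6):
            hi = j % 3
            base = rng.integers(1, 3, size=400)
            strong = rng.random(400) < 0.85
            codes[:, j] = np.where((labels == hi) & strong, 3, base)
        res = blrt(codes, 2, n_bootstrap=99, n_starts=6, seed=1,
                   tol=1e-4, max_iter=200)
        assert res.p_value <= 0.01

    def test_select_k_boundary(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(1, 3, size=(50, 3))
        res = select_k(codes, k_max=1, n_bootstrap=5, n_starts=3, seed=0)
        assert res.n_classes == 1
        assert res.blrt_trace == []


class TestRecovery:
    def test_separated_classes_recovered(self):
        m = _two_class_model(pi1=0.65, hi=0.9, J=10)
        d = simulate_from_model(m, 1200, seed=6)
        fit = fit_lca(d, 2, n_starts=10, seed=0)
        assert np.allclose(fit.weights_, [0.65, 0.35], atol=0.05)
        # posterior assignment agrees with the Bayes-rule assignment of the truth
        bayes = m.predict(d)
        est = fit.predict(d)
        assert adjusted_rand_score(bayes, est) >= 0.9


class TestLPA:
    def test_two_blob_recovery(self, rng):
        X = np.vstack([
            rng.normal(0.0, 0.3, size=(200, 2)),
            rng.normal(3.0, 0.3, size=(100, 2)),
        ])
        m = LatentProfileAnalysis(n_classes=2, random_state=0).fit(X)
        assert np.allclose(sorted(m.means_[:, 0]), [0.0, 3.0], atol=0.1)
        assert m.weights_[0] == pytest.approx(2 / 3, abs=0.05)

    def test_single_component_moments(self, rng):
        X = rng.normal(1.5, 2.0, size=(500, 3))
        m = LatentProfileAnalysis(n_classes=1, random_state=0).fit(X)
        assert np.allclose(m.means_[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(m.covariances_[0], X.var(axis=0), atol=1e-4)

    def test_loglik_trace_monotone(self, rng):
        X = np.vstack([
            rng.normal(0, 1, size=(80, 2)),
            rng.normal(2, 1, size=(80, 2)),
        ])
        m = LatentProfileAnalysis(n_classes=2, n_starts=3, random_state=1).fit(X)
        assert np.all(np.diff(m.loglik_trace_) >= -1e-6)
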