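import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_stem_map
from fruitprod.covariates import build_design
from fruitprod.model_core import (
    BinomialModel,
    ModelParams,
    OrdinalModel,
    cumulative_category_probs,
    linear_predictor,
    ordinal_loglik_terms,
)


def _simple_design(n=20, seed=0, covariate_set="dbh"):
    trees = random_stem_map(np.random.default_rng(seed), n)
    return build_design(trees, None, covariate_set)


def _params_for(design, beta=None, eps=None, **kw):
    J, p = design.n_species, design.n_coef
    return ModelParams(
        beta=np.zeros((J, p)) if beta is None else np.asarray(beta, float),
        mu=np.zeros(p),
        Sigma=np.eye(p),
        eps=np.zeros(design.n_trees) if eps is None else eps,
        **kw,
    )


class TestCategoryProbs:
    def test_eta_zero_first_cut_gives_half(self):
        pi = cumulative_category_probs(0.0, [0.0, 1.0, 2.0])
        assert pi[0] == pytest.approx(0.5, abs=1e-15)

    def test_known_probability_vector(self):
        pi = cumulative_category_probs(0.0, [0.0, 1.0, 2.0])
        np.testing.assert_allclose(
            pi, [0.5, 0.23105858, 0.14973849, 0.11920292], atol=1e-7
        )
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_extreme_eta_concentrates_mass(self):
        hi = cumulative_category_probs(40.0, [0.0, 1.0, 2.0])
        lo = cumulative_category_probs(-40.0, [0.0, 1.0, 2.0])
        assert hi[-1] == pytest.approx(1.0, abs=1e-12)
        assert lo[0] == pytest.approx(1.0, abs=1e-12)

    def test_rejects_unordered_cuts(self):
        with pytest.raises(ValueError):
            cumulative_category_probs(0.0, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            cumulative_category_probs(0.0, [0.5, 1.0, 2.0])

    @given(
        st.floats(-30, 30),
        st.floats(0.1, 5),
        st.floats(0.1, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_sums_to_one_and_positive(self, eta, d1, d2):
        gamma = np.array([0.0, d1, d1 + d2])
        pi = cumulative_category_probs(eta, gamma)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pi >= 0).all()  # extreme eta underflows to exactly 0
        if abs(eta) < 20:
            assert (pi > 0).all()

    @given(st.floats(-10, 10), st.floats(0.5, 8))
    @settings(max_examples=100, deadline=None)
    def test_stochastic_ordering_in_eta(self, eta, bump):
        gamma = np.array([0.0, 1.0, 2.5])
        c_lo = np.cumsum(cumulative_category_probs(eta, gamma))
        c_hi = np.cumsum(cumulative_category_probs(eta + bump, gamma))
        assert np.all(c_hi <= c_lo + 1e-12)


class TestLikelihoods:
    def test_single_tree_eta_zero_is_log_half(self):
        d = _simple_design(n=1, covariate_set="intercept")
        p = _params_for(d)
        for status in (0, 1):
            m = BinomialModel(d, [status])
            assert m.loglik(p) == pytest.approx(np.log(0.5))

    def test_binomial_additivity(self):
        d = _simple_design(n=17)
        p = _params_for(d)
        m = BinomialModel(d, np.zeros(17, dtype=int))
        assert m.loglik(p) == pytest.approx(17 * np.log(0.5))

    def test_binomial_matches_per_record_product_oracle(self):
        rng = np.random.default_rng(2)
        d = _simple_design(n=30, seed=2)
        beta = rng.normal(0, 1, (d.n_species, d.n_coef))
        eps = rng.normal(0, 0.4, d.n_trees)
        p = _params_for(d, beta=beta, eps=eps)
        y = rng.integers(0, 2, d.n_trees)
        m = BinomialModel(d, y)
        eta = m.eta(p)
        from scipy.special import expit

        oracle = sum(
            np.log(expit(e)) if yi else np.log(1 - expit(e))
            for e, yi in zip(eta, y)
        )
        assert m.loglik(p) == pytest.approx(oracle, abs=1e-10)

    def test_ordinal_single_tree_category_one(self):
        d = _simple_design(n=1, covariate_set="intercept")
        p = _params_for(d, gamma=np.array([0.0, 1.0, 2.0]))
        m = OrdinalModel(d, [1], K=4)
        assert m.loglik(p) == pytest.approx(np.log(0.5))

    def test_ordinal_k2_equals_bernoulli(self):
        rng = np.random.default_rng(5)
        d = _simple_design(n=40, seed=5)
        beta = rng.normal(0, 1.5, (d.n_species, d.n_coef))
        eps = rng.normal(0, 0.5, d.n_trees)
        y = rng.integers(0, 2, d.n_trees)
        pb = _params_for(d, beta=beta, eps=eps)
        po = _params_for(d, beta=beta, eps=eps, gamma=np.array([0.0]))
        lb = BinomialModel(d, y).loglik(pb)
        lo = OrdinalModel(d, y + 1, K=2).loglik(po)
        assert lo == pytest.approx(lb, abs=1e-10)

    def test_ordinal_rejects_out_of_range_category(self):
        d = _simple_design(n=3)
        with pytest.raises(ValueError, match="1..3"):
            OrdinalModel(d, [1, 2, 4], K=3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        trees = random_stem_map(rng, 25)
        y = rng.integers(1, 5, 25)
        perm = rng.permutation(25)
        d1 = build_design(trees, None, "dbh")
        d2 = build_design(trees.iloc[perm].reset_index(drop=True), None,
                          "dbh")
        gamma = np.array([0.0, 1.0, 2.0])
        beta = rng.normal(0, 1, (d1.n_species, d1.n_coef))
        p1 = _params_for(d1, beta=beta, gamma=gamma)
        # species order is sorted, identical in both designs
        p2 = _params_for(d2, beta=beta, gamma=gamma)
        l1 = OrdinalModel(d1, y, K=4).loglik(p1)
        l2 = OrdinalModel(d2, y[perm], K=4).loglik(p2)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_loglik_terms_stable_at_extreme_eta(self):
        gamma = np.array([0.0, 1.0, 2.0])
        eta = np.array([-500.0, 500.0, 0.0])
        y = np.array([1, 4, 2])
        out = ordinal_loglik_terms(eta, y, gamma, 4)
        assert np.isfinite(out[:2]).all()
        assert out[0] == pytest.approx(0.0, abs=1e-12)  # certain category 1


class TestLinearPredictor:
    def test_zero_params_zero_eta(self):
        d = _simple_design(n=10)
        eta = linear_predictor(_params_for(d), d)
        np.testing.assert_allclose(eta, 0.0)

    def test_intercept_only_constant(self):
        d = _simple_design(n=12, covariate_set="intercept")
        beta = np.full((d.n_species, 1), 1.3)
        eta = linear_predictor(_params_for(d, beta=beta), d)
        np.testing.assert_allclose(eta, 1.3)

    def test_dbh_nci_matches_hand_dot_product(self):
        trees = random_stem_map(np.random.default_rng(7), 15)
        d = build_design(trees, None, "dbh+nci")
        rng = np.random.default_rng(1)
        beta = rng.normal(0, 1, (d.n_species, 3))
        alpha = np.abs(rng.normal(1, 0.2, d.n_species))
        nu = np.abs(rng.normal(1, 0.2, d.n_species))
        p = _params_for(d, beta=beta, alpha=alpha, nu=nu)
        eta = linear_predictor(p, d)
        from fruitprod.covariates import compute_nci

        nl = d.neighbors
        for i in range(d.n_trees):
            j = d.species_index[i]
            nb_dbh, nb_dist, _ = nl.for_tree(i)
            nci = compute_nci(nb_dbh, nb_dist, alpha[j], nu[j],
                              kernel="as_printed") / d.nci_scale
            hand = beta[j, 0] + beta[j, 1] * d.X[i, 1] + beta[j, 2] * nci
            assert eta[i] == pytest.approx(hand, abs=1e-10)


class TestPrior:
    def test_unit_gamma_crowding_prior_contribution(self):
        d = _simple_design(n=8, covariate_set="dbh+anci")
        m = BinomialModel(d, np.zeros(8, dtype=int), hierarchical=False,
                          random_effects=False)
        p1 = _params_for(d, alpha=np.ones(d.n_species),
                         nu=np.ones(d.n_species))
        base = m.log_prior(
            _params_for(d, alpha=np.full(d.n_species, 1e-12),
                        nu=np.full(d.n_species, 1e-12))
        )
        # Gamma(1,1) log-density at 1 is -1 per parameter
        got = m.log_prior(p1)
        expected_drop = 1.0 * 2 * d.n_species
        assert base - got == pytest.approx(expected_drop - 2e-12 * d.n_species,
                                           abs=1e-6)

    def test_beta_at_hyper_mean_reduces_to_normalizer(self):
        d = _simple_design(n=5)
        m = BinomialModel(d, np.zeros(5, dtype=int), random_effects=False)
        p = _params_for(d)
        p.mu = np.zeros(d.n_coef)
        p.Sigma = np.eye(d.n_coef)
        from scipy import stats

        mvn_part = d.n_species * stats.multivariate_normal.logpdf(
            np.zeros(d.n_coef), np.zeros(d.n_coef), np.eye(d.n_coef)
        )
        shifted = p.copy()
        shifted.beta = shifted.beta + 1.0
        diff = m.log_prior(p) - m.log_prior(shifted)
        quad = 0.5 * d.n_coef * d.n_species  # 0.5 * ||1||^2 per species
        hyper_shift = 0.0  # mu unchanged
        assert diff == pytest.approx(quad + hyper_shift, abs=1e-9)
        assert np.isfinite(mvn_part)

    def test_out_of_support_is_minus_inf(self):
        d = _simple_design(n=4)
        m = BinomialModel(d, np.zeros(4, dtype=int))
        p = _params_for(d)
        p.tau = -1.0
        assert m.log_prior(p) == -np.inf
        p = _params_for(d, gamma=None)
        p.Sigma = -np.eye(d.n_coef)
        assert m.log_prior(p) == -np.inf

    def test_unordered_gamma_rejected(self):
        d = _simple_design(n=4)
        m = OrdinalModel(d, [1, 2, 3, 4], K=4)
        p = _params_for(d, gamma=np.array([0.0, 2.0, 1.0]))
        assert m.log_prior(p) == -np.inf
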