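"""DirectLiNGAM order search, adaptive-LASSO pruning, bootstrap, HSIC."""

import numpy as np
import pytest

from propriolearn.causal_discovery import (
    bootstrap_paths,
    check_exogenous_assumptions,
    direct_lingam,
    estimate_causal_order,
    exhaustive_order_search,
    prune_adaptive_lasso,
)
from propriolearn.hsic import hsic_test


def chain_data(rng, n=2000, b_am=-0.39, b_ml=0.70):
    """A -> M -> L with uniform disturbances, unit-variance columns."""
    u = lambda var: rng.uniform(-np.sqrt(3 * var), np.sqrt(3 * var), n)
    a = u(1.0)
    m = b_am * a + u(1.0 - b_am**2)
    l = b_ml * m + u(1.0 - b_ml**2)
    return np.column_stack([a, m, l])


class TestOrderSearch:
    def test_two_variable_direction(self, rng):
        x = rng.uniform(-1, 1, 5000)
        y = 1.5 * x + rng.uniform(-1, 1, 5000)
        order = estimate_causal_order(np.column_stack([x, y]))
        assert order == [0, 1]

    def test_three_variable_chain_recovery_rate(self):
        hits = 0
        for seed in range(40):
            x = chain_data(np.random.default_rng(seed))
            if estimate_causal_order(x) == [0, 1, 2]:
                hits += 1
        assert hits >= 38  # >= 95%

    def test_matches_exhaustive_oracle(self):
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = chain_data(rng, n=2000, b_am=0.6, b_ml=0.7)
            if estimate_causal_order(x) == exhaustive_order_search(x):
                agree += 1
        assert agree >= 19  # >= 95% agreement on well-separated models

    def test_label_equivariance_under_permutation(self, rng):
        x = chain_data(rng)
        perm = [2, 0, 1]
        order = estimate_causal_order(x)
        order_p = estimate_causal_order(x[:, perm])
        assert [perm[i] for i in order_p] == order

    def test_constant_column_rejected(self, rng):
        x = np.column_stack([rng.normal(size=100), np.ones(100)])
        with pytest.raises(ValueError):
            estimate_causal_order(x)


class TestPruning:
    def test_noiseless_coefficient_retained(self, rng):
        x = rng.uniform(-1, 1, 500)
        y = 2.0 * x
        b = prune_adaptive_lasso(np.column_stack([x, y + rng.normal(0, 1e-6, 500)]), [0, 1])
        assert b[1, 0] == pytest.approx(2.0, abs=1e-3)
        assert b[0, 1] == 0.0

    def test_true_zero_pruned_exactly(self):
        zeros = 0
        for seed in range(20):
            x = chain_data(np.random.default_rng(200 + seed))
            b = prune_adaptive_lasso(x, [0, 1, 2])
            if b[2, 0] == 0.0:
                zeros += 1
        assert zeros >= 15  # oracle property: A -> L pruned in most draws

    def test_first_variable_row_is_zero(self, rng):
        x = chain_data(rng)
        b = prune_adaptive_lasso(x, [0, 1, 2])
        assert np.all(b[0] == 0.0)
        # strictly lower-triangular under the order
        assert np.all(np.triu(b) == 0.0)


class TestDirectLingam:
    def test_default_model_recovery(self):
        x = chain_data(np.random.default_rng(1))
        g = direct_lingam(x, labels=["A", "M", "L"])
        assert [g.labels[i] for i in g.order] == ["A", "M", "L"]
        assert g.b[2, 1] == pytest.approx(0.70, abs=0.05)
        assert g.b[1, 0] == pytest.approx(-0.39, abs=0.05)
        assert g.b[2, 0] == 0.0
        assert list(g.exogenous) == [True, False, False]

    def test_gaussian_data_warns_but_returns(self, rng):
        x = rng.normal(size=(500, 3))
        with pytest.warns(UserWarning, match="non-Gaussianity"):
            g = direct_lingam(x)
        assert g.b.shape == (3, 3)

    def test_single_variable_trivial_graph(self, rng):
        g = direct_lingam(rng.uniform(size=(50, 1)))
        assert g.order == [0]
        assert not g.edges()

    def test_scale_equivariance(self, rng):
        x = chain_data(rng)
        g1 = direct_lingam(x)
        scaled = x.copy()
        scaled[:, 1] *= 37.0
        g2 = direct_lingam(scaled)
        assert g1.order == g2.order
        assert g1.b == pytest.approx(g2.b, abs=1e-8)


class TestBootstrap:
    def test_strong_chain_path_probability(self):
        x = chain_data(np.random.default_rng(3), n=5000)
        boot = bootstrap_paths(x, n_resamples=200, seed=0, labels=["A", "M", "L"])
        assert boot.path_probability[2, 1] >= 0.99  # M -> L
        assert boot.path_probability[1, 0] >= 0.90  # A -> M

    def test_single_resample_probabilities_binary(self, rng):
        x = chain_data(rng, n=500)
        boot = bootstrap_paths(x, n_resamples=1, seed=5)
        assert set(np.unique(boot.path_probability)) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, rng):
        x = chain_data(rng, n=300)
        b1 = bootstrap_paths(x, n_resamples=25, seed=9)
        b2 = bootstrap_paths(x, n_resamples=25, seed=9)
        assert b1.path_probability == pytest.approx(b2.path_probability)
        assert b1.graph_probability == b2.graph_probability

    def test_zero_resamples_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_paths(chain_data(rng, n=100), n_resamples=0, seed=1)


class TestHsic:
    def test_perfect_dependence_rejected(self, rng):
        x = rng.normal(size=100)
        stat, p = hsic_test(x, x)
        assert p < 0.001

    def test_constant_vector_no_dependence(self, rng):
        stat, p = hsic_test(rng.normal(size=50), np.zeros(50))
        assert (stat, p) == (0.0, 1.0)

    def test_nonlinear_dependence_detected(self, rng):
        x = rng.normal(size=200)
        y = x**2 + 0.1 * rng.normal(size=200)
        _, p = hsic_test(x, y)
        assert p < 0.01

    def test_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            hsic_test(rng.normal(size=10), rng.normal(size=10))


class TestAssumptionChecks:
    def test_well_specified_model_passes(self):
        ok = 0
        for seed in range(10):
            x = chain_data(np.random.default_rng(400 + seed), n=800)
            g = direct_lingam(x)
            report = check_exogenous_assumptions(g, x)
            if report.all_independent:
                ok += 1
        assert ok >= 9

    def test_uniform_disturbances_flagged_non_gaussian(self):
        x = chain_data(np.random.default_rng(7), n=800)
        g = direct_lingam(x)
        report = check_exogenous_assumptions(g, x)
        assert report.normality["non_gaussian"].sum() >= 2

    def test_gaussian_noise_type_one_error(self):
        """Shapiro-Wilk should accept normality ~95% of the time under the null."""
        from scipy.stats import shapiro

        rejections = 0
        n_rep = 200
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            if shapiro(rng.normal(size=200)).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_residuals_orthogonal_to_predecessors(self):
        x = chain_data(np.random.default_rng(11))
        g = direct_lingam(x)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        resid_l = z[:, 2] - z @ g.b[2]
        assert abs(np.corrcoef(resid_l, z[:, 1])[0, 1]) < 0.05
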