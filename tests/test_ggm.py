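"""Spearman input, graphical lasso, EBIC selection, covariate control."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from symptomnet import (ITEMS, SyntheticScenario, covariate_network,
                        delta_network, ebic_score, estimate_network,
                        glasso_fit, make_ground_truth, precision_to_partials,
                        select_network, simulate_responses, simulate_study,
                        spearman_matrix)
from symptomnet._glasso import glasso_objective
from symptomnet.ggm import (CorrelationMatrix, GgmConfig, ZeroVarianceError,
                            lambda_grid)


def _corr(values, labels=None, n=100):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"x{i}" for i in range(len(values)))
    return CorrelationMatrix(labels=tuple(labels), values=values, n_effective=n)


def _random_corr(rng, p):
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((p, p + 3))
    s = a @ a.T + 0.5 * p * np.eye(p)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def brute_force_glasso(S, lam, x0=None):
    """Independent penalized-likelihood optimizer over Cholesky factors.

    Maximizes log det(Theta) - tr(S Theta) - lam * sum_{i!=j}|Theta_ij| with
    Theta = L L' parameterized by the lower triangle of L (diagonal through
    exp to stay positive definite). Derivative-free Powell search handles the
    non-smooth penalty.
    """
    p = S.shape[0]
    il = np.tril_indices(p)

    def unpack(x):
        L = np.zeros((p, p))
        L[il] = x
        L[np.diag_indices(p)] = np.exp(np.diag(L))
        return L @ L.T

    def neg_obj(x):
        return -glasso_objective(unpack(x), S, lam)

    if x0 is None:
        L0 = np.linalg.cholesky(np.linalg.inv(S))
        x = L0[il].copy()
        x[np.cumsum(np.arange(1, p + 1)) - 1] = np.log(np.diag(L0))
    else:
        x = x0
    res = optimize.minimize(neg_obj, x, method="Powell",
                            options={"maxiter": 40_000, "xtol": 1e-10, "ftol": 1e-12})
    return unpack(res.x), -res.fun


class TestSpearman:
    def test_hand_example_matches_rank_then_correlate(self):
        df = pd.DataFrame({"a": [1, 2, 2, 3], "b": [0, 1, 1, 3]})
        corr = spearman_matrix(df, columns=("a", "b"))
        ra = stats.rankdata(df["a"])
        rb = stats.rankdata(df["b"])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert corr.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_perfectly_monotone_columns(self):
        df = pd.DataFrame({"a": [1, 2, 3, 5], "b": [2, 9, 30, 40]})
        corr = spearman_matrix(df, columns=("a", "b"))
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_reversal_negates(self):
        df = pd.DataFrame({"a": [1, 2, 2, 3], "b": [0, 1, 1, 3]})
        rev = df.assign(b=df["b"].values[::-1])
        c1 = spearman_matrix(df, columns=("a", "b")).values[0, 1]
        c2 = spearman_matrix(rev, columns=("a", "b")).values[0, 1]
        assert c2 == pytest.approx(-c1, abs=1e-12)

    def test_zero_variance_item_named(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [2, 2, 2, 2]})
        with pytest.raises(ZeroVarianceError, match="b"):
            spearman_matrix(df, columns=("a", "b"))

    def test_listwise_complete_rows_only(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, np.nan], "b": [1, 3, 2, 4, 0]})
        corr = spearman_matrix(df, columns=("a", "b"))
        assert corr.n_effective == 4


class TestGlasso:
    def test_identity_input_gives_identity(self):
        for lam in (0.0, 0.1, 0.9):
            theta = glasso_fit(_corr(np.eye(4)), lam)
            np.testing.assert_allclose(theta, np.eye(4), atol=1e-10)

    def test_screening_bound_empties_network(self):
        rng = np.random.default_rng(0)
        S = _random_corr(rng, 3)
        lam = np.abs(S - np.eye(3)).max()
        theta = glasso_fit(_corr(S), lam * 1.0001)
        off = theta - np.diag(np.diag(theta))
        assert np.abs(off).max() < 1e-10

    def test_zero_lambda_recovers_inverse_correlation(self):
        rng = np.random.default_rng(1)
        S = _random_corr(rng, 5)
        w = precision_to_partials(glasso_fit(_corr(S), 0.0))
        expected = precision_to_partials(np.linalg.inv(S))
        np.testing.assert_allclose(w, expected, atol=1e-6)

    def test_objective_at_least_brute_force_on_three_nodes(self):
        rng = np.random.default_rng(2)
        S = _random_corr(rng, 3)
        for lam in (0.01, 0.05, 0.2):
            theta = glasso_fit(_corr(S), lam)
            _, best = brute_force_glasso(S, lam)
            assert glasso_objective(theta, S, lam) >= best - 1e-5

    def test_agrees_with_independent_library_solver(self):
        sklearn = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(3)
        S = _random_corr(rng, 8)
        for lam in (0.02, 0.1, 0.3):
            ours = glasso_fit(_corr(S), lam)
            _, ref = sklearn.graphical_lasso(S, alpha=lam, tol=1e-8, max_iter=2000)
            np.testing.assert_allclose(ours, ref, atol=2e-4)

    def test_monotone_sparsity_along_path(self):
        rng = np.random.default_rng(4)
        S = _random_corr(rng, 10)
        grid = lambda_grid(_corr(S), GgmConfig(n_lambda=25))
        counts = []
        for lam in grid:  # descending lambda
            theta = glasso_fit(_corr(S), float(lam))
            off = theta[np.triu_indices(10, 1)]
            counts.append(int((np.abs(off) > 1e-8).sum()))
        assert all(b >= a - 0 for a, b in zip(counts, counts[1:])), counts


class TestPartials:
    def test_two_by_two_hand_value(self):
        w = precision_to_partials(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert w[0, 1] == pytest.approx(0.5)
        assert w[0, 0] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        S = _random_corr(rng, 4)
        theta = np.linalg.inv(S)
        np.testing.assert_allclose(precision_to_partials(theta),
                                   precision_to_partials(3.7 * theta), atol=1e-12)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partials(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestEbic:
    def test_identity_case_value(self):
        score = ebic_score(np.eye(16), _corr(np.eye(16)), n=100, gamma=0.5)
        assert score == pytest.approx(1600.0)

    def test_matches_manual_formula(self):
        rng = np.random.default_rng(6)
        S = _random_corr(rng, 6)
        theta = glasso_fit(_corr(S), 0.08)
        n, gamma, p = 250, 0.5, 6
        E = int((np.abs(theta[np.triu_indices(p, 1)]) > 1e-8).sum())
        loglik = np.linalg.slogdet(theta)[1] - np.sum(S * theta)
        manual = -n * loglik + E * np.log(n) + 4 * E * gamma * np.log(p)
        assert ebic_score(theta, _corr(S), n, gamma) == pytest.approx(manual)

    def test_gamma_zero_is_bic(self):
        rng = np.random.default_rng(7)
        S = _random_corr(rng, 5)
        theta = glasso_fit(_corr(S), 0.05)
        E = int((np.abs(theta[np.triu_indices(5, 1)]) > 1e-8).sum())
        loglik = np.linalg.slogdet(theta)[1] - np.sum(S * theta)
        assert ebic_score(theta, _corr(S), 100, 0.0) == pytest.approx(
            -100 * loglik + E * np.log(100))

    def test_sparser_model_wins_ties_by_penalty(self):
        # equal likelihood, E=5 vs E=6: the sparser model scores lower by
        # log n + 4*gamma*log p
        n, p, gamma = 500, 16, 0.5
        penalty = lambda E: E * np.log(n) + 4 * E * gamma * np.log(p)
        assert penalty(6) - penalty(5) == pytest.approx(np.log(n) + 2 * np.log(p))


class TestSelection:
    def test_sixteen_node_network_has_120_possible_edges(self, small_study, fast_ggm):
        table, _ = small_study
        net = estimate_network(table[table["group"] == "school"], fast_ggm)
        assert net.n_possible_edges == 120

    def test_single_lambda_grid_is_selected(self):
        rng = np.random.default_rng(8)
        S = _random_corr(rng, 5)
        cfg = GgmConfig(n_lambda=1)
        net = select_network(_corr(S, n=200), config=cfg)
        assert net.lambda_selected == pytest.approx(np.abs(S - np.eye(5)).max())

    def test_selection_is_deterministic(self, small_study, fast_ggm):
        table, _ = small_study
        school = table[table["group"] == "school"]
        n1 = estimate_network(school, fast_ggm)
        n2 = estimate_network(school, fast_ggm)
        assert np.array_equal(n1.weights, n2.weights)
        assert n1.lambda_selected == n2.lambda_selected

    def test_few_spurious_edges_under_independence(self, fast_ggm):
        """Specificity of EBIC selection on null (diagonal-truth) data."""
        sc = SyntheticScenario(n_per_group=1000, sparsity=0.0, n_bridge_edges=0,
                               group_shift=0.0)
        clean = 0
        reps = 20
        for rep in range(reps):
            sci = SyntheticScenario(**{**sc.__dict__, "seed": 100 + rep})
            model = make_ground_truth(sci)
            table = simulate_responses(model, sci, "school")
            net = estimate_network(table, fast_ggm)
            if net.edge_count <= 2:
                clean += 1
        assert clean >= 0.9 * reps


class TestCovariateControl:
    def test_null_covariates_barely_move_the_network(self, fast_ggm):
        sc = SyntheticScenario(n_per_group=2000, seed=23)
        table, _ = simulate_study(sc)
        school = table[table["group"] == "school"]
        plain = estimate_network(school, fast_ggm)
        adjusted = covariate_network(
            school, ["gender", "age", "residence", "income"], fast_ggm)
        delta = delta_network(plain, adjusted)
        assert delta.max_delta < 0.05

    def test_planted_covariate_gains_an_edge(self, fast_ggm):
        sc = SyntheticScenario(n_per_group=2000, seed=29)
        table, _ = simulate_study(sc)
        school = table[table["group"] == "school"].copy()
        rng = np.random.default_rng(31)
        noisy = school["P1"].to_numpy(dtype=float) + 0.6 * rng.standard_normal(len(school))
        school["shadow"] = noisy
        net = covariate_network(school, ["shadow"], fast_ggm)
        i, j = net.labels.index("P1"), net.labels.index("shadow")
        assert net.weights[i, j] > 0
        assert net.cluster_of["shadow"] == "covariate"

    def test_empty_covariate_list_matches_plain_network(self, small_study, fast_ggm):
        table, _ = small_study
        school = table[table["group"] == "school"]
        plain = estimate_network(school, fast_ggm)
        cov = covariate_network(school, [], fast_ggm)
        np.testing.assert_allclose(cov.weights, plain.weights, atol=1e-12)

    def test_constant_covariate_named(self, small_study):
        table, _ = small_study
        school = table[table["group"] == "school"].copy()
        school["flat"] = 1
        with pytest.raises(ValueError, match="flat"):
            covariate_network(school, ["flat"])

    def test_delta_of_network_with_itself_is_zero(self, small_study, fast_ggm):
        table, _ = small_study
        net = estimate_network(table[table["group"] == "school"], fast_ggm)
        delta = delta_network(net, net)
        assert delta.max_delta == 0.0
        assert delta.delta.max() == delta.max_delta
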