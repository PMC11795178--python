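"""Permutation network comparison: counting rule, FDR, enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from symptomnet import (NctConfig, SyntheticScenario, compare_networks,
                        fdr_adjust, make_ground_truth, permutation_null,
                        permutation_p, simulate_responses, simulate_study)
from symptomnet.centrality import global_strength, bridge_strength, nodal_strength
from symptomnet.ggm import GgmConfig
from symptomnet import estimate_network


class TestPermutationP:
    def test_direct_count_example(self):
        assert permutation_p(2.5, np.array([1, 2, 3, 4])) == 0.5

    def test_all_draws_at_least_observed_gives_one(self):
        assert permutation_p(0.5, np.full(5000, 0.7)) == 1.0

    def test_zero_observed_is_never_significant(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(100)
        assert permutation_p(0.0, draws) == 1.0

    def test_two_tailed_on_absolute_values(self):
        assert permutation_p(-2.5, np.array([-3, -1, 1, 3])) == 0.5

    def test_literal_zero_floor_warns(self):
        with pytest.warns(UserWarning, match="plus_one"):
            p = permutation_p(10.0, np.array([1.0, 2.0]))
        assert p == 0.0

    def test_plus_one_variant_never_zero(self):
        assert permutation_p(10.0, np.array([1.0, 2.0]), plus_one=True) \
            == pytest.approx(1 / 3)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_p(1.0, np.array([]))


class TestFdr:
    def test_step_up_hand_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(7)), np.ones(7))

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.2])), [0.2])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert (fdr_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


def _corr_diff_stat(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Tiny glasso-free statistic: |Pearson correlation difference| of x, y."""
    ca = np.corrcoef(a["x"], a["y"])[0, 1]
    cb = np.corrcoef(b["x"], b["y"])[0, 1]
    return abs(ca - cb)


class TestEnumerationOracle:
    def test_monte_carlo_matches_full_enumeration(self):
        """On 4-vs-4 rows the label shuffle has C(8,4) distinct splits; the
        sampled permutation p must approach the exact enumeration value."""
        rng = np.random.default_rng(7)
        pooled = pd.DataFrame(rng.standard_normal((8, 3)), columns=["x", "y", "z"])
        a, b = pooled.iloc[:4], pooled.iloc[4:]
        observed = _corr_diff_stat(a, b)

        exact_draws = []
        rows = range(8)
        for half in itertools.combinations(rows, 4):
            rest = [r for r in rows if r not in half]
            exact_draws.append(_corr_diff_stat(pooled.iloc[list(half)],
                                               pooled.iloc[rest]))
        p_exact = np.mean(np.abs(exact_draws) >= observed)

        null = permutation_null(a, b, _corr_diff_stat, n_perm=2000, seed=3)
        p_mc = permutation_p(observed, null[:, 0])
        assert p_mc == pytest.approx(p_exact, abs=0.05)


@pytest.fixture(scope="module")
def null_split():
    """Two same-truth groups (exchangeable under the null)."""
    sc = SyntheticScenario(n_per_group=500, group_shift=0.0, seed=71)
    model = make_ground_truth(sc)
    a = simulate_responses(model, sc, "school")
    b = simulate_responses(model, sc, "vacation")
    return a, b


class TestCompareNetworks:
    def test_observed_stats_match_separate_estimation(self, null_split, fast_ggm):
        """No leakage: observed differences equal those from the two
        independently estimated networks."""
        a, b = null_split
        res = compare_networks(a, b, fast_ggm, NctConfig(n_perm=20, seed=5))
        na, nb = estimate_network(a, fast_ggm), estimate_network(b, fast_ggm)
        assert res.observed_global_diff == pytest.approx(
            abs(global_strength(na) - global_strength(nb)), abs=1e-12)
        iu = np.triu_indices(16, 1)
        np.testing.assert_allclose(res.edge_diff,
                                   np.abs(na.weights[iu] - nb.weights[iu]),
                                   atol=1e-12)
        np.testing.assert_allclose(
            res.nodal_diff, np.abs(nodal_strength(na) - nodal_strength(nb)),
            atol=1e-12)
        np.testing.assert_allclose(
            res.bridge_diff, np.abs(bridge_strength(na) - bridge_strength(nb)),
            atol=1e-12)
        assert res.global_strengths == pytest.approx(
            (global_strength(na), global_strength(nb)))

    def test_reproducible_given_seed(self, null_split, fast_ggm):
        a, b = null_split
        r1 = compare_networks(a, b, fast_ggm, NctConfig(n_perm=30, seed=9))
        r2 = compare_networks(a, b, fast_ggm, NctConfig(n_perm=30, seed=9))
        assert r1.p_global == r2.p_global
        np.testing.assert_array_equal(r1.edge_p, r2.edge_p)

    def test_p_values_are_quantized_counts(self, null_split, fast_ggm):
        a, b = null_split
        res = compare_networks(a, b, fast_ggm, NctConfig(n_perm=40, seed=13))
        for p in (res.p_global, res.p_structure, *res.edge_p, *res.nodal_p):
            assert p == pytest.approx(round(p * 40) / 40, abs=1e-12)
        assert (res.edge_p_fdr >= res.edge_p - 1e-15).all()

    def test_planted_edge_difference_is_detected(self, fast_ggm):
        """Groups from truths differing by one strong bridge edge: that
        edge's unadjusted p should usually fall below 0.05."""
        hits = 0
        reps = 6
        for rep in range(reps):
            base = dict(n_per_group=800, sparsity=0.5, group_shift=0.0,
                        partial_range=(0.1, 0.25), seed=500 + rep)
            sc_edge = SyntheticScenario(**base, n_bridge_edges=1,
                                        bridge_anchor="P8",
                                        )
            sc_null = SyntheticScenario(**{**base, "n_bridge_edges": 0})
            m_edge = make_ground_truth(sc_edge)
            m_null = make_ground_truth(sc_null)
            a = simulate_responses(_strengthen_bridge(m_edge), sc_edge, "school")
            b = simulate_responses(m_null, sc_null, "vacation")
            res = compare_networks(a, b, fast_ggm, NctConfig(n_perm=250, seed=rep))
            iu = np.triu_indices(16, 1)
            truth_edges = np.abs(_strengthen_bridge(m_edge).true_partials[iu])
            cross = [k for k, (i, j) in enumerate(zip(*iu))
                     if m_edge.cluster_of[m_edge.node_labels[i]]
                     != m_edge.cluster_of[m_edge.node_labels[j]]]
            planted = cross[int(np.argmax(truth_edges[cross]))]
            if res.edge_p[planted] < 0.05:
                hits += 1
        assert hits >= reps - 1


def _strengthen_bridge(model):
    """Rescale the model so its single bridge edge has partial ~0.4."""
    import dataclasses
    from symptomnet.simulate import GroundTruthModel
    theta = model.precision_matrix.copy()
    bridge = np.abs(model.true_partials) * (model.bridge_truth()[:, None] > 0) \
        * (model.bridge_truth()[None, :] > 0)
    i, j = np.unravel_index(np.argmax(bridge), bridge.shape)
    target = 0.4
    cur = abs(model.true_partials[i, j])
    if cur >= target:
        return model
    scale = target / cur
    theta[i, j] *= scale
    theta[j, i] *= scale
    if np.linalg.eigvalsh(theta)[0] <= 0.02:
        return model
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    theta = theta * np.outer(d, d)
    dd = np.sqrt(np.diag(theta))
    partials = -theta / np.outer(dd, dd)
    np.fill_diagonal(partials, 0.0)
    return GroundTruthModel(
        node_labels=model.node_labels, cluster_of=model.cluster_of,
        precision_matrix=theta, true_partials=partials,
        thresholds=model.thresholds, group_shift=model.group_shift,
        covariate_effects=model.covariate_effects, seed=model.seed)
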