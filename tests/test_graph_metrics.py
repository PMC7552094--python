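"""Graph-metric unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hubdisrupt.connectome_io import Connectome
from hubdisrupt.graph_metrics import (
    betweenness_centrality, clustering_coefficient, compute_metric_table,
    global_efficiency, local_efficiency, nodal_strength, threshold_sparsity,
    transitivity)

import oracles


def _conn(w):
    w = np.asarray(w, dtype=float)
    return Connectome("s", w, [f"r{i}" for i in range(len(w))])


def _complete(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return _conn(w)


def _star(n_leaves, weights=None):
    n = n_leaves + 1
    w = np.zeros((n, n))
    for i in range(1, n):
        val = 1.0 if weights is None else weights[i - 1]
        w[0, i] = w[i, 0] = val
    return _conn(w)


def _path(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return _conn(w)


class TestThresholding:
    def test_retains_k_largest_edges(self, rng):
        n = 84
        w = oracles.random_weighted_graph(rng, n, density=0.6)
        tc = threshold_sparsity(_conn(w), 0.10)
        assert tc.retained_edge_count == 348  # floor(0.10 * 84*83/2)
        iu = np.triu_indices(n, k=1)
        kept = tc.weights[iu][tc.weights[iu] > 0]
        dropped_max = np.max(w[iu][tc.weights[iu] == 0])
        assert kept.min() >= dropped_max
        # surviving weights are a subset of the originals, unrescaled
        assert np.all((tc.weights == 0) | (tc.weights == w))

    def test_sparsity_one_is_identity(self, rng):
        w = oracles.random_weighted_graph(rng, 10)
        tc = threshold_sparsity(_conn(w), 1.0)
        np.testing.assert_array_equal(tc.weights, w)

    def test_idempotent(self, rng):
        w = oracles.random_weighted_graph(rng, 20, density=0.8)
        t1 = threshold_sparsity(_conn(w), 0.10)
        t2 = threshold_sparsity(t1, 0.10)
        np.testing.assert_array_equal(t1.weights, t2.weights)

    def test_keeps_single_largest_of_four_edges(self):
        w = np.zeros((5, 5))
        edges = [(0, 1, 2.0), (1, 2, 7.0), (2, 3, 1.0), (3, 4, 4.0)]
        for i, j, v in edges:
            w[i, j] = w[j, i] = v
        tc = threshold_sparsity(_conn(w), 0.10)  # K = floor(0.1*10) = 1
        assert tc.retained_edge_count == 1
        assert tc.weights[1, 2] == 7.0
        assert np.count_nonzero(tc.weights) == 2

    def test_tie_break_by_ascending_index(self):
        w = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (2, 3), (3, 4)]:
            w[i, j] = w[j, i] = 5.0
        tc = threshold_sparsity(_conn(w), 0.10)  # K = 1, all weights tied
        assert tc.weights[0, 1] == 5.0 and tc.retained_edge_count == 1

    def test_fewer_edges_than_k_keeps_all(self, caplog):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 3.0
        tc = threshold_sparsity(_conn(w), 0.5)  # K = 7 > 1 edge
        assert tc.retained_edge_count == 1

    @pytest.mark.parametrize("sparsity", [0.0, -0.1, 1.2])
    def test_rejects_bad_sparsity(self, sparsity, rng):
        w = oracles.random_weighted_graph(rng, 5)
        with pytest.raises(ValueError):
            threshold_sparsity(_conn(w), sparsity)

    def test_permutation_equivariance(self, rng):
        w = oracles.random_weighted_graph(rng, 12, density=0.7)
        perm = rng.permutation(12)
        tw = threshold_sparsity(_conn(w), 0.25).weights
        tw_perm = threshold_sparsity(_conn(w[np.ix_(perm, perm)]), 0.25).weights
        np.testing.assert_array_equal(tw_perm, tw[np.ix_(perm, perm)])


class TestAnalyticLimits:
    def test_complete_unit_graph(self):
        c = threshold_sparsity(_complete(5), 1.0)
        np.testing.assert_allclose(clustering_coefficient(c), 1.0)
        assert transitivity(c) == pytest.approx(1.0)
        assert global_efficiency(c) == pytest.approx(1.0)
        np.testing.assert_allclose(local_efficiency(c), 1.0)
        np.testing.assert_allclose(betweenness_centrality(c), 0.0)
        np.testing.assert_allclose(nodal_strength(c), 4.0)

    def test_star_graph(self, rng):
        c = threshold_sparsity(_star(5, weights=rng.uniform(1, 3, 5)), 1.0)
        np.testing.assert_allclose(clustering_coefficient(c), 0.0)
        assert transitivity(c) == 0.0
        # all 10 leaf pairs route through the center
        bc = betweenness_centrality(threshold_sparsity(_star(5), 1.0))
        assert bc[0] == pytest.approx(10.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_unit_path(self):
        c = threshold_sparsity(_path(3), 1.0)
        assert global_efficiency(c) == pytest.approx(5.0 / 6.0)
        bc = betweenness_centrality(c)
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])

    def test_triangle(self):
        c = threshold_sparsity(_complete(3), 1.0)
        np.testing.assert_allclose(clustering_coefficient(c), 1.0)
        assert transitivity(c) == pytest.approx(1.0)

    def test_isolated_node_strength_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 2.0
        w[1, 2] = w[2, 1] = 1.0
        c = threshold_sparsity(_conn(w), 1.0)
        assert nodal_strength(c)[3] == 0.0
        assert local_efficiency(c)[3] == 0.0
        assert local_efficiency(c)[0] == 0.0  # single neighbor


METRIC_ORACLE_PAIRS = [
    (nodal_strength, oracles.strength_oracle),
    (clustering_coefficient, oracles.clustering_oracle),
    (betweenness_centrality, oracles.betweenness_oracle),
    (local_efficiency, oracles.local_efficiency_oracle),
    (global_efficiency, oracles.global_efficiency_oracle),
    (transitivity, oracles.transitivity_oracle),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("func,oracle", METRIC_ORACLE_PAIRS,
                             ids=lambda f: getattr(f, "__name__", ""))
    def test_random_graphs_match_oracle(self, func, oracle, rng):
        for _ in range(15):
            n = int(rng.integers(4, 13))
            w = oracles.random_weighted_graph(rng, n,
                                              density=rng.uniform(0.3, 0.9))
            got = func(threshold_sparsity(_conn(w), 1.0))
            np.testing.assert_allclose(got, oracle(w), atol=1e-9)

    def test_betweenness_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            n = int(rng.integers(5, 11))
            w = oracles.random_weighted_graph(rng, n, density=0.6)
            g = nx.from_numpy_array(w)
            for u, v, d in g.edges(data=True):
                d["length"] = 1.0 / d["weight"]
            expected = nx.betweenness_centrality(g, weight="length",
                                                 normalized=False)
            got = betweenness_centrality(threshold_sparsity(_conn(w), 1.0))
            np.testing.assert_allclose(
                got, [expected[i] for i in range(n)], atol=1e-9)

    def test_clustering_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            n = int(rng.integers(5, 11))
            w = oracles.random_weighted_graph(rng, n, density=0.6)
            g = nx.from_numpy_array(w)
            expected = nx.clustering(g, weight="weight")
            got = clustering_coefficient(threshold_sparsity(_conn(w), 1.0))
            np.testing.assert_allclose(
                got, [expected[i] for i in range(n)], atol=1e-9)


class TestInvariances:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        w = oracles.random_weighted_graph(rng, n, density=0.6)
        perm = rng.permutation(n)
        wp = w[np.ix_(perm, perm)]
        for func in (nodal_strength, clustering_coefficient,
                     betweenness_centrality, local_efficiency):
            a = func(threshold_sparsity(_conn(w), 1.0))
            b = func(threshold_sparsity(_conn(wp), 1.0))
            np.testing.assert_allclose(b, a[perm], atol=1e-9)
        for func in (global_efficiency, transitivity):
            assert func(threshold_sparsity(_conn(wp), 1.0)) == \
                pytest.approx(func(threshold_sparsity(_conn(w), 1.0)))

    @given(st.floats(0.1, 50.0), st.integers(0, 2 ** 31 - 1))
    def test_weight_scaling(self, c, seed):
        rng = np.random.default_rng(seed)
        w = oracles.random_weighted_graph(rng, 8, density=0.7)
        t1 = threshold_sparsity(_conn(w), 1.0)
        t2 = threshold_sparsity(_conn(c * w), 1.0)
        # normalization / path-ordering invariant metrics
        np.testing.assert_allclose(clustering_coefficient(t2),
                                   clustering_coefficient(t1), atol=1e-9)
        assert transitivity(t2) == pytest.approx(transitivity(t1))
        np.testing.assert_allclose(betweenness_centrality(t2),
                                   betweenness_centrality(t1), atol=1e-8)
        # linearly scaling metrics
        np.testing.assert_allclose(nodal_strength(t2),
                                   c * nodal_strength(t1), rtol=1e-9)
        assert global_efficiency(t2) == \
            pytest.approx(c * global_efficiency(t1))


class TestMetricTable:
    def test_shapes_and_global_consistency(self, rng, make_connectome):
        cohort = [make_connectome(oracles.random_weighted_graph(rng, 20, 0.6),
                                  subject_id=f"s{i}") for i in range(5)]
        mt = compute_metric_table(cohort, sparsity=0.3)
        for name, df in mt.local.items():
            assert df.shape == (5, 20)
            assert np.isfinite(df.to_numpy()).all()
            assert (df.to_numpy() >= 0).all()
        np.testing.assert_allclose(
            mt.global_["global_clustering"].to_numpy(),
            mt.local["clustering"].to_numpy().mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(
            mt.global_["global_strength"].to_numpy(),
            mt.local["strength"].to_numpy().mean(axis=1), rtol=1e-12)

    def test_identical_subjects_identical_rows(self, rng, make_connectome):
        w = oracles.random_weighted_graph(rng, 12, 0.6)
        cohort = [make_connectome(w, subject_id=f"s{i}") for i in range(2)]
        mt = compute_metric_table(cohort, sparsity=0.2)
        for df in mt.local.values():
            np.testing.assert_array_equal(df.iloc[0].to_numpy(),
                                          df.iloc[1].to_numpy())

    def test_label_mismatch_rejected(self, rng):
        w = oracles.random_weighted_graph(rng, 5, 0.8)
        a = Connectome("a", w, [f"r{i}" for i in range(5)])
        b = Connectome("b", w, [f"q{i}" for i in range(5)])
        with pytest.raises(ValueError, match="labels"):
            compute_metric_table([a, b], 0.5)
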