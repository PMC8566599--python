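from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from funconn import (
    apply_weight_policy,
    distance_matrix,
    global_efficiency,
    modularity_q,
    modularity_signed,
    nodal_efficiency,
    nodal_local_efficiency,
    normalize_total_weight,
    weighted_degree,
)
from funconn.metrics import GraphMetricsExtractor, network_local_efficiency

from conftest import random_positive_connected_graph, random_signed_graph

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path by enumerating every simple path (edge length 1/w)."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = range(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            others = [k for k in nodes if k not in (i, j)]
            for r in range(len(others) + 1):
                for mid in permutations(others, r):
                    path = (i, *mid, j)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok:
                        d[i, j] = min(d[i, j], length)
    return d


def direct_signed_q(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Double-loop evaluation of signed modularity, no vectorization."""
    n = w.shape[0]
    wp = np.maximum(w, 0.0)
    wn = np.maximum(-w, 0.0)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(1), wn.sum(1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            if vp > 0:
                q += (wp[i, j] - gamma * sp[i] * sp[j] / vp) / vp
            if vn > 0:
                q -= (wn[i, j] - gamma * sn[i] * sn[j] / vn) / (vp + vn)
    return q


def all_partitions(n: int):
    """Every set partition of range(n), as label vectors (Bell(n) of them)."""
    if n == 1:
        yield [0]
        return
    for p in all_partitions(n - 1):
        for c in range(max(p) + 2):
            yield p + [c]


# ---------------------------------------------------------------------------
# weight policies and normalization
# ---------------------------------------------------------------------------


class TestWeightPolicy:
    def test_policies_on_signed_entry(self):
        w = np.array([[0, -0.3], [-0.3, 0.0]])
        assert apply_weight_policy(w, "absolute")[0, 1] == 0.3
        assert apply_weight_policy(w, "zero_negatives")[0, 1] == 0.0
        assert apply_weight_policy(w, "preserve")[0, 1] == -0.3

    def test_all_positive_matrix_is_fixed_point(self):
        rng = np.random.default_rng(0)
        w = np.abs(random_signed_graph(rng, 5))
        for policy in ("absolute", "zero_negatives", "preserve"):
            np.testing.assert_array_equal(apply_weight_policy(w, policy), w)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            apply_weight_policy(np.zeros((2, 2)), "clip")


class TestNormalization:
    def test_unique_edge_sum_becomes_one(self):
        rng = np.random.default_rng(1)
        w = np.abs(random_signed_graph(rng, 6))
        normed = normalize_total_weight(w)
        iu = np.triu_indices(6, k=1)
        assert np.abs(normed[iu]).sum() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        w = np.abs(random_signed_graph(rng, 5))
        np.testing.assert_allclose(
            normalize_total_weight(2.0 * w), normalize_total_weight(w), atol=1e-14
        )

    def test_uniform_complete_graph_closed_form(self):
        n = 105
        w = np.ones((n, n)) - np.eye(n)
        normed = normalize_total_weight(w)
        assert normed[0, 1] == pytest.approx(2.0 / (n * (n - 1)))

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_total_weight(np.zeros((3, 3)))


class TestDegree:
    def test_three_node_sums(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.3
        w[1, 2] = w[2, 1] = 0.2
        np.testing.assert_allclose(weighted_degree(w), [0.8, 0.7, 0.5])

    def test_isolated_node_and_k4(self):
        assert weighted_degree(np.zeros((3, 3)))[0] == 0.0
        k4 = 0.5 * (np.ones((4, 4)) - np.eye(4))
        np.testing.assert_allclose(weighted_degree(k4), 1.5)

    def test_negative_weights_rejected(self):
        w = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError, match="policy"):
            weighted_degree(w)


# ---------------------------------------------------------------------------
# distances and efficiencies
# ---------------------------------------------------------------------------


class TestDistances:
    def test_path_graph(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        d = distance_matrix(w)
        assert d[0, 2] == pytest.approx(2.0)

    def test_detour_beats_weak_direct_edge(self):
        w = np.array([[0, 1, 0.1], [1, 0, 1], [0.1, 1, 0.0]])
        assert distance_matrix(w)[0, 2] == pytest.approx(2.0)

    def test_dijkstra_equals_brute_force_on_random_graphs(self):
        """Oracle equivalence on every random graph with up to 6 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            w = np.abs(random_signed_graph(rng, n))
            np.testing.assert_allclose(
                distance_matrix(w), brute_force_distances(w), atol=1e-10
            )


class TestEfficiencies:
    def test_k4_and_path_nodal_efficiency(self):
        k4 = 0.5 * (np.ones((4, 4)) - np.eye(4))
        np.testing.assert_allclose(nodal_efficiency(k4), 0.5)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        np.testing.assert_allclose(nodal_efficiency(path), [0.75, 1.0, 0.75])

    def test_disconnected_graph_zero(self):
        np.testing.assert_array_equal(nodal_efficiency(np.zeros((4, 4))), 0.0)

    def test_triangle_local_efficiency(self):
        tri = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(nodal_local_efficiency(tri), 1.0)

    def test_star_graph_local_efficiency_zero(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        np.testing.assert_array_equal(nodal_local_efficiency(w), 0.0)

    def test_k4_symmetry(self):
        k4 = 0.7 * (np.ones((4, 4)) - np.eye(4))
        le = nodal_local_efficiency(k4)
        assert np.ptp(le) == pytest.approx(0.0, abs=1e-12)

    def test_global_is_mean_of_nodal(self):
        rng = np.random.default_rng(7)
        w = random_positive_connected_graph(rng, 6)
        assert global_efficiency(w) == pytest.approx(nodal_efficiency(w).mean())
        assert network_local_efficiency(w) == pytest.approx(
            nodal_local_efficiency(w).mean()
        )

    def test_uniform_complete_graph_closed_form(self):
        n = 105
        w = normalize_total_weight(np.ones((n, n)) - np.eye(n))
        assert global_efficiency(w) == pytest.approx(2.0 / (n * (n - 1)), rel=1e-12)

    def test_normalized_efficiency_scale_invariant(self):
        rng = np.random.default_rng(9)
        w = random_positive_connected_graph(rng, 8)
        e1 = global_efficiency(normalize_total_weight(w))
        e2 = global_efficiency(normalize_total_weight(4.2 * w))
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        w = random_positive_connected_graph(rng, 7)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        np.testing.assert_allclose(nodal_efficiency(wp), nodal_efficiency(w)[perm], atol=1e-12)
        np.testing.assert_allclose(
            nodal_local_efficiency(wp), nodal_local_efficiency(w)[perm], atol=1e-12
        )
        assert global_efficiency(wp) == pytest.approx(global_efficiency(w))


# ---------------------------------------------------------------------------
# signed modularity
# ---------------------------------------------------------------------------


class TestModularity:
    def test_two_cliques_match_exhaustive_oracle(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[a, b] = w[b, a] = 1.0
        labels, q = modularity_signed(w, seed=1, n_restarts=5)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        best = max(modularity_q(w, np.array(p)) for p in all_partitions(6))
        assert q == pytest.approx(best, abs=1e-12)

    def test_louvain_attains_exhaustive_optimum_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 7))
            w = random_signed_graph(rng, n)
            if np.maximum(w, 0).sum() == 0:
                continue
            _, q = modularity_signed(w, seed=3, n_restarts=20)
            best = max(modularity_q(w, np.array(p)) for p in all_partitions(n))
            assert q <= best + 1e-12
            assert q == pytest.approx(best, abs=1e-9)

    def test_q_evaluation_equals_direct_double_loop(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            w = random_signed_graph(rng, n)
            labels = rng.integers(0, 3, n)
            assert modularity_q(w, labels) == pytest.approx(
                direct_signed_q(w, labels), abs=1e-12
            )

    def test_within_module_negative_edge_decreases_q(self):
        w = np.zeros((6, 6))
        for a, b in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[a, b] = w[b, a] = 1.0
        labels = np.array([0, 0, 0, 1, 1, 1])
        q0 = modularity_q(w, labels)
        w_neg = w.copy()
        w_neg[0, 1] = w_neg[1, 0] = -0.5
        assert modularity_q(w_neg, labels) < q0

    def test_all_positive_reduces_to_newman_modularity(self):
        rng = np.random.default_rng(23)
        w = np.abs(random_signed_graph(rng, 6)) + 0.01
        np.fill_diagonal(w, 0.0)
        labels = np.array([0, 0, 1, 1, 2, 2])
        g = nx.from_numpy_array(w)
        communities = [set(np.flatnonzero(labels == c)) for c in range(3)]
        q_nx = nx.community.modularity(g, communities, weight="weight")
        assert modularity_q(w, labels) == pytest.approx(q_nx, abs=1e-10)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(29)
        w = random_signed_graph(rng, 10)
        r1 = modularity_signed(w, seed=5, n_restarts=8)
        r2 = modularity_signed(w, seed=5, n_restarts=8)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]

    def test_no_positive_weights_rejected(self):
        w = -(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError, match="positive"):
            modularity_signed(w)

    def test_partition_labels_contiguous(self):
        rng = np.random.default_rng(31)
        w = random_signed_graph(rng, 9)
        labels, _ = modularity_signed(w, seed=2, n_restarts=5)
        assert sorted(set(labels)) == list(range(labels.max() + 1))


class TestExtractor:
    def test_global_equals_mean_of_nodal_and_shapes(self, small_cohort):
        from funconn import FisherZConnectivity

        cohort, _ = small_cohort
        mats = FisherZConnectivity().fit_transform(cohort.series[:4])
        ext = GraphMetricsExtractor(n_restarts=4, seed=1)
        nodal, glob = ext.fit_transform(mats)
        assert nodal["weighted_degree"].shape == (4, 12)
        np.testing.assert_allclose(
            glob["global_efficiency"], nodal["nodal_efficiency"].mean(axis=1)
        )
        # degree is on unnormalized |z|
        np.testing.assert_allclose(
            nodal["weighted_degree"][0], np.abs(mats[0]).sum(axis=1)
        )

    def test_policy_variants_agree_on_positive_matrices(self):
        rng = np.random.default_rng(37)
        w = np.abs(random_signed_graph(rng, 8)) + 0.05
        np.fill_diagonal(w, 0.0)
        a = GraphMetricsExtractor(policy="absolute", n_restarts=3)
        z = GraphMetricsExtractor(policy="zero_negatives", n_restarts=3)
        na, ga = a.fit(w[None]).subject_metrics(w)
        nz, gz = z.fit(w[None]).subject_metrics(w)
        for key in na:
            np.testing.assert_array_equal(na[key], nz[key])
        assert ga == gz
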