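import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from glycoclust.data_io import AcaMatrix, ValidationError
from glycoclust.network import (
    CommunityPartition,
    FuzzyGraph,
    fuzzy_knn_graph,
    louvain,
    merge_graphs,
    modularity,
    smooth_knn_calibration,
)
from tests.conftest import small_matrix


def naive_fuzzy_graph(matrix: AcaMatrix, k: int) -> dict:
    """Independent all-pairs reference: cosine distances from the dot-product
    formula, kNN by full sort, sigma via brentq, t-conorm symmetrization."""
    X = matrix.values.to_numpy(dtype=float).T
    n = X.shape[0]
    norms = np.sqrt((X**2).sum(axis=1))
    directed = {}
    for i in range(n):
        d = np.array(
            [1.0 - X[i] @ X[j] / (norms[i] * norms[j]) if j != i else np.inf for j in range(n)]
        )
        nbrs = np.argsort(d, kind="stable")[:k]
        dk = d[nbrs]
        rho = dk[0]
        shifted = np.maximum(dk - rho, 0.0)
        target = np.log2(k)
        if np.all(shifted == 0):
            sigma = 1.0
        else:
            f = lambda s: np.exp(-shifted / s).sum() - target
            hi = 1.0
            while f(hi) < 0:
                hi *= 2
            sigma = brentq(f, 1e-14, hi, xtol=1e-14)
        for j, dj in zip(nbrs, dk):
            directed[(i, int(j))] = float(np.exp(-max(dj - rho, 0.0) / sigma))
    edges = {}
    ids = matrix.glycan_ids
    for (i, j), w in directed.items():
        key = tuple(sorted((ids[i], ids[j])))
        if key in edges:
            continue
        w_rev = directed.get((j, i), 0.0)
        edges[key] = w + w_rev - w * w_rev if (j, i) in directed else w
    return edges


class TestFuzzyKnn:
    def test_nearest_neighbor_membership_is_one(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.uniform(0.1, 1.0, size=5))
        rho, sigma = smooth_knn_calibration(d, k=5)
        assert rho == d[0]
        assert np.exp(-max(d[0] - rho, 0.0) / sigma) == 1.0
        # calibration hits the log2(k) target
        assert np.exp(-np.maximum(d - rho, 0) / sigma).sum() == pytest.approx(np.log2(5), abs=1e-5)

    def test_weights_in_unit_interval_and_no_isolated_nodes(self, default_data):
        g = fuzzy_knn_graph(default_data["aca_b"], k=5)
        w = np.array(list(g.edges.values()))
        assert ((w > 0) & (w <= 1)).all()
        touched = {n for e in g.edges for n in e}
        assert touched == set(g.nodes)

    def test_orthogonal_triplets_give_disconnected_triangles(self):
        """3 groups of duplicated glycans with orthogonal sample patterns and
        k=2 produce 3 disconnected triangles."""
        # glycan j in group g has a pattern supported on samples 2g, 2g+1 only,
        # so triplets are duplicated within groups and orthogonal across them
        arr = np.zeros((6, 9))
        for grp in range(3):
            for j in range(3):
                arr[2 * grp, 3 * grp + j] = 3.0
                arr[2 * grp + 1, 3 * grp + j] = 1.0
        m = AcaMatrix(
            cohort="A",
            values=pd.DataFrame(
                arr, index=[f"s{i}" for i in range(6)], columns=[f"g{j}" for j in range(9)]
            ),
        )
        g = fuzzy_knn_graph(m, k=2)
        expected = {
            tuple(sorted((f"g{3 * grp + a}", f"g{3 * grp + b}")))
            for grp in range(3)
            for a in range(3)
            for b in range(a + 1, 3)
        }
        assert set(g.edges) == expected
        assert all(w == pytest.approx(1.0) for w in g.edges.values())

    def test_matches_naive_all_pairs_reference(self):
        rng = np.random.default_rng(42)
        for n_gly in (10, 25, 50):
            m = small_matrix(rng, n_samples=40, n_glycans=n_gly)
            g = fuzzy_knn_graph(m, k=5)
            ref = naive_fuzzy_graph(m, k=5)
            assert set(g.edges) == set(ref)
            for key in ref:
                assert g.edges[key] == pytest.approx(ref[key], abs=1e-9)

    def test_constant_column_rejected_by_name(self):
        rng = np.random.default_rng(1)
        m = small_matrix(rng, n_glycans=8)
        m.values["G003"] = 7.0
        with pytest.raises(ValidationError, match="G003"):
            fuzzy_knn_graph(m)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(1)
        m = small_matrix(rng, n_glycans=6)
        with pytest.raises(ValidationError, match="k"):
            fuzzy_knn_graph(m, k=6)


class TestMerge:
    def _graph(self, edges):
        nodes = sorted({n for e in edges for n in e})
        return FuzzyGraph(nodes=nodes, edges=dict(edges))

    def test_shared_edge_rule_and_unique_kept(self):
        ga = self._graph({("a", "b"): 0.5, ("a", "c"): 0.3})
        gb = FuzzyGraph(nodes=["a", "b", "c"], edges={("a", "b"): 0.5})
        merged = merge_graphs(ga, gb)
        assert merged.edges[("a", "b")] == pytest.approx(0.75)
        assert merged.edges[("a", "c")] == 0.3
        assert merged.provenance[("a", "b")] == "both"
        assert merged.provenance[("a", "c")] == "cohort-A only"

    def test_absorbing_element(self):
        ga = self._graph({("a", "b"): 1.0})
        gb = FuzzyGraph(nodes=["a", "b"], edges={("a", "b"): 0.4})
        assert merge_graphs(ga, gb).edges[("a", "b")] == pytest.approx(1.0)

    def test_node_mismatch_lists_difference(self):
        ga = FuzzyGraph(nodes=["a", "b"], edges={("a", "b"): 0.5})
        gb = FuzzyGraph(nodes=["a", "c"], edges={("a", "c"): 0.5})
        with pytest.raises(ValidationError, match="symmetric difference"):
            merge_graphs(ga, gb)

    @settings(deadline=None, derandomize=True)
    @given(
        wa=st.floats(1e-6, 1.0),
        wb=st.floats(1e-6, 1.0),
        wc=st.floats(1e-6, 1.0),
    )
    def test_tconorm_algebra(self, wa, wb, wc):
        """Commutativity, associativity, monotonicity and bounds of the
        probabilistic t-conorm on shared-edge weights."""
        t = lambda a, b: a + b - a * b
        assert t(wa, wb) == pytest.approx(t(wb, wa))
        assert t(t(wa, wb), wc) == pytest.approx(t(wa, t(wb, wc)), rel=1e-9)
        assert t(wa, wb) >= max(wa, wb) - 1e-12
        assert 0.0 < t(wa, wb) <= 1.0 + 1e-12
        assert t(1.0, wb) == pytest.approx(1.0)


class TestModularityAndLouvain:
    def test_three_node_path_hand_formula(self):
        """Q on a weighted 3-node path checked against the hand-expanded
        Newman-Girvan sum."""
        g = FuzzyGraph(nodes=["a", "b", "c"], edges={("a", "b"): 0.8, ("b", "c"): 0.4})
        m = 1.2
        ka, kb, kc = 0.8, 1.2, 0.4
        # partition {a,b},{c}
        q_hand = (2 * 0.8) / (2 * m) - ((ka + kb) / (2 * m)) ** 2 - (kc / (2 * m)) ** 2
        assert modularity(g, {"a": 1, "b": 1, "c": 2}) == pytest.approx(q_hand, abs=1e-12)
        # all-singletons partition
        q_singl = -((ka / (2 * m)) ** 2 + (kb / (2 * m)) ** 2 + (kc / (2 * m)) ** 2)
        assert modularity(g, {"a": 1, "b": 2, "c": 3}) == pytest.approx(q_singl, abs=1e-12)

    def test_matches_networkx_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(5, 15))
            nodes = [f"n{i}" for i in range(n)]
            edges = {
                (nodes[i], nodes[j]): float(rng.uniform(0.05, 1))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            }
            if not edges:
                continue
            g = FuzzyGraph(nodes=nodes, edges=edges)
            assign = {nd: int(rng.integers(1, 4)) for nd in nodes}
            communities = [
                {nd for nd in nodes if assign[nd] == c} for c in sorted(set(assign.values()))
            ]
            q_nx = nx.algorithms.community.modularity(g.to_networkx(), communities, weight="weight")
            assert modularity(g, assign) == pytest.approx(q_nx, abs=1e-12)

    def test_singletons_on_clique_negative(self):
        nodes = list("abcd")
        edges = {(a, b): 1.0 for i, a in enumerate(nodes) for b in nodes[i + 1 :]}
        g = FuzzyGraph(nodes=nodes, edges=edges)
        assert modularity(g, {n: i + 1 for i, n in enumerate(nodes)}) < 0

    def test_two_cliques_with_weak_bridge(self):
        nodes = [f"n{i}" for i in range(8)]
        edges = {}
        for grp in (nodes[:4], nodes[4:]):
            for i, a in enumerate(grp):
                for b in grp[i + 1 :]:
                    edges[(a, b)] = 1.0
        edges[("n0", "n4")] = 0.01
        g = FuzzyGraph(nodes=nodes, edges=edges)
        part = louvain(g, seed=0)
        assert part.n_communities == 2
        assert len({part.assignment[n] for n in nodes[:4]}) == 1
        assert len({part.assignment[n] for n in nodes[4:]}) == 1
        assert part.modularity == pytest.approx(modularity(g, part), abs=1e-12)

    def test_empty_edge_set_warns_singletons(self):
        g = FuzzyGraph(nodes=["a", "b"], edges={})
        with pytest.warns(UserWarning):
            part = louvain(g, seed=0)
        assert part.n_communities == 2
        assert part.modularity == 0.0

    def test_missing_node_in_partition_rejected(self):
        g = FuzzyGraph(nodes=["a", "b"], edges={("a", "b"): 0.5})
        with pytest.raises(ValidationError, match="missing"):
            modularity(g, {"a": 1})

    def test_determinism_and_restarts(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i}" for i in range(20)]
        edges = {
            (nodes[i], nodes[j]): float(rng.uniform(0.1, 1))
            for i in range(20)
            for j in range(i + 1, 20)
            if rng.random() < 0.3
        }
        g = FuzzyGraph(nodes=nodes, edges=edges)
        p1 = louvain(g, seed=5)
        p2 = louvain(g, seed=5)
        assert p1.assignment == p2.assignment
        best = louvain(g, seed=5, n_restarts=5)
        assert best.modularity >= p1.modularity - 1e-12
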