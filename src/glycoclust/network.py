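"""Fuzzy k-NN glycan graphs, cross-cohort merging, and weighted Louvain.

Edge weights come from the fuzzy-simplicial-set construction used by
topological KNN methods: for each glycan (a point in sample space under the
cosine metric), distances to its k nearest neighbors are converted to
membership strengths

    w_ij = exp(-max(0, d_ij - rho_i) / sigma_i)

where rho_i is the distance to the nearest neighbor (local connectivity 1) and
sigma_i is calibrated by bisection so the memberships sum to log2(k). Directed
memberships are symmetrized with the probabilistic t-conorm a + b - a*b, which
also serves as the cross-cohort merge rule for shared edges ("the product
subtracted from the sum"); weights therefore stay in (0, 1] at every stage.

Community detection is the two-phase Louvain algorithm on the weighted graph:
seeded greedy local moving maximizing Newman-Girvan modularity, then graph
aggregation, repeated until the modularity gain of a full pass is negligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances

from glycoclust.data_io import AcaMatrix, ValidationError

Edge = tuple[str, str]

SMOOTH_KNN_TOL = 1e-5
SMOOTH_KNN_MAX_ITER = 64
LOUVAIN_MIN_GAIN = 1e-10


def _edge_key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class FuzzyGraph:
    """Weighted undirected glycan graph with weights in (0, 1].

    ``provenance`` flags each edge as coming from one cohort, both, or a
    single-graph construction.
    """

    nodes: list[str]
    edges: dict[Edge, float]
    provenance: dict[Edge, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge ({a}, {b}) references unknown node")
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"edge ({a}, {b}) weight {w} outside (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        for (a, b), w in self.edges.items():
            adj[a][b] = w
            adj[b][a] = w
        return adj

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w, provenance=self.provenance.get((a, b), ""))
        return g

    def to_edge_frame(self):
        import pandas as pd

        rows = [
            (a, b, w, self.provenance.get((a, b), ""))
            for (a, b), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "provenance"])


@dataclass
class CommunityPartition:
    """Glycan -> cluster assignment (labels 1..C) with the partition's modularity."""

    assignment: dict[str, int]
    modularity: float
    seed: int
    resolution: float
    pass_modularities: list[float] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, label: int) -> list[str]:
        return [n for n, c in self.assignment.items() if c == label]

    def labels(self) -> list[int]:
        return sorted(set(self.assignment.values()))


# ---------------------------------------------------------------------------
# Fuzzy simplicial-set KNN graph


def smooth_knn_calibration(
    dists: np.ndarray, k: int, tol: float = SMOOTH_KNN_TOL, max_iter: int = SMOOTH_KNN_MAX_ITER
) -> tuple[float, float]:
    """Solve (rho, sigma) for one point's ascending k-NN distance vector.

    rho = distance to the nearest neighbor (local connectivity 1); sigma is the
    bandwidth making Sum_j exp(-max(0, d_j - rho)/sigma) = log2(k), found by
    bisection with an expanding upper bracket.
    """
    rho = float(dists[0])
    target = np.log2(k)
    shifted = np.maximum(dists - rho, 0.0)
    if np.all(shifted == 0.0):
        return rho, 1.0  # all neighbors at rho: any sigma gives sum = k >= target

    def member_sum(sigma: float) -> float:
        return float(np.exp(-shifted / sigma).sum())

    lo, hi = 0.0, 1.0
    while member_sum(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    # plain bisection; 64 iterations shrink the bracket far below the 1e-5
    # tolerance contract, so no early exit is needed
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = member_sum(mid) if mid > 0 else float((shifted == 0).sum())
        if val < target:
            lo = mid
        else:
            hi = mid
    assert abs(member_sum(0.5 * (lo + hi)) - target) < tol or hi >= 1e12
    return rho, 0.5 * (lo + hi)


def fuzzy_knn_graph(
    matrix: AcaMatrix, k: int = 5, log1p: bool = False, provenance: str | None = None
) -> FuzzyGraph:
    """Fuzzy k-nearest-neighbor graph over glycans under the cosine metric.

    Each glycan is a point whose coordinates are its MFI values across the
    cohort's samples. Directed membership weights from the smooth-kNN
    calibration are symmetrized with a + b - a*b.
    """
    n_glycans = matrix.shape[1]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n_glycans:
        raise ValidationError(f"k={k} must be < number of glycans ({n_glycans})")
    if n_glycans < k + 2:
        raise ValidationError("need at least k + 2 glycans")

    X = matrix.values.to_numpy(dtype=float).T  # glycans x samples
    if log1p:
        X = np.log1p(X)
    variances = X.var(axis=1)
    constant = [matrix.glycan_ids[i] for i in np.nonzero(variances == 0.0)[0]]
    if constant:
        raise ValidationError(f"constant glycan column(s): {constant}")

    # all-pairs cosine distances; n_glycans is small (~200) so O(n^2) is fine
    dist = pairwise_distances(X, metric="cosine")
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1)[:, :k]
    knn_d = np.take_along_axis(dist, order, axis=1)

    ids = matrix.glycan_ids
    directed: dict[tuple[int, int], float] = {}
    for i in range(n_glycans):
        rho, sigma = smooth_knn_calibration(knn_d[i], k)
        for j_pos in range(k):
            j = int(order[i, j_pos])
            w = float(np.exp(-max(knn_d[i, j_pos] - rho, 0.0) / sigma)) if sigma > 0 else (
                1.0 if knn_d[i, j_pos] <= rho else 0.0
            )
            directed[(i, j)] = w

    tag = provenance if provenance is not None else "single-graph"
    edges: dict[Edge, float] = {}
    prov: dict[Edge, str] = {}
    for (i, j), w_ij in directed.items():
        if i > j:
            continue
        w_ji = directed.get((j, i), 0.0)
        w = w_ij + w_ji - w_ij * w_ji
        if w > 0.0:
            key = _edge_key(ids[i], ids[j])
            edges[key] = min(w, 1.0)
            prov[key] = tag
    for (i, j), w_ij in directed.items():
        if i < j or (j, i) in directed:
            continue  # pair already handled by the i < j loop
        if w_ij > 0.0:
            key = _edge_key(ids[i], ids[j])
            edges[key] = min(w_ij, 1.0)
            prov[key] = tag
    return FuzzyGraph(nodes=list(ids), edges=edges, provenance=prov)


def merge_graphs(ga: FuzzyGraph, gb: FuzzyGraph) -> FuzzyGraph:
    """Merge two cohort graphs: unique edges kept as is, shared edges combined
    with the probabilistic t-conorm w = wA + wB - wA*wB."""
    if set(ga.nodes) != set(gb.nodes):
        diff = sorted(set(ga.nodes) ^ set(gb.nodes))
        raise ValidationError(f"node sets differ; symmetric difference: {diff}")
    edges: dict[Edge, float] = {}
    prov: dict[Edge, str] = {}
    for key, wa in ga.edges.items():
        if key in gb.edges:
            wb = gb.edges[key]
            edges[key] = wa + wb - wa * wb
            prov[key] = "both"
        else:
            edges[key] = wa
            prov[key] = "cohort-A only"
    for key, wb in gb.edges.items():
        if key not in ga.edges:
            edges[key] = wb
            prov[key] = "cohort-B only"
    return FuzzyGraph(nodes=list(ga.nodes), edges=edges, provenance=prov)


# ---------------------------------------------------------------------------
# Modularity and Louvain


def modularity(graph: FuzzyGraph, partition: CommunityPartition | dict[str, int],
               resolution: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity
    Q = (1/2m) Sum_ij [w_ij - gamma * k_i k_j / (2m)] delta(c_i, c_j)."""
    assignment = partition.assignment if isinstance(partition, CommunityPartition) else partition
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing}")
    two_m = 2.0 * graph.total_weight()
    if two_m == 0.0:
        return 0.0
    degree: dict[str, float] = {n: 0.0 for n in graph.nodes}
    for (a, b), w in graph.edges.items():
        degree[a] += w
        degree[b] += w
    q = 0.0
    for (a, b), w in graph.edges.items():
        if assignment[a] == assignment[b]:
            q += 2.0 * w  # each undirected edge counts twice in the ij sum
    q /= two_m
    comm_degree: dict[int, float] = {}
    for n in graph.nodes:
        comm_degree[assignment[n]] = comm_degree.get(assignment[n], 0.0) + degree[n]
    q -= resolution * sum((d / two_m) ** 2 for d in comm_degree.values())
    return q


def _louvain_local_move(
    adj: list[dict[int, float]],
    self_w: list[float],
    comm: list[int],
    degree: list[float],
    two_m: float,
    resolution: float,
    rng: np.random.Generator,
) -> tuple[bool, list[int]]:
    """One phase of seeded greedy local moving. Mutates ``comm``; returns
    whether any node moved."""
    n = len(adj)
    sigma_tot = [0.0] * n  # indexed by community label
    for v in range(n):
        sigma_tot[comm[v]] += degree[v]
    improved = False
    moved = True
    while moved:
        moved = False
        for v in rng.permutation(n):
            v = int(v)
            c_old = comm[v]
            # weight from v to each neighboring community (v removed from its own)
            links: dict[int, float] = {}
            for u, w in adj[v].items():
                if u != v:
                    links[comm[u]] = links.get(comm[u], 0.0) + w
            sigma_tot[c_old] -= degree[v]
            stay_gain = links.get(c_old, 0.0) - resolution * degree[v] * sigma_tot[c_old] / two_m
            best_c, best_gain = c_old, stay_gain
            for c_cand in sorted(links):
                if c_cand == c_old:
                    continue
                gain = links[c_cand] - resolution * degree[v] * sigma_tot[c_cand] / two_m
                # strict improvement required to move; ties among movers break
                # toward the lowest community label via the sorted scan
                if gain > best_gain + 1e-15:
                    best_c, best_gain = c_cand, gain
            sigma_tot[best_c] += degree[v]
            if best_c != c_old:
                comm[v] = best_c
                moved = True
                improved = True
    return improved, comm


def louvain(
    graph: FuzzyGraph, seed: int = 0, resolution: float = 1.0, n_restarts: int = 1
) -> CommunityPartition:
    """Two-phase weighted Louvain community detection.

    Local moving visits nodes in a seeded shuffled order; ties in modularity
    gain break toward the lowest community label; passes of local moving and
    graph aggregation repeat until the total modularity gain of a pass is
    below 1e-10. Deterministic for a fixed seed. With ``n_restarts`` > 1 the
    algorithm reruns with derived seeds and returns the best-modularity
    partition (greedy local moving is order-dependent, so restarts can escape
    shallow local optima).
    """
    if n_restarts > 1:
        best = None
        for r in range(n_restarts):
            cand = louvain(graph, seed=seed + r, resolution=resolution, n_restarts=1)
            if best is None or cand.modularity > best.modularity:
                best = cand
        return best
    nodes = list(graph.nodes)
    if graph.n_edges == 0:
        warnings.warn("graph has no edges; every node becomes its own community")
        return CommunityPartition(
            assignment={n: i + 1 for i, n in enumerate(nodes)},
            modularity=0.0,
            seed=seed,
            resolution=resolution,
            pass_modularities=[0.0],
        )

    rng = np.random.default_rng(seed)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj: list[dict[int, float]] = [dict() for _ in range(n)]
    self_w = [0.0] * n
    for (a, b), w in graph.edges.items():
        ia, ib = index[a], index[b]
        adj[ia][ib] = adj[ia].get(ib, 0.0) + w
        adj[ib][ia] = adj[ib].get(ia, 0.0) + w
    two_m = 2.0 * graph.total_weight()

    # node -> community mapping composed across aggregation levels
    membership = list(range(n))
    pass_mods: list[float] = []

    def current_modularity(adj_l, self_l, comm_l, two_m_l) -> float:
        deg = [sum(adj_l[v].values()) + 2.0 * self_l[v] for v in range(len(adj_l))]
        q = 0.0
        sigma = {}
        internal = {}
        for v in range(len(adj_l)):
            c = comm_l[v]
            sigma[c] = sigma.get(c, 0.0) + deg[v]
            internal[c] = internal.get(c, 0.0) + 2.0 * self_l[v]
            for u, w in adj_l[v].items():
                if comm_l[u] == c:
                    internal[c] = internal[c] + w
        for c in sigma:
            q += internal[c] / two_m_l - resolution * (sigma[c] / two_m_l) ** 2
        return q

    adj_l, self_l = adj, self_w
    comm_l = list(range(len(adj_l)))
    prev_q = current_modularity(adj_l, self_l, comm_l, two_m)
    pass_mods.append(prev_q)

    while True:
        degree_l = [sum(adj_l[v].values()) + 2.0 * self_l[v] for v in range(len(adj_l))]
        comm_l = list(range(len(adj_l)))
        improved, comm_l = _louvain_local_move(
            adj_l, self_l, comm_l, degree_l, two_m, resolution, rng
        )
        q = current_modularity(adj_l, self_l, comm_l, two_m)
        pass_mods.append(q)
        if not improved or q - prev_q < LOUVAIN_MIN_GAIN:
            break
        prev_q = q
        # aggregate: communities become nodes
        labels = sorted(set(comm_l))
        relabel = {c: i for i, c in enumerate(labels)}
        comm_l = [relabel[c] for c in comm_l]
        membership = [comm_l[m] for m in membership]
        n_new = len(labels)
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        new_self = [0.0] * n_new
        for v in range(len(adj_l)):
            cv = comm_l[v]
            new_self[cv] += self_l[v]
            for u, w in adj_l[v].items():
                cu = comm_l[u]
                if cu == cv:
                    if u > v:
                        new_self[cv] += w
                else:
                    new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
        adj_l, self_l = new_adj, new_self

    final = [comm_l[m] for m in membership]
    # relabel deterministically: 1..C by decreasing size, ties by first node index
    sizes: dict[int, tuple[int, int]] = {}
    for i, c in enumerate(final):
        cnt, first = sizes.get(c, (0, i))
        sizes[c] = (cnt + 1, min(first, i))
    ordered = sorted(sizes, key=lambda c: (-sizes[c][0], sizes[c][1]))
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    assignment = {nodes[i]: relabel[final[i]] for i in range(n)}
    q_final = modularity(graph, assignment, resolution=resolution)
    return CommunityPartition(
        assignment=assignment,
        modularity=q_final,
        seed=seed,
        resolution=resolution,
        pass_modularities=pass_mods,
    )
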