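"""Stages 4-5 — pathway-crosstalk extraction and its significance.

A pathway-derived gene network (the union of per-pathway edge sets, each
edge found in at least one curated pathway) is searched for a connected
subnetwork of highly scored genes. The objective is the node-prize form of
the prize-collecting Steiner tree (PCST) problem: maximise
sum_{v in S} (score_v - theta) over connected S, where theta is a prize
threshold. It is solved heuristically by a metric-closure minimum spanning
tree over the above-threshold ("positive") nodes, expanded back to network
paths and greedily pruned. A bisection over score quantiles tunes theta to
a requested subnetwork size, and significance is assessed by a
degree-preserving node permutation test: scores are shuffled within degree
quantile bins and the full search re-run per permutation.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_EPS = 1e-9  # floor on edge lengths so shortest paths are well defined

__all__ = [
    "CrosstalkConfig",
    "CrosstalkResult",
    "build_pathway_network",
    "max_scoring_subnet",
    "subnet_score",
    "size_search",
    "permutation_test",
    "label_nodes",
]


@dataclass
class CrosstalkConfig:
    """Search and significance parameters.

    desired_nodes : requested subnetwork size (int), or "auto" to take the
        90th percentile of the score distribution as theta with no search.
    size_tolerance : acceptable deviation from desired_nodes (default +-5).
    n_permutations : B, number of degree-preserving permutations.
    degree_bins : quantile bins for the permutation null (0 = exact-degree
        groups, suitable for small networks).
    seed : RNG seed for the permutation test.
    """

    desired_nodes: int | str = 30
    size_tolerance: int = 5
    n_permutations: int = 100
    degree_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.desired_nodes != "auto" and int(self.desired_nodes) < 2:
            raise ValueError("desired_nodes must be >= 2 or 'auto'")
        if self.n_permutations < 19:
            raise ValueError("n_permutations must be >= 19")
        if self.degree_bins < 0:
            raise ValueError("degree_bins must be >= 0")


@dataclass
class CrosstalkResult:
    nodes: list[str]
    node_scores: dict[str, float]
    edges: list[tuple[str, str]]
    subnet_score: float
    theta_star: float
    pvalue_empirical: float | None = None
    pvalue_approx: float | None = None
    permutation_scores: list[float] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.nodes,
                "score": [self.node_scores[g] for g in self.nodes],
                "label": [self.labels.get(g, "") for g in self.nodes],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene_a", "gene_b"])


def build_pathway_network(
    pathway_edges: Mapping[str, Iterable[tuple[str, str]]]
) -> nx.Graph:
    """Union of per-pathway edge sets, with per-edge pathway provenance.

    Each merged edge carries the sorted tuple of pathway ids it occurs in.
    """
    g = nx.Graph()
    for pid in sorted(pathway_edges):
        for a, b in pathway_edges[pid]:
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["pathways"] = tuple(sorted(set(g[a][b]["pathways"]) | {pid}))
            else:
                g.add_edge(a, b, pathways=(pid,))
    if g.number_of_nodes() == 0:
        raise ValueError("pathway edge union is empty")
    return g


# ---------------------------------------------------------------------------
# PCST heuristic
# ---------------------------------------------------------------------------


def _adjacency(graph: nx.Graph) -> dict:
    return {v: list(graph.neighbors(v)) for v in graph.nodes}


def _dijkstra(adj, lengths, source, targets):
    """Single-source shortest paths to ``targets``; returns dist and parent."""
    dist = {source: 0.0}
    parent = {source: None}
    remaining = set(targets)
    remaining.discard(source)
    heap = [(0.0, source)]
    while heap and remaining:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        remaining.discard(u)
        for v in adj[u]:
            nd = d + lengths[(u, v) if u < v else (v, u)]
            if nd < dist.get(v, np.inf) - 1e-18:
                dist[v] = nd
                parent[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, parent


def subnet_score(nodes: Iterable[str], scores: Mapping[str, float], theta: float) -> float:
    """Net prize sum_{v in S} (score_v - theta) of a node set."""
    return float(sum(scores.get(v, 0.0) - theta for v in nodes))


def max_scoring_subnet(
    network: nx.Graph,
    scores: Mapping[str, float],
    theta: float,
) -> set[str]:
    """Heuristic maximum-scoring connected subnetwork at prize threshold theta.

    Steps: (1) positives P = {v : score_v > theta}; (2) metric closure over
    P with edge length max(theta - min(endpoint scores), eps); (3) minimum
    spanning tree of the closure, expanded back to network paths (Steiner
    nodes may enter here); (4) greedy pruning of negative-prize leaves.
    If P spans several network components the best-scoring component's
    solution is returned. Empty P yields the empty set.
    """
    positives = [v for v in network.nodes if scores.get(v, 0.0) > theta]
    if not positives:
        return set()

    adj = _adjacency(network)
    lengths = {}
    for u, v in network.edges:
        key = (u, v) if u < v else (v, u)
        lengths[key] = max(theta - min(scores.get(u, 0.0), scores.get(v, 0.0)), _EPS)

    # group positives by connected component
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(network)):
        for v in comp:
            comp_of[v] = ci
    groups: dict[int, list[str]] = {}
    for v in positives:
        groups.setdefault(comp_of[v], []).append(v)

    best: set[str] = set()
    best_score = -np.inf
    for group in groups.values():
        for tree in _candidate_trees(network, adj, lengths, sorted(group)):
            nodes = _prune(tree, scores, theta)
            nodes = _grow(adj, nodes, scores, theta)
            s = subnet_score(nodes, scores, theta)
            if s > best_score or (s == best_score and sorted(nodes) < sorted(best)):
                best, best_score = nodes, s
    return best


def _candidate_trees(network, adj, lengths, positives: list[str]):
    """Candidate Steiner trees spanning the positives of one component.

    One candidate is the classic metric-closure MST expanded back to
    network paths; the others are the shortest-path trees rooted at each
    positive (already computed for the closure, so essentially free).
    Pruning the best of these candidates recovers optima that any single
    tree topology would miss. Trees are plain adjacency dicts.
    """
    if len(positives) == 1:
        yield {positives[0]: set()}
        return
    targets = set(positives)
    dists, parents = {}, {}
    for p in positives:
        dists[p], parents[p] = _dijkstra(adj, lengths, p, targets)

    def _chain_tree(root, reachable) -> dict[str, set]:
        tree: dict[str, set] = {root: set()}
        for q in reachable:
            v = q
            tree.setdefault(v, set())
            while v != root:
                u = parents[root][v]
                tree.setdefault(u, set())
                tree[u].add(v)
                tree[v].add(u)
                v = u
        return tree

    # Prim's MST over the metric closure of the positives
    in_tree = {positives[0]}
    tree_edges: list[tuple[str, str]] = []
    closest = {
        q: (dists[positives[0]].get(q, np.inf), positives[0]) for q in positives[1:]
    }
    while len(in_tree) < len(positives):
        q = min(closest, key=lambda x: (closest[x][0], x))
        d, src = closest.pop(q)
        if not np.isfinite(d):  # positive unreachable within the component
            break
        tree_edges.append((src, q))
        in_tree.add(q)
        for other in closest:
            alt = dists[q].get(other, np.inf)
            if alt < closest[other][0]:
                closest[other] = (alt, q)

    mst_nodes: set[str] = set(in_tree)
    for src, q in tree_edges:
        v = q
        while v != src:
            mst_nodes.add(v)
            v = parents[src][v]
    yield _kruskal_tree(adj, lengths, mst_nodes)

    for root in positives:
        reach = [q for q in positives if q != root and np.isfinite(dists[root].get(q, np.inf))]
        if reach:
            yield _chain_tree(root, reach)


def _kruskal_tree(adj, lengths, nodes: set[str]) -> dict[str, set]:
    """Minimum spanning tree (by closure edge lengths) of an induced subgraph."""
    edges = sorted(
        (lengths[(u, v) if u < v else (v, u)], u, v)
        for u in nodes
        for v in adj[u]
        if v in nodes and u < v
    )
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    tree: dict[str, set] = {v: set() for v in nodes}
    for _, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree[u].add(v)
            tree[v].add(u)
    return tree


def _prune(tree: dict[str, set], scores, theta: float) -> set[str]:
    """Drop leaf branches of a Steiner tree whose net prize is negative.

    A post-order pass keeps, for every node, only child branches with
    positive net prize, then returns the best-valued subtree — the
    maximum-net-prize connected subtree of the given tree. A tree of
    all-positive nodes is never cut.
    """
    if len(tree) <= 1:
        return set(tree)
    root = min(tree)
    # iterative DFS for parent pointers and post-order
    parent: dict[str, str | None] = {root: None}
    order: list[str] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for c in tree[v]:
            if c not in parent:
                parent[c] = v
                stack.append(c)
    value = {}  # best net prize of a subtree rooted at v, keeping v
    kept_children: dict[str, list[str]] = {v: [] for v in tree}
    for v in reversed(order):  # children before parents
        val = scores.get(v, 0.0) - theta
        for c in tree[v]:
            if parent.get(c) == v and value[c] > 0:
                val += value[c]
                kept_children[v].append(c)
        value[v] = val
    best_root = max(sorted(value), key=lambda v: value[v])
    out: set[str] = set()
    stack = [best_root]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(kept_children[v])
    return out


def _grow(adj, nodes: set[str], scores, theta: float) -> set[str]:
    """Absorb adjacent above-threshold nodes: each strictly improves the
    net prize at zero connection cost, so this never hurts."""
    nodes = set(nodes)
    frontier = list(nodes)
    while frontier:
        v = frontier.pop()
        for u in adj[v]:
            if u not in nodes and scores.get(u, 0.0) > theta:
                nodes.add(u)
                frontier.append(u)
    return nodes


# ---------------------------------------------------------------------------
# Size-targeted search and permutation significance
# ---------------------------------------------------------------------------


def size_search(
    network: nx.Graph,
    scores: Mapping[str, float],
    cfg: CrosstalkConfig | None = None,
) -> CrosstalkResult:
    """Bisection over score quantiles for a subnetwork of the desired size.

    Larger theta gives fewer positives and hence smaller subnetworks; the
    search stops at an exact size hit or once the quantile grid is
    exhausted, returning the theta whose non-empty size is closest to
    ``desired_nodes`` (ties resolved toward the smaller theta, i.e. the
    larger subnetwork); ``size_tolerance`` states how much deviation the
    caller accepts when no grid theta admits the exact size.
    ``desired_nodes="auto"`` takes theta at the 90th score percentile with
    no search.
    """
    cfg = cfg or CrosstalkConfig()
    values = np.array([scores.get(v, 0.0) for v in network.nodes], dtype=float)

    if cfg.desired_nodes == "auto":
        theta = float(np.quantile(values, 0.9))
        nodes = max_scoring_subnet(network, scores, theta)
        return _finish(network, scores, nodes, theta)

    desired = int(cfg.desired_nodes)
    if desired > network.number_of_nodes():
        raise ValueError(
            f"desired_nodes={desired} exceeds network size {network.number_of_nodes()}"
        )
    grid = np.unique(values)
    grid = np.concatenate([[grid[0] - 1.0], grid])  # admit the all-positive end
    lo, hi = 0, len(grid) - 1
    # (empty?, |size gap|, theta, nodes); empty subnetworks rank last and
    # size ties resolve toward the smaller theta (the larger subnetwork)
    best: tuple[bool, int, float, set[str]] | None = None
    while lo <= hi:
        mid = (lo + hi) // 2
        theta = float(grid[mid])
        nodes = max_scoring_subnet(network, scores, theta)
        gap = abs(len(nodes) - desired)
        cand = (not nodes, gap, theta, nodes)
        if best is None or cand[:3] < best[:3]:
            best = cand
        if nodes and gap == 0:
            break
        if len(nodes) > desired:
            lo = mid + 1
        else:
            hi = mid - 1
    assert best is not None
    return _finish(network, scores, best[3], best[2])


def _finish(network, scores, nodes, theta) -> CrosstalkResult:
    ordered = sorted(nodes)
    sub = network.subgraph(nodes)
    edges = sorted(tuple(sorted(e)) for e in sub.edges)
    return CrosstalkResult(
        nodes=ordered,
        node_scores={v: float(scores.get(v, 0.0)) for v in ordered},
        edges=edges,
        subnet_score=subnet_score(nodes, scores, theta),
        theta_star=theta,
    )


def _degree_groups(network: nx.Graph, nodes: list[str], n_bins: int) -> list[np.ndarray]:
    degrees = np.array([network.degree(v) for v in nodes])
    idx = np.arange(len(nodes))
    if n_bins == 0:  # exact-degree matching
        return [idx[degrees == d] for d in np.unique(degrees)]
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, n_bins - 1)
    return [idx[bins == b] for b in np.unique(bins)]


def permutation_test(
    network: nx.Graph,
    scores: Mapping[str, float],
    observed: CrosstalkResult,
    cfg: CrosstalkConfig | None = None,
) -> tuple[float, float, list[float]]:
    """Degree-preserving permutation significance of the observed crosstalk.

    Node scores are shuffled within degree quantile bins and the full
    size search re-run with the same configuration per permutation.
    Empirical p = (1 + #{null >= observed}) / (B + 1), never below
    1/(B+1); an upper normal-tail approximation from the null mean/SD is
    reported alongside (NaN when the null is degenerate).
    """
    cfg = cfg or CrosstalkConfig()
    if not observed.nodes:
        raise ValueError("observed crosstalk is empty; nothing to test")
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(network.nodes)
    base = np.array([scores.get(v, 0.0) for v in nodes], dtype=float)
    groups = _degree_groups(network, nodes, cfg.degree_bins)

    null_scores: list[float] = []
    for _ in range(cfg.n_permutations):
        perm = base.copy()
        for g in groups:
            perm[g] = perm[rng.permutation(g)]
        shuffled = dict(zip(nodes, perm))
        res = size_search(network, shuffled, cfg)
        null_scores.append(res.subnet_score)

    null = np.array(null_scores)
    b = cfg.n_permutations
    p_emp = (1 + int((null >= observed.subnet_score).sum())) / (b + 1)
    sd = float(null.std(ddof=1)) if b > 1 else 0.0
    if sd > 0:
        p_approx = float(stats.norm.sf((observed.subnet_score - null.mean()) / sd))
    else:
        p_approx = float("nan")
    return p_emp, p_approx, null_scores


def label_nodes(result: CrosstalkResult, priority: pd.DataFrame) -> CrosstalkResult:
    """Attach 'rating(R)rank' labels (e.g. ``4.97®1``) from the priority table."""
    table = priority.set_index("gene")
    missing = [g for g in result.nodes if g not in table.index]
    if missing:
        raise KeyError(f"crosstalk gene(s) missing from the priority table: {missing}")
    result.labels = {
        g: f"{table.at[g, 'rating']:.2f}®{int(table.at[g, 'rank'])}"
        for g in result.nodes
    }
    return result
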