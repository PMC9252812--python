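import networkx as nx
import numpy as np
import pytest

from targetpri.fixtures import FixtureSpec, make_network_and_pathways, write_fixture_dir


def brute_force_subnet(graph, scores, theta):
    """Exhaustive maximum of sum(score - theta) over connected node subsets.

    Bitmask enumeration; independent of the heuristic solver. Returns
    (best score, best set) with the empty set scoring 0.
    """
    nodes = list(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adjmask = {v: sum(1 << idx[u] for u in graph.neighbors(v)) for v in nodes}
    n = len(nodes)
    best, best_set = 0.0, set()
    for mask in range(1, 1 << n):
        start = mask & -mask
        seen, frontier = start, start
        while frontier:
            nxt, m = 0, frontier
            while m:
                b = m & -m
                m ^= b
                nxt |= adjmask[nodes[b.bit_length() - 1]]
            frontier = nxt & mask & ~seen
            seen |= frontier
        if seen != mask:
            continue
        s = sum(scores[nodes[i]] - theta for i in range(n) if mask >> i & 1)
        if s > best:
            best = s
            best_set = {nodes[i] for i in range(n) if mask >> i & 1}
    return best, best_set


def random_connected_graph(rng, n_max=10, p=0.4):
    """Small random connected graph with string node names."""
    n = int(rng.integers(4, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    return nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes})


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A fully written toy input directory shared across CLI tests."""
    spec = FixtureSpec(n_genes=150, n_snps=30, n_pathways=6,
                       planted_module_size=8, seed=11)
    out = tmp_path_factory.mktemp("toydata")
    write_fixture_dir(spec, out)
    return out


@pytest.fixture(scope="session")
def pathway_network():
    """Pathway-derived network of a mid-sized fixture, with planted module."""
    from targetpri.crosstalk import build_pathway_network

    spec = FixtureSpec(n_genes=300, n_pathways=8, planted_module_size=10,
                       planted_effect=5.0, seed=3)
    net = make_network_and_pathways(spec)
    return spec, build_pathway_network(net["pathway_edges"]), net["planted"]
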