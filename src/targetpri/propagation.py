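"""Stage 2 — network propagation of core-gene scores.

Core genes seed a random walk with restart (RWR) over the protein
interaction network: p <- (1 - r) W^T p + r p0, with W the column-normalised
adjacency (binary by default, confidence-weighted optionally) and p0 the
seed weights normalised to sum 1. The fixed point assigns every network
gene an affinity quantifying its connectivity to the seeds; a highly
networked seed receives a high affinity itself, and unseeded (peripheral)
genes are ranked by network influence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import NetworkEdge

log = logging.getLogger(__name__)

__all__ = ["PropagationConfig", "build_graph", "rwr", "rank_genes"]


@dataclass
class PropagationConfig:
    """RWR parameters.

    restart : restart probability r in (0,1); default 0.75.
    tol : L1 convergence tolerance on successive iterates.
    max_iter : iteration cap; non-convergence raises.
    edge_weighting : 'unweighted' (binary adjacency at the chosen
        confidence tier) or 'confidence' (edges weighted by confidence).
    """

    restart: float = 0.75
    tol: float = 1e-10
    max_iter: int = 10_000
    edge_weighting: str = "unweighted"

    def __post_init__(self):
        if not (0.0 < self.restart < 1.0):
            raise ValueError("restart must be in (0,1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.edge_weighting not in ("unweighted", "confidence"):
            raise ValueError("edge_weighting must be 'unweighted' or 'confidence'")


def build_graph(edges: Iterable[NetworkEdge]) -> nx.Graph:
    """Build the undirected interaction graph from validated edges.

    Nodes exist only via edges, so isolated nodes are impossible and every
    column of the normalised adjacency is stochastic.
    """
    g = nx.Graph()
    for e in edges:
        prev = g.get_edge_data(e.gene_a, e.gene_b)
        if prev is None or e.confidence > prev["confidence"]:
            g.add_edge(e.gene_a, e.gene_b, confidence=e.confidence)
    if g.number_of_nodes() == 0:
        raise ValueError("empty edge set: cannot build an interaction graph")
    log.info("interaction graph: %d nodes, %d edges",
             g.number_of_nodes(), g.number_of_edges())
    return g


def _column_stochastic(graph: nx.Graph, nodes: Sequence[str], weighted: bool) -> sp.csr_matrix:
    weight = "confidence" if weighted else None
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=weight, format="csr")
    a = a.astype(float)
    colsum = np.asarray(a.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0  # unreachable: no isolated nodes by construction
    return (a @ sp.diags(1.0 / colsum)).tocsr()


def rwr(
    graph: nx.Graph,
    seeds: Mapping[str, float],
    cfg: PropagationConfig | None = None,
) -> pd.Series:
    """Random walk with restart from weighted seed genes.

    Seeds absent from the graph are dropped with a warning; if none remain
    the walk is undefined and an error is raised. The returned affinity
    vector is indexed by the sorted node list and sums to 1; nodes in
    components containing no seed receive affinity 0.
    """
    cfg = cfg or PropagationConfig()
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}

    dropped = [g for g in seeds if g not in index]
    if dropped:
        log.warning("%d seed gene(s) not in the interaction graph: %s",
                    len(dropped), ", ".join(sorted(dropped)[:10]))
    p0 = np.zeros(len(nodes))
    for g, w in seeds.items():
        if w < 0:
            raise ValueError(f"negative seed weight for {g}")
        if g in index:
            p0[index[g]] = w
    total = p0.sum()
    if total <= 0:
        raise ValueError("no seed with positive weight is present in the graph")
    p0 /= total

    w_mat = _column_stochastic(graph, nodes, cfg.edge_weighting == "confidence")
    r = cfg.restart
    p = p0.copy()
    for _ in range(cfg.max_iter):
        p_next = (1.0 - r) * (w_mat @ p) + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"RWR failed to converge in {cfg.max_iter} iterations "
            f"(final L1 residual {delta:.3e})"
        )
    return pd.Series(p, index=nodes, name="affinity")


def rank_genes(affinity: pd.Series, seeds: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Rank genes by descending affinity; ties broken by gene symbol.

    Seeds with positive weight are flagged as core genes.
    """
    seed_set = {g for g, w in (seeds or {}).items() if w > 0}
    df = pd.DataFrame({"gene": affinity.index, "affinity": affinity.values})
    df = df.sort_values(["affinity", "gene"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_seed"] = df["gene"].isin(seed_set)
    return df.reset_index(drop=True)
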