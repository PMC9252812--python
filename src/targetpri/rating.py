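"""Stage 3 — combining per-predictor affinities into a 0-5 priority rating.

One RWR run per evidence predictor gives a gene x predictor affinity
matrix. Affinities in each column are converted to empirical p-values by
descending rank (midranks for ties, divided by N+1 so p stays inside
(0,1)), the per-gene p-values are combined across predictors with Fisher's
method, and genes are ranked by the combined p. The rating is a linear
percentile rescale of the rank to (0,5]: the top gene scores exactly 5.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .propagation import PropagationConfig, rwr

log = logging.getLogger(__name__)

__all__ = [
    "assemble_matrix",
    "affinity_to_empirical_p",
    "fisher_combine",
    "rate",
]


def assemble_matrix(
    per_predictor_seeds: Mapping[str, Mapping[str, float]],
    graph: nx.Graph,
    cfg: PropagationConfig | None = None,
) -> pd.DataFrame:
    """Run one RWR per predictor and collect the affinity columns.

    Predictors whose seeds all fall outside the graph (or are all zero) are
    dropped with a warning; an error is raised only if nothing remains.
    Each retained column is a probability vector over the sorted node list.
    """
    cfg = cfg or PropagationConfig()
    columns: dict[str, pd.Series] = {}
    for predictor in sorted(per_predictor_seeds):
        seeds = {g: w for g, w in per_predictor_seeds[predictor].items() if w > 0}
        try:
            columns[predictor] = rwr(graph, seeds, cfg)
        except ValueError:
            log.warning("predictor %r has no seed in the graph; dropped", predictor)
    if not columns:
        raise ValueError("no predictor has any seed present in the graph")
    return pd.DataFrame(columns)


def affinity_to_empirical_p(column: pd.Series) -> pd.Series:
    """Empirical p-value of each gene's affinity within one predictor column.

    p_g = rank_desc(g) / (N + 1) with average ranks for ties; strictly
    inside (0,1), so Fisher's method is always defined.
    """
    ranks = stats.rankdata(-np.asarray(column, dtype=float), method="average")
    return pd.Series(ranks / (len(column) + 1), index=column.index, name=column.name)


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability test.

    X = -2 sum(ln p_j) referred to chi-square with 2k degrees of freedom;
    returns (X, upper-tail p). With a single p-value the combination is the
    identity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0,1]")
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(stats.chi2.sf(stat, df=2 * p.size))


def rate(
    matrix: pd.DataFrame,
    core_genes: set[str] | None = None,
    evidence_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the priority table from the affinity matrix.

    Genes are ranked by ascending Fisher-combined p (ties: larger Fisher
    statistic first, then symbol — bit-deterministic), and rated
    5 * (N - rank + 1) / N, equally spaced percentile scores in (0,5].
    ``core_genes`` flags genes with direct variant evidence; others are
    peripheral. ``evidence_counts`` (index gene, columns
    proximity/qtl/pchic) fills the evidence summary, defaulting to zero.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty affinity matrix")
    pmat = matrix.apply(affinity_to_empirical_p, axis=0)
    stats_p = pmat.apply(lambda row: fisher_combine(row.values), axis=1)
    fisher_stat = stats_p.map(lambda t: t[0]).astype(float)
    combined_p = stats_p.map(lambda t: t[1]).astype(float)

    df = pd.DataFrame(
        {
            "gene": matrix.index,
            "combined_p": combined_p.values,
            "fisher_stat": fisher_stat.values,
        }
    )
    df = df.sort_values(
        ["combined_p", "fisher_stat", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["rating"] = 5.0 * (n - df["rank"] + 1) / n

    core = core_genes or set()
    df["type"] = np.where(df["gene"].isin(core), "core", "peripheral")
    for source in ("proximity", "qtl", "pchic"):
        if evidence_counts is not None and source in evidence_counts.columns:
            df[source] = (
                df["gene"].map(evidence_counts[source]).fillna(0).astype(int)
            )
        else:
            df[source] = 0
    return df[
        ["gene", "rank", "rating", "combined_p", "fisher_stat", "type",
         "proximity", "qtl", "pchic"]
    ]
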