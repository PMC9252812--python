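"""Chained pipeline runs: each stage's result feeds the next.

These functions are the library form of the CLI subcommands; the
gene-level run is exactly the elementary stages chained (variant linking,
one propagation per evidence predictor, Fisher rating), and the
crosstalk-level run appends subnetwork extraction, pathway enrichment and
drug repurposing. The CLI adds only argument parsing and manifests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from . import annotate as _annotate
from . import crosstalk as _crosstalk
from . import io as _io
from . import linking as _linking
from . import propagation as _propagation
from . import rating as _rating

log = logging.getLogger(__name__)

__all__ = ["LinkResult", "PriorityResult", "CrosstalkRun", "run_link",
           "run_prioritize", "run_crosstalk", "run_full"]


@dataclass
class LinkResult:
    variants: list
    links: list
    per_predictor: dict[str, pd.Series]
    summary: list
    evidence: pd.DataFrame

    def core_gene_table(self) -> pd.DataFrame:
        rows = []
        for s in self.summary:
            row = {"gene": s.gene, "score": s.score, "n_snps": s.n_snps,
                   "proximity": s.evidence_counts.get("proximity", 0),
                   "qtl": s.evidence_counts.get("qtl", 0),
                   "pchic": s.evidence_counts.get("pchic", 0)}
            for pred, col in self.per_predictor.items():
                row[f"score_{pred}"] = float(col.get(s.gene, 0.0))
            rows.append(row)
        return pd.DataFrame(rows).sort_values("score", ascending=False,
                                              kind="mergesort").reset_index(drop=True)

    def evidence_count_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proximity": {s.gene: s.evidence_counts.get("proximity", 0) for s in self.summary},
                "qtl": {s.gene: s.evidence_counts.get("qtl", 0) for s in self.summary},
                "pchic": {s.gene: s.evidence_counts.get("pchic", 0) for s in self.summary},
            }
        )


@dataclass
class PriorityResult:
    link: LinkResult
    graph: nx.Graph
    matrix: pd.DataFrame
    priority: pd.DataFrame
    unrated: pd.DataFrame  # core genes absent from the interaction network


@dataclass
class CrosstalkRun:
    priority: PriorityResult
    network: nx.Graph
    result: _crosstalk.CrosstalkResult
    enrichment: pd.DataFrame
    repurposing_matrix: pd.DataFrame
    repurposing_detail: pd.DataFrame
    repurposing_unmatched: pd.DataFrame


def run_link(
    variants_path,
    ld_path,
    annotation_path,
    snp_positions_path,
    qtl_paths: Sequence = (),
    pchic_paths: Sequence = (),
    cfg: _linking.LinkConfig | None = None,
) -> LinkResult:
    """Stage 1 from files: filter + LD-expand variants, score core genes."""
    cfg = cfg or _linking.LinkConfig()
    variants = _io.read_variants(variants_path)
    ld = _io.read_ld_table(ld_path) if ld_path else None
    annotation = _io.read_gene_annotation(annotation_path)
    snp_pos = _io.read_snp_positions(snp_positions_path)
    qtl_tables = [_io.read_qtl_table(p) for p in qtl_paths]
    pchic_tables = [_io.read_pchic_table(p) for p in pchic_paths]

    kept = _linking.filter_and_expand(variants, ld, cfg)
    links = _linking.link_evidence(kept, annotation, snp_pos, qtl_tables,
                                   pchic_tables, cfg)
    per_predictor, summary = _linking.score_core_genes(links, kept, cfg)
    evidence = _linking.evidence_table(links, kept)
    return LinkResult(kept, links, per_predictor, summary, evidence)


def run_prioritize(
    edges_path,
    min_confidence: float = 0.7,
    prop_cfg: _propagation.PropagationConfig | None = None,
    link_result: LinkResult | None = None,
    **link_kwargs,
) -> PriorityResult:
    """Gene-level prioritisation: link -> per-predictor propagation -> rating."""
    prop_cfg = prop_cfg or _propagation.PropagationConfig()
    link = link_result or run_link(**link_kwargs)
    edges = _io.read_edge_list(edges_path, min_confidence=min_confidence)
    graph = _propagation.build_graph(edges)

    seeds = {pred: col.to_dict() for pred, col in link.per_predictor.items()}
    matrix = _rating.assemble_matrix(seeds, graph, prop_cfg)
    core = {s.gene for s in link.summary}
    priority = _rating.rate(matrix, core_genes=core,
                            evidence_counts=link.evidence_count_frame())
    unrated = pd.DataFrame(
        {"gene": sorted(core - set(graph.nodes))}
    )
    if len(unrated):
        log.info("%d core gene(s) absent from the interaction network", len(unrated))
    return PriorityResult(link, graph, matrix, priority, unrated)


def run_crosstalk(
    scores: Mapping[str, float],
    pathway_edges: Mapping[str, Sequence[tuple[str, str]]],
    cfg: _crosstalk.CrosstalkConfig | None = None,
    priority: pd.DataFrame | None = None,
) -> tuple[nx.Graph, _crosstalk.CrosstalkResult]:
    """Crosstalk extraction with permutation significance on pathway edges."""
    cfg = cfg or _crosstalk.CrosstalkConfig()
    network = _crosstalk.build_pathway_network(pathway_edges)
    result = _crosstalk.size_search(network, scores, cfg)
    if result.nodes:
        p_emp, p_approx, null = _crosstalk.permutation_test(network, scores, result, cfg)
        result.pvalue_empirical = p_emp
        result.pvalue_approx = p_approx
        result.permutation_scores = null
    if priority is not None and result.nodes:
        _crosstalk.label_nodes(result, priority)
    return network, result


def run_full(
    edges_path,
    pathway_edges_path,
    pathways_path,
    drugs_path,
    min_confidence: float = 0.7,
    top_fraction: float = 0.01,
    prop_cfg: _propagation.PropagationConfig | None = None,
    crosstalk_cfg: _crosstalk.CrosstalkConfig | None = None,
    **link_kwargs,
) -> CrosstalkRun:
    """Crosstalk-level prioritisation: gene rating + crosstalk + annotation.

    Crosstalk node scores are the 0-5 priority ratings (genes absent from
    the pathway network contribute nothing).
    """
    pri = run_prioritize(edges_path, min_confidence=min_confidence,
                         prop_cfg=prop_cfg, **link_kwargs)
    ratings = dict(zip(pri.priority["gene"], pri.priority["rating"]))
    pathway_edges = _io.read_pathway_edges(pathway_edges_path)
    network, result = run_crosstalk(ratings, pathway_edges,
                                    cfg=crosstalk_cfg, priority=pri.priority)

    pathways = _io.read_gmt(pathways_path)
    universe = set(pri.priority["gene"])
    selected = _annotate.select_top(pri.priority, top_fraction)
    enrichment = _annotate.enrich(selected, pathways, universe)

    drugs = _io.read_drug_table(drugs_path)
    matrix, detail, unmatched = _annotate.repurpose(result.nodes, drugs)
    return CrosstalkRun(pri, network, result, enrichment, matrix, detail, unmatched)
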