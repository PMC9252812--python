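"""Deterministic toy-scale generators for every pipeline input.

The generators emulate, at desk scale, the reference resources the real
pipeline consumes: a gene annotation and SNP map, GWAS summary statistics
with LD proxies, QTL and promoter-capture Hi-C evidence tables, a
STRING-like confidence-scored interaction network, KEGG-like pathway gene
sets with a pathway-derived edge list, and a ChEMBL-like drug table. A
planted mode inflates the evidence (or node scores) of one connected gene
module so that end-to-end signal recovery is testable.

Each generator draws from its own RNG stream derived from the master seed
by a fixed offset, so adding a generator never perturbs the others, and
outputs are byte-identical across runs for a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import DrugIndication, GeneAnnotation, NetworkEdge, PathwaySet, write_table

# fixed per-generator RNG stream offsets
_STREAM_GENOME = 11
_STREAM_EVIDENCE = 23
_STREAM_NETWORK = 37
_STREAM_SCORES = 53

_INDICATIONS = (
    "rheumatoid arthritis",
    "inflammatory bowel disease",
    "psoriasis",
    "asthma",
    "type 2 diabetes",
    "hypertension",
)

__all__ = [
    "FixtureSpec",
    "make_genome",
    "make_evidence",
    "make_network_and_pathways",
    "planted_node_scores",
    "write_fixture_dir",
]


@dataclass
class FixtureSpec:
    """Scale and signal parameters of one synthetic dataset.

    Defaults keep everything tiny (hundreds of genes) so a full pipeline
    run completes in seconds. ``planted_module_size`` > 0 with
    ``planted_effect`` > 1 plants a connected module with inflated signal;
    ``planted_effect`` = 1 leaves the data exactly null.
    """

    n_genes: int = 200
    n_snps: int = 40
    n_pathways: int = 8
    network_model: str = "barabasi_albert"
    planted_module_size: int = 0
    planted_effect: float = 5.0
    fraction_in_window: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.planted_module_size >= self.n_genes:
            raise ValueError("planted module must be smaller than the gene set")
        if self.network_model not in ("barabasi_albert", "erdos_renyi"):
            raise ValueError("network_model must be 'barabasi_albert' or 'erdos_renyi'")
        if not (0.0 <= self.fraction_in_window <= 1.0):
            raise ValueError("fraction_in_window must be in [0,1]")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _rng(spec: FixtureSpec, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, spec.seed])


# ---------------------------------------------------------------------------
# Genome: gene annotation + SNP positions
# ---------------------------------------------------------------------------


def make_genome(spec: FixtureSpec) -> tuple[list[GeneAnnotation], pd.DataFrame]:
    """Tile genes on synthetic chromosomes and place SNPs around them.

    A ``fraction_in_window`` share of SNPs lands within 50 kb of a gene
    body; the remainder sits on a gene-free chromosome, so they can only
    gain gene links through QTL/PCHi-C evidence.
    """
    rng = _rng(spec, _STREAM_GENOME)
    chroms = [f"chr{i}" for i in range(1, 5)]
    genes: list[GeneAnnotation] = []
    cursor = {c: 100_000 for c in chroms}
    for i, name in enumerate(spec.gene_names()):
        chrom = chroms[i % len(chroms)]
        start = cursor[chrom] + int(rng.integers(20_000, 120_000))
        length = int(rng.integers(5_000, 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(name, chrom, start, start + length, strand))
        cursor[chrom] = start + length

    rows = []
    for j in range(spec.n_snps):
        rsid = f"rs{10_000 + j}"
        if rng.random() < spec.fraction_in_window:
            g = genes[int(rng.integers(0, len(genes)))]
            pos = int(rng.integers(max(g.start - 50_000, 1), g.end + 50_000))
            rows.append({"rsid": rsid, "chrom": g.chrom, "pos": pos})
        else:
            rows.append({"rsid": rsid, "chrom": "chr9_desert",
                         "pos": int(rng.integers(1, 5_000_000))})
    return genes, pd.DataFrame(rows, columns=["rsid", "chrom", "pos"])


# ---------------------------------------------------------------------------
# GWAS + functional evidence
# ---------------------------------------------------------------------------


def make_evidence(
    spec: FixtureSpec,
    genome: tuple[list[GeneAnnotation], pd.DataFrame],
    planted_genes: Sequence[str] = (),
) -> dict:
    """Generate GWAS summary stats, LD proxies and QTL/PCHi-C tables.

    Lead p-values are log-uniform over [1e-30, 1e-6] so some fail the 5e-8
    threshold; each lead carries 0-3 EUR proxies with R^2 uniform on
    [0.5, 1.0]. QTL and PCHi-C rows link a share of significant SNPs to
    nearby and to distal genes. With ``planted_effect`` != 1 every planted
    gene receives one QTL row per of a few significant leads with its
    -log10 significance multiplied by the effect; at effect exactly 1 the
    data are untouched null.
    """
    rng = _rng(spec, _STREAM_EVIDENCE)
    genes, snp_pos = genome
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_names = [g.gene for g in genes]

    exponents = rng.uniform(6, 30, size=spec.n_snps)
    variants = pd.DataFrame(
        {"rsid": snp_pos["rsid"], "pvalue": 10.0 ** (-exponents)}
    )
    significant = variants.loc[variants["pvalue"] < 5e-8, "rsid"].tolist()

    ld_rows, extra_pos = [], []
    for lead, chrom, pos in snp_pos.itertuples(index=False):
        for k in range(int(rng.integers(0, 4))):
            proxy = f"{lead}_p{k}"
            ld_rows.append(
                {"snp": lead, "proxy": proxy,
                 "r2": round(float(rng.uniform(0.5, 1.0)), 4), "population": "EUR"}
            )
            extra_pos.append(
                {"rsid": proxy, "chrom": chrom,
                 "pos": int(pos + rng.integers(-10_000, 10_000))}
            )
    ld = pd.DataFrame(ld_rows, columns=["snp", "proxy", "r2", "population"])
    positions = pd.concat(
        [snp_pos, pd.DataFrame(extra_pos, columns=["rsid", "chrom", "pos"])],
        ignore_index=True,
    )

    def _nearby(rsid: str) -> str | None:
        row = positions.loc[positions["rsid"] == rsid].iloc[0]
        cands = [g.gene for g in by_chrom.get(row["chrom"], ())
                 if abs(g.start - row["pos"]) < 300_000]
        if not cands:
            return None
        return cands[int(rng.integers(0, len(cands)))]

    qtl_rows, pchic_rows = [], []
    for rsid in significant:
        for dataset, bucket in (("blood_eqtl", qtl_rows), ("plasma_pqtl", qtl_rows)):
            if rng.random() < 0.5:
                gene = _nearby(rsid) if rng.random() < 0.7 else None
                if gene is None:
                    gene = gene_names[int(rng.integers(0, len(gene_names)))]
                bucket.append(
                    {"rsid": rsid, "gene": gene,
                     "significance": 10.0 ** (-float(rng.uniform(2, 12))),
                     "dataset": dataset}
                )
        if rng.random() < 0.5:
            gene = _nearby(rsid) if rng.random() < 0.7 else None
            if gene is None:
                gene = gene_names[int(rng.integers(0, len(gene_names)))]
            pchic_rows.append(
                {"rsid": rsid, "gene": gene,
                 "strength": round(float(rng.uniform(2, 30)), 3),
                 "dataset": "monocyte_pchic"}
            )

    if planted_genes and spec.planted_effect != 1 and significant:
        leads = list(significant[: max(3, len(significant) // 4)])
        for gene in planted_genes:
            for lead in leads:
                exp10 = float(rng.uniform(2, 12)) * spec.planted_effect
                qtl_rows.append(
                    {"rsid": lead, "gene": gene,
                     "significance": 10.0 ** (-min(exp10, 100.0)),
                     "dataset": "blood_eqtl"}
                )

    qtl = pd.DataFrame(qtl_rows, columns=["rsid", "gene", "significance", "dataset"])
    pchic = pd.DataFrame(pchic_rows, columns=["rsid", "gene", "strength", "dataset"])
    return {
        "variants": variants,
        "ld": ld,
        "positions": positions,
        "qtl_tables": [qtl.loc[qtl["dataset"] == d].reset_index(drop=True)
                       for d in sorted(qtl["dataset"].unique())],
        "pchic_tables": [pchic] if len(pchic) else [],
    }


# ---------------------------------------------------------------------------
# Network, pathways, drugs
# ---------------------------------------------------------------------------


def _connected_subgraph(graph: nx.Graph, size: int, rng: np.random.Generator,
                        start: str | None = None) -> list[str]:
    """Random connected node subset grown by breadth-first frontier sampling."""
    nodes = sorted(graph.nodes)
    if start is None:
        start = nodes[int(rng.integers(0, len(nodes)))]
    chosen = [start]
    frontier = sorted(graph.neighbors(start))
    while len(chosen) < size and frontier:
        nxt = frontier.pop(int(rng.integers(0, len(frontier))))
        if nxt in chosen:
            continue
        chosen.append(nxt)
        frontier.extend(v for v in sorted(graph.neighbors(nxt))
                        if v not in chosen and v not in frontier)
    return chosen


def make_network_and_pathways(spec: FixtureSpec) -> dict:
    """Scale-free (or ER) interaction network, pathways, drugs, planted module.

    Edge confidences are uniform on [0.3, 1.0] so the 0.4/0.7/0.9 tiers
    are all populated. Pathways are connected subgraphs of the network;
    the pathway edge list is the union of each pathway's induced edges.
    When a module is planted, it is a connected subgraph embedded in one
    pathway (connectivity asserted).
    """
    rng = _rng(spec, _STREAM_NETWORK)
    names = spec.gene_names()
    if spec.network_model == "barabasi_albert":
        raw = nx.barabasi_albert_graph(spec.n_genes, 3, seed=int(rng.integers(2**31)))
    else:
        raw = nx.gnp_random_graph(spec.n_genes, 6.0 / spec.n_genes,
                                  seed=int(rng.integers(2**31)))
        for comp in list(nx.connected_components(raw))[1:]:
            raw.add_edge(next(iter(comp)), 0)  # stitch small ER components
    relabel = dict(zip(sorted(raw.nodes), names))
    graph = nx.relabel_nodes(raw, relabel)

    edges = [
        NetworkEdge(*sorted((a, b)), confidence=round(float(rng.uniform(0.3, 1.0)), 3))
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges)
    ]

    planted: list[str] = []
    if spec.planted_module_size > 0:
        planted = _connected_subgraph(graph, spec.planted_module_size, rng)
        assert nx.is_connected(graph.subgraph(planted))

    pathways: list[PathwaySet] = []
    pathway_edges: dict[str, list[tuple[str, str]]] = {}
    for i in range(spec.n_pathways):
        pid = f"PW{i + 1:02d}"
        if i == 0 and planted:
            members = list(planted)
            extra = _connected_subgraph(graph, 6, rng, start=planted[0])
            members = sorted(set(members) | set(extra))
        else:
            size = int(rng.integers(8, 26))
            members = sorted(_connected_subgraph(graph, size, rng))
        pathways.append(PathwaySet(pid, f"synthetic pathway {i + 1}", frozenset(members)))
        pathway_edges[pid] = sorted(
            tuple(sorted(e)) for e in graph.subgraph(members).edges
        )

    drug_rows: list[DrugIndication] = []
    druggable = [n for n in names if rng.random() < 0.15]
    for j, gene in enumerate(druggable):
        for k in range(int(rng.integers(1, 4))):
            phase = int(rng.choice([1, 2, 3, 4], p=[0.2, 0.25, 0.15, 0.4]))
            drug_rows.append(
                DrugIndication(
                    target_gene=gene,
                    drug_name=f"DRUG{j:03d}{chr(65 + k)}",
                    indication=_INDICATIONS[int(rng.integers(0, len(_INDICATIONS)))],
                    moa=f"{gene} inhibitor",
                    phase=phase,
                )
            )
    return {
        "graph": graph,
        "edges": edges,
        "pathways": pathways,
        "pathway_edges": pathway_edges,
        "drugs": drug_rows,
        "planted": planted,
    }


def planted_node_scores(
    spec: FixtureSpec, network: nx.Graph, planted: Sequence[str]
) -> dict[str, float]:
    """I.i.d. node scores with the planted module inflated.

    Base scores are uniform on [0.5, 1.5]; planted genes are multiplied by
    ``planted_effect`` (a multiplier of 1 leaves the field exactly i.i.d.).
    """
    rng = _rng(spec, _STREAM_SCORES)
    nodes = sorted(network.nodes)
    scores = dict(zip(nodes, rng.uniform(0.5, 1.5, size=len(nodes))))
    for g in planted:
        if g in scores:
            scores[g] *= spec.planted_effect
    return {g: float(s) for g, s in scores.items()}


# ---------------------------------------------------------------------------
# On-disk fixture directory
# ---------------------------------------------------------------------------


def write_fixture_dir(spec: FixtureSpec, outdir) -> dict[str, Path]:
    """Write every input file the pipeline subcommands consume.

    Returns a mapping of logical input name -> written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(spec)
    net = make_network_and_pathways(spec)
    ev = make_evidence(spec, genome, planted_genes=net["planted"])

    genes, _ = genome
    paths = {}

    def _write(name, obj):
        p = outdir / name
        write_table(obj, p)
        paths[name.split(".")[0]] = p

    _write("variants.tsv", ev["variants"])
    _write("ld.tsv", ev["ld"])
    _write("annotation.tsv", genes)
    _write("snp_positions.tsv", ev["positions"])
    for i, q in enumerate(ev["qtl_tables"]):
        label = q["dataset"].iloc[0] if len(q) else f"qtl{i}"
        _write(f"qtl_{label}.tsv", q)
    for i, p in enumerate(ev["pchic_tables"]):
        label = p["dataset"].iloc[0] if len(p) else f"pchic{i}"
        _write(f"pchic_{label}.tsv", p)
    _write("ppi_edges.tsv", net["edges"])

    gmt = outdir / "pathways.gmt"
    with open(gmt, "w") as fh:
        for pw in net["pathways"]:
            fh.write("\t".join([pw.pathway_id, pw.pathway_name, *sorted(pw.members)]) + "\n")
    paths["pathways"] = gmt

    pe_rows = [
        {"gene_a": a, "gene_b": b, "pathway_id": pid}
        for pid, es in sorted(net["pathway_edges"].items())
        for a, b in es
    ]
    _write("pathway_edges.tsv", pd.DataFrame(pe_rows, columns=["gene_a", "gene_b", "pathway_id"]))
    _write("drugs.tsv", net["drugs"])
    if net["planted"]:
        _write("planted_module.tsv", pd.DataFrame({"gene": sorted(net["planted"])}))
    return paths
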