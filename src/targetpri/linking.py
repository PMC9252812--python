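"""Stage 1 — linking disease-associated variants to core genes.

GWAS input SNPs passing a genome-wide significance threshold (default
p < 5e-8, strict) are optionally expanded with linkage-disequilibrium
proxies (R^2 > 0.8, strict, in a chosen reference population); proxies
inherit the lead SNP's p-value. The retained variants are then linked to
candidate core genes through three kinds of functional evidence:

* genomic proximity — genes whose body lies within a window of the SNP;
* QTL — variants associated with a gene's expression or protein abundance;
* PCHi-C — chromatin conformation contacts between the SNP region and a
  gene promoter.

Each evidence predictor yields a per-gene score in [0,1]: per-link
contributions are the capped -log10 SNP weight times a source-specific
modifier (linear distance decay for proximity; per-dataset 95th-percentile
saturation for QTL/PCHi-C strengths), combined across SNPs per gene
(max by default) and rescaled by the predictor's maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EvidenceLink, GeneAnnotation, ValidationError, VariantRecord

log = logging.getLogger(__name__)

SNP_WEIGHT_CAP = 100.0
PROXIMITY = "proximity"

__all__ = [
    "LinkConfig",
    "CoreGeneScore",
    "EmptyResultError",
    "filter_and_expand",
    "snp_weight",
    "link_evidence",
    "score_core_genes",
    "evidence_table",
]


class EmptyResultError(ValueError):
    """No variants or links survive filtering; thresholds may need relaxing."""


@dataclass
class LinkConfig:
    """Knobs of the variant-to-gene stage.

    p_threshold : genome-wide significance cutoff, strict ``<`` (default 5e-8)
    r2_threshold : LD cutoff for proxies, strict ``>`` (default 0.8)
    population : LD reference population (default EUR)
    include_ld : whether to expand with LD proxies at all
    window_bp : proximity window half-width in bp (default 50 kb)
    decay : proximity weighting, ``linear`` (1 - d/window) or ``constant``
    score_combine : per-gene combination across SNPs, ``max`` or ``sum``
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.8
    population: str = "EUR"
    include_ld: bool = True
    window_bp: int = 50_000
    decay: str = "linear"
    score_combine: str = "max"

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0,1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.decay not in ("linear", "constant"):
            raise ValueError("decay must be 'linear' or 'constant'")
        if self.score_combine not in ("max", "sum"):
            raise ValueError("score_combine must be 'max' or 'sum'")


@dataclass(frozen=True)
class CoreGeneScore:
    gene: str
    score: float
    n_snps: int
    evidence_counts: Mapping[str, int] = field(default_factory=dict)


def filter_and_expand(
    variants: Sequence[VariantRecord],
    ld_table: pd.DataFrame | None,
    cfg: LinkConfig,
) -> list[VariantRecord]:
    """Apply the significance threshold and expand with LD proxies.

    Returns the retained user SNPs plus, when ``cfg.include_ld``, proxies
    with R^2 strictly above the threshold in ``cfg.population``. A proxy
    reachable from two leads keeps the more significant lead; a proxy rsid
    that is itself a retained user SNP is not duplicated.
    """
    retained = [v for v in variants if v.origin == "user" and v.pvalue < cfg.p_threshold]
    if not retained:
        raise EmptyResultError(
            f"no input SNP passes p < {cfg.p_threshold:g}; relax p_threshold"
        )
    out = {v.rsid: v for v in retained}
    if cfg.include_ld and ld_table is not None and len(ld_table):
        ld = ld_table.loc[
            (ld_table["population"] == cfg.population)
            & (ld_table["r2"] > cfg.r2_threshold)
        ]
        by_lead = {v.rsid: v for v in retained}
        for row in ld.itertuples():
            lead = by_lead.get(row.snp)
            if lead is None or row.proxy in by_lead:
                continue
            prev = out.get(row.proxy)
            if prev is not None and prev.pvalue <= lead.pvalue:
                continue
            out[row.proxy] = VariantRecord(
                rsid=row.proxy,
                pvalue=lead.pvalue,
                origin="ld_proxy",
                lead_rsid=lead.rsid,
                r2=float(row.r2),
                population=cfg.population,
            )
    return list(out.values())


def snp_weight(pvalue: float) -> float:
    """Capped -log10 weight of a SNP's association p-value.

    Strictly decreasing in the p-value below the cap (100, i.e. p = 1e-100),
    0 at p = 1.
    """
    if pvalue <= 0:
        raise ValueError(f"p-value must be positive, got {pvalue}")
    return min(-math.log10(pvalue), SNP_WEIGHT_CAP)


def link_evidence(
    variants: Sequence[VariantRecord],
    annotation: Sequence[GeneAnnotation],
    snp_positions: pd.DataFrame,
    qtl_tables: Sequence[pd.DataFrame] = (),
    pchic_tables: Sequence[pd.DataFrame] = (),
    cfg: LinkConfig | None = None,
) -> list[EvidenceLink]:
    """Link retained variants to genes via proximity, QTL and PCHi-C.

    Proximity: every gene whose body lies within ``window_bp`` of the SNP
    position, raw_weight = distance in bp (0 inside the gene body).
    QTL: table rows whose SNP is in the variant set, raw_weight = -log10 of
    the association significance. PCHi-C: rows whose SNP is in the variant
    set, raw_weight = interaction strength. SNPs with no position and no
    QTL/PCHi-C row contribute nothing (logged).
    """
    cfg = cfg or LinkConfig()
    rsids = {v.rsid for v in variants}
    links: list[EvidenceLink] = []

    pos_map: dict[str, tuple[str, int]] = {}
    if snp_positions is not None and len(snp_positions):
        for row in snp_positions.itertuples():
            if row.rsid in rsids:
                pos_map[row.rsid] = (str(row.chrom), int(row.pos))

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)

    for rsid in sorted(rsids):
        loc = pos_map.get(rsid)
        if loc is None:
            continue
        chrom, pos = loc
        for g in by_chrom.get(chrom, ()):
            if pos < g.start:
                dist = g.start - pos
            elif pos > g.end:
                dist = pos - g.end
            else:
                dist = 0
            if dist <= cfg.window_bp:
                links.append(EvidenceLink(rsid, g.gene, PROXIMITY, PROXIMITY, float(dist)))

    for table in qtl_tables:
        for row in table.itertuples():
            if row.rsid in rsids:
                weight = min(-math.log10(max(row.significance, 1e-300)), SNP_WEIGHT_CAP)
                links.append(EvidenceLink(row.rsid, row.gene, "qtl", row.dataset, weight))
    for table in pchic_tables:
        for row in table.itertuples():
            if row.rsid in rsids:
                links.append(
                    EvidenceLink(row.rsid, row.gene, "pchic", row.dataset, float(row.strength))
                )

    silent = rsids - pos_map.keys() - {l.rsid for l in links}
    if silent:
        log.info("%d SNP(s) contributed no evidence link: %s",
                 len(silent), ", ".join(sorted(silent)[:10]))
    return links


def _modifier(link: EvidenceLink, cfg: LinkConfig, w95: Mapping[str, float]) -> float:
    if link.source == PROXIMITY:
        if cfg.decay == "constant":
            return 1.0
        return max(1.0 - link.raw_weight / cfg.window_bp, 0.0)
    cap = w95.get(link.dataset, 0.0)
    if cap <= 0:
        return 1.0
    return min(link.raw_weight / cap, 1.0)


def score_core_genes(
    links: Sequence[EvidenceLink],
    variants: Sequence[VariantRecord],
    cfg: LinkConfig | None = None,
) -> tuple[dict[str, pd.Series], list[CoreGeneScore]]:
    """Score core genes per evidence predictor and build a combined summary.

    Per-link contribution = snp_weight(p) x source modifier, combined
    across SNPs per gene by ``cfg.score_combine``; each predictor's scores
    are then rescaled to [0,1] by its maximum. A predictor is one evidence
    dataset (proximity, or each QTL/PCHi-C dataset label).

    Returns ``(per_predictor, summary)`` where ``per_predictor`` maps
    predictor label -> per-gene score Series and ``summary`` carries the
    combined (max across predictors) score with SNP and evidence counts.
    """
    cfg = cfg or LinkConfig()
    if not links:
        raise EmptyResultError("no evidence links; nothing to score")
    pvals = {v.rsid: v.pvalue for v in variants}
    missing = {l.rsid for l in links} - pvals.keys()
    if missing:
        raise ValidationError(f"links reference unknown SNPs: {sorted(missing)[:5]}")

    # per-dataset saturation point for QTL/PCHi-C raw weights
    w95: dict[str, float] = {}
    raw_by_dataset: dict[str, list[float]] = {}
    for l in links:
        if l.source != PROXIMITY:
            raw_by_dataset.setdefault(l.dataset, []).append(l.raw_weight)
    for ds, vals in raw_by_dataset.items():
        w95[ds] = float(np.percentile(vals, 95))

    contrib: dict[str, dict[str, list[float]]] = {}  # predictor -> gene -> contributions
    for l in links:
        c = snp_weight(pvals[l.rsid]) * _modifier(l, cfg, w95)
        contrib.setdefault(l.dataset, {}).setdefault(l.gene, []).append(c)

    combine = max if cfg.score_combine == "max" else sum
    per_predictor: dict[str, pd.Series] = {}
    for pred in sorted(contrib):
        scores = {g: float(combine(cs)) for g, cs in contrib[pred].items()}
        top = max(scores.values())
        if top > 0:
            scores = {g: s / top for g, s in scores.items()}
        per_predictor[pred] = pd.Series(scores, name=pred).sort_index()

    genes = sorted({l.gene for l in links})
    summary = []
    for g in genes:
        counts = {"proximity": 0, "qtl": 0, "pchic": 0}
        snps = set()
        for l in links:
            if l.gene == g:
                counts[l.source] += 1
                snps.add(l.rsid)
        score = max(s.get(g, 0.0) for s in per_predictor.values())
        summary.append(CoreGeneScore(g, float(score), len(snps), counts))
    return per_predictor, summary


def evidence_table(
    links: Sequence[EvidenceLink], variants: Sequence[VariantRecord]
) -> pd.DataFrame:
    """Flat evidence table: which SNPs define which core genes, and how."""
    origin = {v.rsid: v.origin for v in variants}
    pval = {v.rsid: v.pvalue for v in variants}
    rows = [
        {
            "rsid": l.rsid,
            "snp_type": origin.get(l.rsid, "user"),
            "pvalue": pval.get(l.rsid, float("nan")),
            "gene": l.gene,
            "source": l.source,
            "dataset": l.dataset,
            "raw_weight": l.raw_weight,
        }
        for l in sorted(links, key=lambda l: (l.gene, l.rsid, l.source, l.dataset))
    ]
    return pd.DataFrame(
        rows,
        columns=["rsid", "snp_type", "pvalue", "gene", "source", "dataset", "raw_weight"],
    )
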