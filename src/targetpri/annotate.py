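"""Pathway enrichment of top-rated genes and drug-repurposing tables.

The top fraction of the priority ranking (default 1%) is tested for
over-representation in each pathway gene set with the one-sided
hypergeometric upper tail, against the universe of rated genes (the
propagation network's node set), with Benjamini-Hochberg FDR control.
Crosstalk genes carrying approved (phase-4) drug records are arranged
into a gene x indication matrix whose cells index a drug detail table.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DrugIndication, PathwaySet

__all__ = ["select_top", "enrich", "repurpose"]


def select_top(priority: pd.DataFrame, fraction: float = 0.01) -> list[str]:
    """Top-ranked genes: ceil(fraction * N), so small inputs never select zero."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0,1]")
    if priority.empty:
        raise ValueError("empty priority table")
    n = math.ceil(fraction * len(priority))
    return priority.sort_values("rank")["gene"].head(n).tolist()


def enrich(
    selected: Iterable[str],
    pathways: Sequence[PathwaySet],
    universe: Iterable[str],
    min_overlap: int = 0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each pathway.

    Pathway members are intersected with the universe before testing;
    p = P(X >= overlap) for X hypergeometric(universe_n, pathway_n,
    selected_n). Rows are sorted by ascending p; FDR is Benjamini-Hochberg
    across the tested pathways. Zero-overlap pathways are reported (p = 1)
    unless ``min_overlap`` excludes them.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")

    rows = []
    for pw in pathways:
        members = pw.members & universe
        k = len(selected & members)
        if k < min_overlap:
            continue
        m, big_n, n_sel = len(members), len(universe), len(selected)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n_sel)) if m else 1.0
        fold = (k / n_sel) / (m / big_n) if m else float("nan")
        rows.append(
            {
                "pathway_id": pw.pathway_id,
                "pathway_name": pw.pathway_name,
                "overlap": k,
                "selected_n": n_sel,
                "pathway_n": m,
                "universe_n": big_n,
                "pvalue": min(p, 1.0),
                "fold_enrichment": fold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["pathway_id", "pathway_name", "overlap", "selected_n",
                 "pathway_n", "universe_n", "pvalue", "fold_enrichment"],
    )
    if len(df):
        df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df = df.sort_values(["pvalue", "pathway_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def repurpose(
    crosstalk_genes: Iterable[str],
    drug_table: Sequence[DrugIndication],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Crosstalk-based drug repurposing tables.

    Returns ``(matrix, detail, unmatched)``: ``matrix`` has one row per
    (gene, indication) pair backed by at least one approved (phase-4)
    drug, with a sequential integer index keying into ``detail`` rows of
    (index, drug, mechanism of action); ``unmatched`` lists crosstalk
    genes with no approved drug record.
    """
    genes = sorted(set(crosstalk_genes))
    approved = [d for d in drug_table if d.approved and d.target_gene in genes]

    cells: dict[tuple[str, str], list[DrugIndication]] = {}
    for d in approved:
        cells.setdefault((d.target_gene, d.indication), []).append(d)

    matrix_rows, detail_rows = [], []
    for idx, (gene, indication) in enumerate(sorted(cells), start=1):
        matrix_rows.append({"target_gene": gene, "indication": indication, "index": idx})
        for d in sorted(cells[(gene, indication)], key=lambda d: d.drug_name):
            detail_rows.append(
                {"index": idx, "target_gene": gene, "indication": indication,
                 "drug_name": d.drug_name, "moa": d.moa, "phase": d.phase}
            )
    matrix = pd.DataFrame(matrix_rows, columns=["target_gene", "indication", "index"])
    detail = pd.DataFrame(
        detail_rows,
        columns=["index", "target_gene", "indication", "drug_name", "moa", "phase"],
    )
    matched = set(matrix["target_gene"]) if len(matrix) else set()
    unmatched = pd.DataFrame({"gene": [g for g in genes if g not in matched]})
    return matrix, detail, unmatched
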