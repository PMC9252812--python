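"""Readers, writers and validated record types for every external table.

All tabular inputs use a TSV dialect by default (delimiter configurable).
Gene identity is the case-preserved symbol string, matched case-sensitively;
coordinates are 1-based inclusive. Each reader returns a single canonical
in-memory representation per input kind: small record dataclasses for
entities with invariants worth enforcing row by row, plain pandas frames
for bulk evidence tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

__all__ = [
    "POPULATIONS",
    "ValidationError",
    "VariantRecord",
    "GeneAnnotation",
    "EvidenceLink",
    "NetworkEdge",
    "PathwaySet",
    "DrugIndication",
    "read_variants",
    "read_ld_table",
    "read_gene_annotation",
    "read_snp_positions",
    "read_qtl_table",
    "read_pchic_table",
    "read_edge_list",
    "read_gmt",
    "read_pathway_edges",
    "read_seed_scores",
    "read_drug_table",
    "write_table",
    "read_table",
]


class ValidationError(ValueError):
    """Raised when an input file violates a format or domain constraint."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A GWAS variant: either user input or an LD proxy of a user SNP.

    ``lead_rsid`` points at the user SNP a proxy derives from (self for user
    SNPs); proxies inherit the lead's p-value. ``r2`` is linkage
    disequilibrium with the lead (1.0 for user SNPs).
    """

    rsid: str
    pvalue: float
    origin: str = "user"  # {user, ld_proxy}
    lead_rsid: str = ""
    r2: float = 1.0
    population: str = "EUR"

    def __post_init__(self):
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(
                f"p-value for {self.rsid} must be in (0,1], got {self.pvalue!r}"
            )
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(f"R^2 for {self.rsid} must be in [0,1], got {self.r2!r}")
        if self.origin not in ("user", "ld_proxy"):
            raise ValidationError(f"unknown variant origin {self.origin!r}")
        if self.population not in POPULATIONS:
            raise ValidationError(f"unknown population {self.population!r}")
        if not self.lead_rsid:
            object.__setattr__(self, "lead_rsid", self.rsid)
        if self.origin == "user" and (self.lead_rsid != self.rsid or self.r2 != 1.0):
            raise ValidationError(
                f"user SNP {self.rsid} must be its own lead with r2=1.0"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body location; 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class EvidenceLink:
    """One SNP-to-gene link from a single evidence source.

    ``raw_weight`` is source specific: distance in bp for proximity, -log10
    of the QTL significance for qtl, interaction strength for pchic.
    """

    rsid: str
    gene: str
    source: str  # {proximity, qtl, pchic}
    dataset: str
    raw_weight: float

    def __post_init__(self):
        if self.source not in ("proximity", "qtl", "pchic"):
            raise ValidationError(f"unknown evidence source {self.source!r}")
        if self.raw_weight < 0:
            raise ValidationError(
                f"raw_weight must be >= 0 ({self.rsid}->{self.gene})"
            )


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected interaction edge with a confidence score in [0,1]."""

    gene_a: str
    gene_b: str
    confidence: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-loop on {self.gene_a}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence for {self.gene_a}-{self.gene_b} outside [0,1]"
            )


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    pathway_name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"pathway {self.pathway_id} has no members")


@dataclass(frozen=True)
class DrugIndication:
    target_gene: str
    drug_name: str
    indication: str
    moa: str
    phase: int

    def __post_init__(self):
        if self.phase not in range(5):
            raise ValidationError(
                f"phase for {self.drug_name} must be 0..4, got {self.phase!r}"
            )

    @property
    def approved(self) -> bool:
        return self.phase == 4


# ---------------------------------------------------------------------------
# Low-level TSV helpers
# ---------------------------------------------------------------------------


def _rows(path, delimiter: str = "\t"):
    """Yield (line_number, fields) for non-empty lines, skipping '#' comments."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, [f.strip() for f in line.split(delimiter)]


def _is_number(text: str) -> bool:
    try:
        float(text)
    except (TypeError, ValueError):
        return False
    return True


def _read_frame(path, columns: Sequence[str], delimiter: str = "\t") -> pd.DataFrame:
    """Read a TSV with an optional header into a frame with canonical columns."""
    df = pd.read_csv(path, sep=delimiter, comment="#", header=None, dtype=str)
    if df.empty:
        return pd.DataFrame(columns=list(columns))
    if df.shape[1] < len(columns):
        raise ValidationError(
            f"{path}: expected >= {len(columns)} columns, found {df.shape[1]}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)
    # header auto-detection: drop a first row that repeats the column names or
    # whose numeric fields do not parse
    first = df.iloc[0]
    numeric_cols = [c for c in columns if c in _NUMERIC_COLUMNS]
    if any(str(first[c]).lower() == c.lower() for c in columns) or (
        numeric_cols and not all(_is_number(first[c]) for c in numeric_cols)
    ):
        df = df.iloc[1:].reset_index(drop=True)
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


_NUMERIC_COLUMNS = {
    "pvalue",
    "r2",
    "start",
    "end",
    "pos",
    "significance",
    "strength",
    "confidence",
    "phase",
    "score",
    "weight",
}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_variants(path, delimiter: str = "\t") -> list[VariantRecord]:
    """Read a two-column (rsid, p-value) GWAS summary table.

    The header is optional and auto-detected as the first row whose second
    field does not parse as a number. Duplicate rsids collapse to the
    smallest p-value (the most significant association wins), keeping file
    order of first appearance.
    """
    records: dict[str, VariantRecord] = {}
    saw_data = False
    for lineno, parts in _rows(path, delimiter):
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected >= 2 columns")
        rsid, pval = parts[0], parts[1]
        if not _is_number(pval):
            if not saw_data:
                continue  # header row
            raise ValidationError(f"{path}:{lineno}: p-value {pval!r} is not a number")
        saw_data = True
        p = float(pval)
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"{path}:{lineno}: p-value {p} outside (0,1]")
        if rsid not in records or p < records[rsid].pvalue:
            records[rsid] = VariantRecord(rsid=rsid, pvalue=p)
    if not saw_data:
        raise ValidationError(f"{path}: no variant rows found")
    return list(records.values())


def read_ld_table(path, delimiter: str = "\t") -> pd.DataFrame:
    """LD reference table: columns (snp, proxy, r2, population)."""
    df = _read_frame(path, ["snp", "proxy", "r2", "population"], delimiter)
    bad = df.loc[(df["r2"] < 0) | (df["r2"] > 1)]
    if len(bad):
        raise ValidationError(f"{path}: R^2 outside [0,1] in {len(bad)} rows")
    unknown = set(df["population"]) - set(POPULATIONS)
    if unknown:
        raise ValidationError(f"{path}: unknown populations {sorted(unknown)}")
    return df


def read_gene_annotation(path, delimiter: str = "\t") -> list[GeneAnnotation]:
    """Gene annotation: (gene, chrom, start, end, strand), 1-based inclusive."""
    df = _read_frame(path, ["gene", "chrom", "start", "end", "strand"], delimiter)
    if df["gene"].duplicated().any():
        dups = sorted(df.loc[df["gene"].duplicated(), "gene"].unique())
        raise ValidationError(f"{path}: duplicate gene symbols {dups[:5]}")
    return [
        GeneAnnotation(r.gene, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_snp_positions(path, delimiter: str = "\t") -> pd.DataFrame:
    """SNP genomic positions: (rsid, chrom, pos)."""
    return _read_frame(path, ["rsid", "chrom", "pos"], delimiter)


def read_qtl_table(path, dataset: str | None = None, delimiter: str = "\t") -> pd.DataFrame:
    """QTL evidence: (rsid, gene, significance, dataset).

    ``significance`` is the raw association p-value of variant vs expression
    or protein abundance; downstream scoring uses -log10 of it.
    """
    df = _read_frame(path, ["rsid", "gene", "significance", "dataset"], delimiter)
    if dataset is not None:
        df["dataset"] = dataset
    if ((df["significance"] <= 0) | (df["significance"] > 1)).any():
        raise ValidationError(f"{path}: QTL significance outside (0,1]")
    return df


def read_pchic_table(path, dataset: str | None = None, delimiter: str = "\t") -> pd.DataFrame:
    """Promoter capture Hi-C evidence: (rsid, gene, strength, dataset)."""
    df = _read_frame(path, ["rsid", "gene", "strength", "dataset"], delimiter)
    if dataset is not None:
        df["dataset"] = dataset
    if (df["strength"] < 0).any():
        raise ValidationError(f"{path}: negative interaction strength")
    return df


def read_edge_list(path, min_confidence: float = 0.0, delimiter: str = "\t") -> list[NetworkEdge]:
    """Read a 3-column (gene_a, gene_b, confidence) interaction edge list.

    Edges below ``min_confidence`` are dropped, self-loops removed, and
    symmetric duplicates merged keeping the maximum confidence.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must be in [0,1]")
    df = _read_frame(path, ["gene_a", "gene_b", "confidence"], delimiter)
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValidationError(f"{path}: confidence outside [0,1]")
    merged: dict[tuple[str, str], float] = {}
    for r in df.itertuples():
        if r.gene_a == r.gene_b:
            continue
        key = (r.gene_a, r.gene_b) if r.gene_a < r.gene_b else (r.gene_b, r.gene_a)
        c = float(r.confidence)
        if c > merged.get(key, -1.0):
            merged[key] = c
    return [
        NetworkEdge(a, b, c)
        for (a, b), c in sorted(merged.items())
        if c >= min_confidence
    ]


def read_gmt(path) -> list[PathwaySet]:
    """Read pathway gene sets in GMT format (id TAB name TAB member...)."""
    out = []
    for lineno, parts in _rows(path, "\t"):
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        members = frozenset(m for m in parts[2:] if m)
        out.append(PathwaySet(parts[0], parts[1], members))
    return out


def read_pathway_edges(path, delimiter: str = "\t") -> dict[str, list[tuple[str, str]]]:
    """Pathway-derived edge list: (gene_a, gene_b, pathway_id) rows.

    Returns a mapping pathway_id -> list of undirected edges.
    """
    df = _read_frame(path, ["gene_a", "gene_b", "pathway_id"], delimiter)
    out: dict[str, list[tuple[str, str]]] = {}
    for r in df.itertuples():
        out.setdefault(r.pathway_id, []).append(tuple(sorted((r.gene_a, r.gene_b))))
    return out


def read_seed_scores(path, delimiter: str = "\t") -> dict[str, float]:
    """Two-column (gene, score) seed-weight table."""
    df = _read_frame(path, ["gene", "score"], delimiter)
    if (df["score"] < 0).any():
        raise ValidationError(f"{path}: negative seed score")
    return {r.gene: float(r.score) for r in df.itertuples()}


def read_drug_table(path, delimiter: str = "\t") -> list[DrugIndication]:
    """Drug-target-indication table: (target_gene, drug_name, indication, moa, phase)."""
    df = _read_frame(
        path, ["target_gene", "drug_name", "indication", "moa", "phase"], delimiter
    )
    return [
        DrugIndication(r.target_gene, r.drug_name, r.indication, r.moa, int(r.phase))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Generic result writer (round-trip stable)
# ---------------------------------------------------------------------------


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if records and hasattr(records[0], "__dataclass_fields__"):
        cols = [f.name for f in dc_fields(records[0])]
        rows = []
        for rec in records:
            row = {}
            for c in cols:
                v = getattr(rec, c)
                if isinstance(v, frozenset):
                    v = "|".join(sorted(v))
                row[c] = v
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)
    return pd.DataFrame(records)


def write_table(records, path, format: str = "tsv") -> None:
    """Write any result table (frame or dataclass sequence) to TSV or JSON.

    Writing then reading back with :func:`read_table` reproduces the frame
    exactly; float formatting is fixed so re-runs are byte-identical.
    """
    df = _to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        payload = {
            "columns": list(df.columns),
            "rows": json.loads(df.to_json(orient="values", double_precision=12)),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    """Inverse of :func:`write_table`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return pd.DataFrame(payload["rows"], columns=payload["columns"])
    raise ValueError(f"unknown format {format!r}")
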