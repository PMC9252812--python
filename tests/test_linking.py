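import math

import pandas as pd
import pytest

from targetpri.io import GeneAnnotation, VariantRecord
from targetpri.linking import (
    EmptyResultError,
    LinkConfig,
    filter_and_expand,
    link_evidence,
    score_core_genes,
    snp_weight,
)


def _ld(rows):
    return pd.DataFrame(rows, columns=["snp", "proxy", "r2", "population"])


class TestFilterAndExpand:
    def test_threshold_is_strict(self):
        variants = [VariantRecord("rs_a", 6e-8), VariantRecord("rs_b", 4.9e-8)]
        out = filter_and_expand(variants, None, LinkConfig())
        assert [v.rsid for v in out] == ["rs_b"]

    def test_proxy_inclusion_strict_r2_and_inherited_p(self):
        variants = [VariantRecord("rs_lead", 1e-9)]
        ld = _ld([("rs_lead", "rs_p1", 0.85, "EUR"), ("rs_lead", "rs_p2", 0.80, "EUR")])
        out = filter_and_expand(variants, ld, LinkConfig())
        by_id = {v.rsid: v for v in out}
        assert set(by_id) == {"rs_lead", "rs_p1"}
        assert by_id["rs_p1"].pvalue == 1e-9
        assert by_id["rs_p1"].origin == "ld_proxy"
        assert by_id["rs_p1"].lead_rsid == "rs_lead"

    def test_population_restriction(self):
        variants = [VariantRecord("rs_lead", 1e-9)]
        ld = _ld([("rs_lead", "rs_p1", 0.95, "EAS")])
        out = filter_and_expand(variants, ld, LinkConfig(population="EUR"))
        assert [v.rsid for v in out] == ["rs_lead"]

    def test_proxy_of_two_leads_keeps_more_significant(self):
        variants = [VariantRecord("rs_a", 1e-9), VariantRecord("rs_b", 1e-12)]
        ld = _ld([("rs_a", "rs_p", 0.9, "EUR"), ("rs_b", "rs_p", 0.9, "EUR")])
        out = filter_and_expand(variants, ld, LinkConfig())
        proxy = next(v for v in out if v.rsid == "rs_p")
        assert proxy.lead_rsid == "rs_b" and proxy.pvalue == 1e-12

    def test_include_ld_off_returns_thresholded_only(self):
        variants = [VariantRecord("rs_lead", 1e-9)]
        ld = _ld([("rs_lead", "rs_p1", 0.99, "EUR")])
        out = filter_and_expand(variants, ld, LinkConfig(include_ld=False))
        assert [v.rsid for v in out] == ["rs_lead"]

    def test_nothing_survives_raises_helpful_error(self):
        with pytest.raises(EmptyResultError, match="relax"):
            filter_and_expand([VariantRecord("rs_a", 0.5)], None, LinkConfig())


class TestSnpWeight:
    @pytest.mark.parametrize(
        "p,expected", [(1e-8, 8.0), (1e-300, 100.0), (1.0, 0.0), (0.1, 1.0)]
    )
    def test_capped_neglog10(self, p, expected):
        assert snp_weight(p) == pytest.approx(expected)

    def test_strictly_decreasing_below_cap(self):
        ps = [1e-2, 1e-4, 1e-8, 1e-50]
        ws = [snp_weight(p) for p in ps]
        assert ws == sorted(ws)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            snp_weight(0.0)


ANNOT = [
    GeneAnnotation("IL6R", "chr1", 100_000, 160_000),
    GeneAnnotation("FAR", "chr1", 300_000, 320_000),
    GeneAnnotation("OTHER", "chr2", 100_000, 120_000),
]
POS = pd.DataFrame(
    {"rsid": ["rs4129267", "rs_far"], "chrom": ["chr1", "chr1"], "pos": [150_000, 240_000]}
)


class TestLinkEvidence:
    def test_multi_source_links_to_one_gene(self):
        variants = [VariantRecord("rs4129267", 1e-12)]
        qtl = pd.DataFrame(
            [["rs4129267", "IL6R", 1e-6, "plasma_pqtl"]],
            columns=["rsid", "gene", "significance", "dataset"],
        )
        pchic = pd.DataFrame(
            [["rs4129267", "IL6R", 12.0, "monocyte"]],
            columns=["rsid", "gene", "strength", "dataset"],
        )
        links = link_evidence(variants, ANNOT, POS, [qtl], [pchic])
        il6r = [l for l in links if l.gene == "IL6R"]
        assert {l.source for l in il6r} == {"proximity", "qtl", "pchic"}
        qlink = next(l for l in il6r if l.source == "qtl")
        assert qlink.raw_weight == pytest.approx(6.0)  # -log10 significance

    def test_snp_inside_gene_body_has_zero_distance(self):
        variants = [VariantRecord("rs4129267", 1e-12)]
        links = link_evidence(variants, ANNOT, POS)
        prox = next(l for l in links if l.gene == "IL6R")
        assert prox.raw_weight == 0.0

    def test_gene_outside_window_not_linked(self):
        # rs_far is 60 kb from FAR's start: outside the default 50 kb window
        variants = [VariantRecord("rs_far", 1e-10)]
        links = link_evidence(variants, ANNOT, POS)
        assert all(l.gene != "FAR" for l in links)
        links_wide = link_evidence(
            variants, ANNOT, POS, cfg=LinkConfig(window_bp=80_000)
        )
        assert any(l.gene == "FAR" for l in links_wide)

    def test_unplaced_snp_contributes_nothing(self):
        variants = [VariantRecord("rs_nowhere", 1e-10)]
        assert link_evidence(variants, ANNOT, POS) == []


class TestScoreCoreGenes:
    def _links(self, variants, cfg=None):
        return link_evidence(variants, ANNOT, POS, cfg=cfg)

    def test_zero_distance_gives_max_contribution(self):
        variants = [VariantRecord("rs4129267", 1e-8)]
        per_pred, summary = score_core_genes(self._links(variants), variants)
        assert per_pred["proximity"]["IL6R"] == 1.0  # sole gene, rescaled max
        (cg,) = summary
        assert cg.gene == "IL6R" and cg.n_snps == 1
        assert cg.evidence_counts["proximity"] == 1

    def test_linear_decay_vanishes_at_window_edge(self):
        # rs_far sits exactly 60 kb from FAR; with window_bp = 60 kb the
        # link exists but its linear-decay contribution is exactly 0
        cfg = LinkConfig(window_bp=60_000)
        variants = [VariantRecord("rs_far", 1e-8)]
        links = [l for l in self._links(variants, cfg) if l.gene == "FAR"]
        (link,) = links
        assert link.raw_weight == 60_000
        per_pred, _ = score_core_genes(links, variants, cfg)
        assert per_pred["proximity"]["FAR"] == 0.0
        # constant decay keeps the full SNP weight instead
        cfg_const = LinkConfig(window_bp=60_000, decay="constant")
        per_const, _ = score_core_genes(links, variants, cfg_const)
        assert per_const["proximity"]["FAR"] == 1.0

    def test_combine_semantics_max_vs_sum(self):
        # IL6R gets two SNPs (weights 8 and 10 inside its body); REF gets
        # one weight-10 SNP. Under max both genes score 10 (ratio 1); under
        # sum IL6R scores 18 so REF rescales to 10/18.
        variants = [
            VariantRecord("rs_a", 1e-8),
            VariantRecord("rs_b", 1e-10),
            VariantRecord("rs_c", 1e-10),
        ]
        annot = ANNOT + [GeneAnnotation("REF", "chr3", 100_000, 120_000)]
        pos = pd.DataFrame(
            {"rsid": ["rs_a", "rs_b", "rs_c"], "chrom": ["chr1", "chr1", "chr3"],
             "pos": [150_000, 150_001, 110_000]}
        )
        links = link_evidence(variants, annot, pos)
        per_max, _ = score_core_genes(links, variants, LinkConfig(score_combine="max"))
        per_sum, _ = score_core_genes(links, variants, LinkConfig(score_combine="sum"))
        assert per_max["proximity"]["REF"] == pytest.approx(1.0)
        assert per_sum["proximity"]["REF"] == pytest.approx(10.0 / 18.0)

    def test_rescaled_scores_in_unit_interval_with_max_one(self):
        variants = [VariantRecord("rs4129267", 1e-12), VariantRecord("rs_far", 1e-9)]
        pos = pd.DataFrame(
            {"rsid": ["rs4129267", "rs_far"], "chrom": ["chr1"] * 2,
             "pos": [150_000, 290_000]}
        )
        per_pred, _ = score_core_genes(link_evidence(variants, ANNOT, pos), variants)
        for col in per_pred.values():
            assert (col >= 0).all() and (col <= 1).all()
            assert col.max() == 1.0

    def test_evidence_counts_match_link_table(self):
        variants = [VariantRecord("rs4129267", 1e-12)]
        qtl = pd.DataFrame(
            [["rs4129267", "IL6R", 1e-6, "eqtl"], ["rs4129267", "IL6R", 1e-4, "pqtl"]],
            columns=["rsid", "gene", "significance", "dataset"],
        )
        links = link_evidence(variants, ANNOT, POS, [qtl])
        _, summary = score_core_genes(links, variants)
        (cg,) = [s for s in summary if s.gene == "IL6R"]
        assert cg.evidence_counts["qtl"] == sum(
            1 for l in links if l.gene == "IL6R" and l.source == "qtl"
        )

    def test_empty_links_raise(self):
        with pytest.raises(EmptyResultError):
            score_core_genes([], [])

    def test_tighter_threshold_never_raises_scores(self):
        variants = [VariantRecord("rs4129267", 1e-12), VariantRecord("rs_far", 6e-8)]
        loose = LinkConfig(p_threshold=1e-6, window_bp=80_000)
        tight = LinkConfig(p_threshold=5e-8, window_bp=80_000)
        out_l = filter_and_expand(variants, None, loose)
        out_t = filter_and_expand(variants, None, tight)
        per_l, _ = score_core_genes(link_evidence(out_l, ANNOT, POS, cfg=loose), out_l, loose)
        per_t, _ = score_core_genes(link_evidence(out_t, ANNOT, POS, cfg=tight), out_t, tight)
        # rescaling is per-predictor; compare the set of scored genes instead
        scored_l = set().union(*(set(c.index) for c in per_l.values()))
        scored_t = set().union(*(set(c.index) for c in per_t.values()))
        assert scored_t <= scored_l
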