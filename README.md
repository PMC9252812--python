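# targetpri

Genetics-led, network-based prioritisation of disease target genes and
pathway crosstalk.

Most GWAS hits for common disease sit in the non-coding genome, so the gene
"under" a signal is rarely the gene the signal regulates, and the genes a
drug should target are often not the ones carrying variants at all. This
package implements the full prioritisation chain for turning a list of
disease-associated SNPs into a ranked, annotated set of candidate targets:

1. **Variant → core gene linking.** Input SNPs passing genome-wide
   significance (p < 5×10⁻⁸, strict) are expanded with linkage-
   disequilibrium proxies (R² > 0.8 in a chosen reference population) and
   linked to *core genes* through genomic proximity, e/pQTL associations
   and promoter-capture Hi-C contacts. Each evidence dataset yields a
   per-gene score in [0,1].
2. **Network propagation.** Core-gene scores seed a random walk with
   restart, p ← (1−r)·Wᵀp + r·p₀ (r = 0.75 by default, W the
   column-normalised adjacency of a confidence-filtered protein-interaction
   network). The stationary affinities rank core genes *and* peripheral
   genes that carry no direct genetic evidence — the omnigenic-model
   rationale.
3. **Priority rating.** One walk per evidence predictor gives a
   gene × predictor affinity matrix; per-column affinities become empirical
   p-values (rank/(N+1)) and are combined per gene with Fisher's method,
   X = −2Σln pⱼ ~ χ²(2k). Genes are ranked by combined p and rated on a
   0–5 percentile scale (top gene = 5).
4. **Pathway crosstalk.** On a network whose every edge occurs in ≥1
   curated pathway, the highest-rated connected subnetwork of a requested
   size is extracted by a prize-collecting Steiner tree heuristic
   (maximise Σ_{v∈S}(score_v − θ) over connected S, with θ tuned by
   bisection over score quantiles). Significance comes from a
   degree-preserving node permutation test.
5. **Annotation.** Hypergeometric pathway enrichment of the top 1% of the
   rating (BH-FDR controlled) and drug-repurposing tables mapping crosstalk
   genes to approved (phase-4) drugs and their indications.

A deterministic synthetic-fixture generator emulates every reference input
(genome annotation, GWAS + LD tables, QTL/PCHi-C evidence, STRING-like
interaction network, KEGG-like pathways, ChEMBL-like drug table) at toy
scale, including a planted high-scoring module for end-to-end recovery
tests — the package runs and is tested with zero downloads.

## Worked example

Generate a toy dataset (200 genes, 40 GWAS SNPs, one planted 10-gene
module) and run the full crosstalk-level prioritisation:

```sh
targetpri fixtures --n-genes 200 --n-snps 40 --planted-size 10 --seed 7 --out demo/inputs
targetpri prioritize-crosstalk \
  --variants demo/inputs/variants.tsv --ld demo/inputs/ld.tsv \
  --annotation demo/inputs/annotation.tsv --snp-positions demo/inputs/snp_positions.tsv \
  --qtl demo/inputs/qtl_blood_eqtl.tsv --qtl demo/inputs/qtl_plasma_pqtl.tsv \
  --pchic demo/inputs/pchic_monocyte_pchic.tsv \
  --edges demo/inputs/ppi_edges.tsv --pathways demo/inputs/pathways.gmt \
  --pathway-edges demo/inputs/pathway_edges.tsv --drugs demo/inputs/drugs.tsv \
  --nodes 12 --permutations 99 --seed 42 --out demo/results
```

which logs the run to stderr and finishes with

```
INFO targetpri.propagation: interaction graph: 183 nodes, 251 edges
183 genes, crosstalk of 9 -> demo/results
```

`demo/results/priority.tsv` ranks all 183 network genes; the head of the
table reads

```
gene   rank  rating       combined_p     fisher_stat  type  proximity  qtl  pchic
G064   1     5            0.0041126819   22.47193876  core  3          10   1
G058   2     4.972677596  0.009511845922 20.22661986  core  1          0    1
G183   3     4.945355191  0.01699336591  18.62593403  core  2          9    0
```

G064 is rated 5.0 (the top of the 0–5 scale): it is a *core* gene backed by
3 proximity links, 10 QTL rows and 1 PCHi-C contact, and its Fisher-combined
p across the evidence-specific propagation columns is the smallest. The
crosstalk stage returns a connected 9-gene, 8-edge subnetwork
(`crosstalk_nodes.tsv` labels each member `rating®rank`, e.g. `4.89®5`) with

```
subnet_score = 4.0984   theta_star = 4.3443
pvalue_empirical = 0.13 (B = 99)   pvalue_approx = 0.107
```

— on this small null-ish example the module is, correctly, not significant.
`enrichment.tsv` and `repurposing_detail.tsv` complete the annotation: the
top pathway here is PW06 (fold enrichment 7.6, p = 0.127) and three of the
crosstalk genes carry approved (phase-4) drug records.

Every output directory contains a `manifest.json` (resolved configuration,
input checksums, seed); re-running with the same inputs and seed reproduces
all result files byte-identically.

The same functionality is available as a library
(`targetpri.pipeline.run_prioritize`, `run_crosstalk`, `run_full`, and the
stage modules `linking`, `propagation`, `rating`, `crosstalk`, `annotate`).

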