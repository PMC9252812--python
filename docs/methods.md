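# Methods

This note documents the models and procedures implemented in `targetpri`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not emulate.

## Variant-to-core-gene linking (`targetpri.linking`)

**Filtering and LD expansion.** User SNPs are retained when their GWAS
p-value is *strictly* below `p_threshold` (default 5×10⁻⁸, the conventional
genome-wide significance level). When `include_ld` is on, proxies with R²
*strictly* above `r2_threshold` (default 0.8) in the chosen reference
population (default EUR; AFR/AMR/EAS/SAS supported) are added. Proxies
inherit their lead SNP's p-value, because association statistics are only
supplied for the user SNPs; a proxy reachable from two leads keeps the more
significant one. An empty post-filter set is an error telling the user to
relax the threshold rather than silently producing nothing.

**Evidence linking.** Three evidence sources define core genes:

* *proximity* — every gene whose body (1-based inclusive coordinates) lies
  within `window_bp` (default 50 kb) of the SNP position; the raw weight is
  the distance in bp, 0 inside the gene body;
* *QTL* — dataset rows whose SNP is in the retained set; the raw weight is
  −log10 of the variant–expression (or variant–protein) significance;
* *PCHi-C* — chromatin-contact rows for retained SNPs; the raw weight is
  the interaction strength.

**Scoring.** The per-link contribution is `snp_weight(p) × modifier`, where
`snp_weight(p) = min(−log10 p, 100)` (capped so one extreme association
cannot dominate) and the modifier is `1 − d/window_bp` for proximity under
linear decay (1 under constant decay) and `min(raw/w95, 1)` for QTL and
PCHi-C, with `w95` the 95th percentile of raw weights *within that
dataset*. The percentile saturation keeps a single extreme QTL or contact
from swamping its dataset while preserving ordering below the cap, and is
computed per dataset label because QTL significances and contact strengths
live on different scales. Contributions are combined per gene across SNPs
by `max` (default; `sum` available) and each predictor column is rescaled
to [0,1] by its maximum. The exact functional forms here are this package's
own choices — the scoring *considerations* (association strength, distance,
QTL significance, contact strength) are standard, their composition is not
canonical — so every form is exposed in `LinkConfig`.

## Network propagation (`targetpri.propagation`)

Random walk with restart on the undirected interaction graph:
p ← (1−r)·Wᵀp + r·p₀, with W the column-stochastic adjacency and p₀ the
seed scores normalised to sum 1. Power iteration stops when the L1 change
drops below `tol` (default 1e-10; the fixed-point residual is then below
10·tol) and errors out at `max_iter` (10,000) with the final residual.
The affinity vector is a probability vector: non-negative, sums to 1, zero
on components containing no seed.

Parameter choices:

* `restart = 0.75`: a common default for gene-network walks; higher r keeps
  mass near the seeds, lower r diffuses further. Seed-node affinity is
  non-decreasing in r (checked numerically in the tests).
* `edge_weighting = "unweighted"` by default: the interaction network is
  already filtered to a confidence tier on load (0.4 / 0.7 / 0.9 for
  medium / high / highest confidence, default ≥ 0.7), so edges at the
  chosen tier count equally. Confidence-weighted propagation is provided
  (`"confidence"`) since either convention is defensible.

Nodes exist only through edges, so the walk has no dangling columns.
Seeds absent from the graph are dropped with a warning; a run in which no
seed lands in the graph is an error.

## Priority rating (`targetpri.rating`)

Each evidence predictor (proximity, each QTL dataset, each PCHi-C dataset)
seeds its own walk, giving a gene × predictor affinity matrix whose columns
are probability vectors. Affinities are converted to empirical p-values by
descending rank: p = rank/(N+1) with midranks for ties, strictly inside
(0,1) so the downstream combination is always defined. This rank-based
bridge is deliberately distribution-free — affinity scales differ wildly
between predictors with different seed counts — and is the package's own
choice, as is the final rescaling. Per gene, Fisher's method combines the k
predictor p-values: X = −2Σln pⱼ referred to the upper tail of χ²(2k).
Genes are ranked by ascending combined p (ties: larger X first, then
symbol, making output bit-deterministic) and rated
`5·(N − rank + 1)/N` — equally spaced percentile scores in (0,5], top gene
exactly 5. No trimming or winsorising is applied to predictor columns
before combination. Core genes (≥1 direct evidence link) are flagged
against peripheral ones; core genes absent from the interaction network
cannot be rated and are emitted in a side table instead.

## Pathway crosstalk (`targetpri.crosstalk`)

**Objective.** On the pathway-derived network (union of per-pathway edge
sets, each edge annotated with its source pathways), find a connected node
set S maximising Σ_{v∈S}(score_v − θ) — the node-prize form of the
prize-collecting Steiner tree problem, NP-hard in general.

**Heuristic.** (1) positives P = {v : score_v > θ}; (2) shortest paths
between positives under edge length max(θ − min(endpoint scores), ε) with
ε = 1e-9, so paths prefer high-scoring intermediaries; (3) candidate
Steiner trees: the minimum spanning tree of the metric closure over P
expanded back to network paths, plus the shortest-path tree rooted at each
positive (the Dijkstra runs needed for the closure already yield them);
(4) each candidate is pruned by a post-order pass that keeps only child
branches with positive net prize — equivalently, the maximum-net-prize
connected subtree of that tree — then greedily absorbs adjacent
above-threshold nodes; the best-scoring candidate wins, per connected
component, and the best component is returned. When the positives induce a
connected subgraph the result is provably the exact optimum (the optimum
is then P itself, every candidate spans P, and pruning removes nothing);
on 500 random ≤10-node instances per seed the heuristic stayed within
98–100% of the exhaustive optimum and was exact on ≥ 99% of them.

**Size search.** θ is tuned by bisection over the unique score values
(plus a value below the minimum so the all-positive end is reachable):
larger θ → fewer positives → smaller subnetworks. The search stops at an
exact size hit or grid exhaustion and returns the θ whose *non-empty* size
is closest to `desired_nodes` (default 30), with ties resolved toward the
smaller θ, i.e. the larger subnetwork. `size_tolerance` (default ±5)
expresses how much deviation is acceptable when the grid admits no exact
hit. `desired_nodes="auto"` skips the search and takes θ at the 90th score
percentile.

**Significance.** Degree-preserving node permutation test: nodes are
binned into `degree_bins` (default 10) quantile bins by degree
(`degree_bins = 0` gives exact-degree groups for small networks), scores
are shuffled within bins, and the *full* size search is re-run per
permutation at the same configuration. Empirical
p = (1 + #{null ≥ observed})/(B+1), bounded below by 1/(B+1); B defaults
to 100 and must be ≥ 19. Because extreme significance is unreachable
empirically at affordable B, an upper normal-tail approximation from the
null mean and SD is always reported alongside (NaN when the null is
degenerate), clearly labelled — the two are not claimed equivalent.
Crosstalk nodes are labelled `rating®rank` (rating to 2 decimals) from the
priority table.

## Annotation (`targetpri.annotate`)

The top `ceil(fraction·N)` rated genes (default fraction 0.01; ceiling so
small inputs never select zero) are tested per pathway with the one-sided
hypergeometric upper tail. The universe is the rated population — the
propagation network's node set — not the whole genome, because the
selection was made from that population; pathway membership is intersected
with the universe before testing. Benjamini–Hochberg FDR is applied across
tested pathways and rows are sorted by ascending p with fold enrichment
reported. Drug repurposing keeps only approved (phase-4) records: rows are
crosstalk genes, columns indications, and each populated cell carries a
sequential index into a detail table of (drug, mechanism of action); genes
with no approved drug are listed separately. Target promiscuity filtering
is assumed already encoded in the supplied drug table.

## Synthetic fixtures (`targetpri.fixtures`)

The generators are pure functions of `(FixtureSpec, seed)`; each draws
from its own RNG stream derived from the master seed by a fixed offset, so
adding a generator never perturbs the others, and all outputs are
byte-identical across runs. Defaults are tiny (200 genes, 40 SNPs, 8
pathways) so the full pipeline runs in seconds.

What they emulate: genes tiled with gaps on four synthetic chromosomes; a
configurable fraction of SNPs within the 50 kb proximity window (the rest
on a gene-free chromosome, so only QTL/PCHi-C can link them); lead
p-values log-uniform on [1e-30, 1e-6] so both sides of the 5×10⁻⁸ cut are
populated; 0–3 EUR proxies per lead with R² uniform on [0.5, 1.0]
straddling the 0.8 cut; QTL and PCHi-C rows linking significant SNPs to
nearby and distal genes; a scale-free (Barabási–Albert, default) or
Erdős–Rényi interaction network with edge confidences uniform on
[0.3, 1.0] so all three confidence tiers are populated; pathways as
connected subgraphs whose induced edges form the pathway edge list; and a
drug table with a phase mix including approved entries.

Planted mode embeds a connected module of `planted_module_size` genes
inside one pathway and inflates its signal by `planted_effect`: at the
evidence level, each planted gene receives QTL rows whose −log10
significance is multiplied by the effect; at the score level
(`planted_node_scores`, used by the crosstalk recovery experiments), base
scores are i.i.d. uniform on [0.5, 1.5] and planted scores are multiplied
by the effect. An effect of exactly 1 leaves the data untouched null in
both modes.

What they do **not** emulate: realistic LD block structure, genome builds,
allele frequencies, cell-type-specific sharing between QTL datasets, or
the degree-confidence correlations of curated interaction databases.
Passing tests therefore demonstrate algorithmic correctness and
calibration under controlled conditions, not performance on real GWAS —
on real data the evidence layers are sparser, noisier and mutually
correlated.

## Problem sizes and numerical choices

The verification experiments use sizes chosen to make their statistical
claims testable in minutes on one core: the propagation oracle uses 200
random graphs of ≤50 nodes (L∞ agreement < 1e-8 with the dense solve;
convergence tolerance 1e-10, tightened to 1e-14 where a closed form is
checked to 1e-12); the subnetwork heuristic is compared with exhaustive
enumeration on 500 connected graphs of ≤10 nodes; permutation calibration
uses a 60-node scale-free network, 200 replicates at B = 99; planted-module
recovery a 500-gene network with a 10-gene module at effect 5. Ties are
everywhere broken deterministically (midranks in rank-based p-values;
Fisher statistic then symbol in the final ranking; lexicographic node
order in graph iteration), so identical inputs and seeds give identical
bytes. Degenerate inputs have defined behaviour: empty variant sets and
empty link sets raise instructive errors, empty crosstalk is representable
and skips the permutation test, a degenerate permutation null (SD = 0)
reports the normal-tail approximation as undefined while keeping the
empirical p.

## Known limitations

* The core-gene scoring forms are reasonable but not canonical; different
  decay or saturation choices reorder borderline genes. They are exposed
  as configuration for exactly that reason.
* The PCST heuristic carries no approximation guarantee on large
  networks; the exhaustive comparison certifies it only at small scale.
* The normal-tail permutation approximation assumes an approximately
  normal null of subnetwork scores; for heavy-tailed score fields it can
  be anti-conservative. The empirical p is the primary statistic.
* Multi-allelic or merged rsIDs are taken at face value; no liftover or
  identifier reconciliation is attempted.
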