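# Methods

This note documents the models and procedures implemented in `thermoss`, the
conventions fixed where the underlying workflows leave choices open, the
synthetic-data generator's design, and known limitations.

## Coordinate model and gene ranks

Coordinates are 1-based inclusive throughout (GFF3 native); the BED export
converts to 0-based half-open at the boundary. Genes on a chromosome carry a
0-based *rank* ordered by ascending start, ties broken by ascending end and
then lexicographic gene id; ranks are reassigned atomically whenever an
annotation is constructed. The intergenic spacer between rank-adjacent genes
is the number of bases strictly between the two gene bodies
(`b.start − a.end − 1`), clamped to 0 for overlapping bodies (logged). The
bound literature does not pin down whether "physical distance" includes
endpoint bases; this convention is declared rather than inferred. Strand is
stored but ignored by island scanning and adjacency analyses, which are
strand-agnostic procedures.

## Expression and differential expression

TPM is the usual within-sample normalisation:
`TPM_gs = (count_gs / length_g) / Σ_g (count_gs / length_g) × 1e6`; columns
sum to 1e6 within 1e-6 relative tolerance unless a sample is all-zero (kept
as zeros, with a warning).

A gene is differentially expressed in a contrast (each stress stage against
the H0 control) when its fold change exceeds 2 — i.e. |log2FC| > 1, strict —
with p < 0.05 on the raw p-value; no multiple-testing correction is applied
by default, mirroring the source analysis (a Benjamini–Hochberg flag
exists). The canonical source of log2FC and p is a plug-in table from a
count-model DE analysis (`thermoss.plugins.deseq2_de_table` produces one
with pydeseq2 when installed). Two self-contained stand-ins operate on
log2(TPM+1):

* **Welch t-test** per gene, with `log2FC = log2((mean_t + 1)/(mean_c + 1))`
  (pseudocount 1 avoids division by zero). At n = 3 vs 3 and
  negative-binomial dispersion 0.1 its joint power for a 4-fold effect is
  about 0.91 — adequate for screening, noticeably below the count-model
  test, which pools dispersion information across genes. Recovery
  experiments therefore run the plug-in route for DEG recall and the Welch
  route everywhere a stronger effect (island and module genes) is involved.
* **Exact label permutation**: two-sided p on the mean difference over all
  C(6,3) = 20 label assignments; the attainable grid is k/20 and, because
  complementary splits share the same absolute statistic, the minimum is
  2/20 = 0.1 — this method cannot reach p < 0.05 at 3+3 and is provided for
  designs with more replicates.

Pattern sets H1UP…H12UP (and DOWN) collect DEGs per contrast; union sets
deliberately allow a gene to appear in both the up and the down union (the
study's tallies overlap the same way).

## Duplication modes

Collinear blocks are chained on the gene-rank dot plot per chromosome pair:
chains must be strictly monotone on both axes (same or consistently inverted
orientation), with per-step rank gaps ≤ `max_gap` on both axes; chain score
is the anchor count; blocks need ≥ `min_block` anchors. Chains are extracted
greedily by score (ties to the leftmost start, same orientation first) and
each dot belongs to at most one chain. Defaults `min_block=5`, `max_gap=25`,
`proximal_window=10` follow the conventional duplicate-classification
workflow. One additional rule: an intra-chromosomal chain is only a block if
its two rank intervals are disjoint — the two copies of a real duplicated
segment occupy separate intervals, whereas runs of tandem/proximal pairs hug
the dot-plot diagonal and would otherwise masquerade as blocks.

Classification applies a fixed precedence per gene: (1) WGD if the gene
anchors any intra-genomic block; (2) TD if it has a homolog at the adjacent
rank on the same chromosome; (3) PD if a homolog lies within
`proximal_window` ranks; (4) TRD if exactly one member of its best-scoring
pair sits at a syntenic locus (an intra-genomic block anchor or a gene in a
supplied inter-species anchor list) — the syntenic member is the ancestral
copy, the other the novel copy; (5) DSD for any remaining homologous gene;
(6) singleton otherwise. "Best-scoring pair" is resolved by score, then
smaller rank distance, then lexicographic partner id — a declared convention
for multi-homolog genes. Note that a gene that is itself a block anchor is
WGD by precedence, so an ancestral TRD role in practice comes from the
inter-species anchor evidence; the novel partner of an intra-genomic anchor
still receives TRD/novel.

## Ka/Ks (NG86)

Codon pairs come from a global protein alignment (match 1, mismatch −1,
gap −2, deterministic first traceback) back-mapped to codons; gapped and
stop-containing columns are dropped. The estimator is classic
Nei–Gojobori (1986): per codon, the synonymous site count is the fraction of
one-step nucleotide changes that preserve the amino acid (over 3 per
position), averaged between the two sequences, so S + N = 3 × codons
exactly; differences at multi-hit codons are averaged over all shortest
substitution pathways with equal weights, excluding pathways through stop
codons (a codon pair whose every pathway hits a stop contributes sites but
no differences). Jukes–Cantor correction is applied separately to p_s and
p_n; p ≥ 3/4 is inapplicable and flags the pair saturated, as does
Ks > 5.0 — saturated pairs are excluded from all downstream summaries. Only
the universal genetic code is wired in (a table hook exists). The original
study used a model-averaged maximum-likelihood estimator; NG86 is used here
as a deterministic, fully specified, oracle-checkable alternative, and
outputs are labelled accordingly. Per-mode summaries report n, median and
quartiles of Ka/Ks plus two-sided Wilcoxon rank-sum p-values between modes.

## Islands

Candidate 50-kb windows are anchored at the start coordinate of every
expressed gene (mean TPM > 2 across samples, the same filter used for
co-expression input); a gene belongs to a window iff its start lies inside.
A window qualifies when it holds ≥ 3 pattern (upregulated) genes and these
are strictly more than 60% of its expressed genes. Overlapping qualifying
windows merge transitively; each merged region becomes one island whose span
is the min start to max end of its member pattern genes, so reported island
sizes are data-driven rather than window artifacts. Gene-anchored scanning
is a deterministic choice (the cited workflow does not state a step size); a
brute-force every-bp-offset oracle in the test suite verifies that every
island found is contained in an exhaustively qualifying region. Summaries
use SEM = sd/√n over islands and report duplicated members via the
duplication calls (mode ≠ singleton).

## Hub genes and neighbour groups

Module labels are an input; the package does not construct the co-expression
network. The module eigengene is the first principal component of the
z-scored (per gene) module expression across samples, sign-fixed so the mean
gene–eigengene correlation is non-negative (an exactly balanced
anti-correlated module leaves that sum at zero; the sign then follows the
largest-magnitude score). MM is the Pearson correlation of a gene's profile
with its module eigengene; GS is the Pearson correlation with the binary
indicator of the trait stage; the GS p-value is the t-test of a correlation
with n−2 degrees of freedom. Hub rule: MM ≥ 0.6 and GS ≥ 0.5 and p < 0.05,
on signed correlations (configurable). MM/GS are computed on log2(TPM+1).
Neighbour groups are maximal runs (≥ 2) of hub genes at consecutive ranks;
member duplication modes are reported, not filtered, so the observation that
such groups consist of non-duplicated genes can be checked.

## Contamination screen

Per query, coverage is the length of the union of hit intervals of one taxon
class divided by query length; overlaps count once. A query is removed when
non-target coverage is strictly greater than 50%. Positions hit by both
target and non-target subjects count fully toward non-target coverage (the
source rule mentions no subtraction); the output header records this
convention. Taxon classing of subjects is an input column; no taxonomy
database is bundled. Organelle screening is the same operation with
organelle references as the non-target class.

## Synthetic-data generator

The generator emulates the study design — 5 stages × 3 replicates — on a
4-chromosome, 1,000-gene genome that runs in well under a second, with every
planted entity recorded in truth tables the pipeline never reads. Design
choices, with defaults:

* **Layout**: gene lengths 300 + Exp(1200) bp, intergenic gaps
  100 + Exp(5900) bp (≈ 7.5 kb per gene footprint, close to the gene density
  of the real 26,898-gene/192-Mb genome); chromosome length from the layout.
* **Islands** (5): runs of 4–8 consecutive genes compacted to ≤ 40 kb
  (capped lengths/gaps) and flanked by one scan-window (50 kb) of gene-free
  buffer on each side, so a planted island satisfies the island definition
  by construction and recovery measures the pipeline rather than layout
  luck; members are upregulated 2^3-fold in the island's contrast. Real
  islands sit in fuzzier genomic context; passing recovery here shows the
  scanner finds rule-conforming clusters, not that the rule is robust to
  ambiguous real-world layouts.
* **Duplications**: 2 cross-chromosome blocks of 8 anchor pairs (WGD), 20
  tandem, 20 proximal (rank offset 2–10), 35 transposed (ancestral copy
  listed in the inter-species anchor table, novel copy on another
  chromosome), 30 dispersed; event gene sets are disjoint.
* **Counts**: negative binomial with dispersion 0.1 and log-normal
  baselines (log-mean log 500, log-sd 0.8 — bulk-RNA-seq-like depth for
  expressed genes; essentially all genes pass the mean-TPM > 2 filter, as
  the WGCNA-filtered real input did). Planted DE effects are ±2 in log2 at
  5% of genes per contrast, 38% up / 62% down, matching the study's
  up:down imbalance (3,819:6,253) and keeping library composition stable.
  Stress-induced module and island genes start from proportionally low
  basal expression (heat-shock-like), which also prevents normalisation
  from diluting the planted fold changes of other genes.
* **Modules**: a 60-gene heat module with log2 stage profile
  (H1:3, H3:1.5, H6:0.75), a 40-gene late module peaking at H12, and a
  60-gene trait-null module used to measure the GS false-positive rate.
  Ancestral TRD copies get 4× the baseline of their novel partners.
* **Ka/Ks divergence**: each pair descends from a random ancestral CDS of
  100 codons; per-mode synonymous/nonsynonymous per-codon mutation rates
  give TD/PD higher Ka/Ks than WGD (weaker purifying selection on
  single-gene duplicates), the ordering the divergence summary recovers.
* **Contamination**: 5 of 20 scaffolds receive non-target hit unions
  covering 55–90% of their length; the rest stay below 45%.

All randomness flows from a single integer seed; identical seeds yield
byte-identical output bundles.

What the generator does **not** emulate: read-level noise and mapping
artifacts, isoforms, batch effects, GC/length biases, overlapping or nested
duplication events, segmental duplications inside one chromosome, fuzzy
island contexts, and real taxonomic ambiguity in contamination calls.
Passing recovery tests therefore demonstrates correctness of the
implementations under the stated generative model, not robustness to every
feature of real data.

## Numerical choices and degenerate inputs

Ties in rank ordering, chain extraction and best-pair selection are all
broken deterministically (documented above), so every stage is reproducible
bit-for-bit. Zero-variance expression rows are dropped from eigengene
computation (warning); modules with no non-constant gene raise. Stages with
fewer than two TRD genes per role are skipped in the expression contrast;
modes with fewer than two unsaturated pairs are omitted from divergence
summaries — both with warnings. Identical sequences give Ka = Ks = 0 with an
undefined (NaN) ratio. Queries without hits are kept with zero coverage.

## Problem sizes

Recovery experiments average ≥ 20 independently seeded genomes of 1,000
genes; oracle-equivalence checks use 100 random 30-codon pairs (NG86),
50 random hit sets (coverage), random ≤ 50-gene genomes (classifier) and
random modules (eigengene). These sizes give stable averages for the rates
being estimated while the whole suite stays desk-scale.

## Known limitations

* NG86 is not the model-averaged estimator used by the original study;
  absolute Ka/Ks values differ, orderings in practice agree.
* The collinearity chainer is a deliberate simplification of MCScanX-style
  detection (anchor count as chain score, no E-value weighting, no HSP
  merging); it is not intended for real cross-species synteny.
* DEG power at three replicates with the Welch stand-in is materially below
  a count-model test; use the plug-in route for real analyses.
* Full co-expression network construction (soft thresholding, TOM, tree
  cutting) is out of scope; module labels must come from elsewhere.
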