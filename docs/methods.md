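# Methods

This note documents the models and procedures implemented in `limbgrn`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was open.

## Replicate-consensus peak combination

Peak callers report per-replicate peaks with −log10 p-value scores
(narrowPeak column 8). The consensus combiner admits a peak only if it
passes a *weak* threshold in its own replicate (default p ≤ 1e-6), groups
admitted peaks into connected components of the overlap graph (≥ 1 bp by
default), requires support from at least `min_replicates` distinct
replicates (default 2), and keeps a group when its Fisher-combined
p-value — X² = −2 Σ ln pᵢ against χ² with 2k degrees of freedom, k the
group size — passes a *stringent* threshold (default p ≤ 1e-10). The
consensus region is the union span of the group; its score is the combined
value; its fold enrichment is the maximum over members.

This is a transparent approximation to combined-evidence replicate mergers
in the MSPC family, whose internal confirmation iteration is not published
in a form we could restate; the weak/stringent thresholds map onto the
`-W`/`-s` parameters of such tools. For k = 1 the combined p equals the
member's p exactly, and raising the stringent threshold monotonically
enlarges the output, both of which are tested. Scores whose p-value
underflows to zero are clamped at −log10 p = 300 (configurable) and the
clamp is logged.

## Cistrome partition and chromatin overlay

All coordinates are 0-based half-open internally (BED convention);
GFF3/GTF input (1-based inclusive) is converted at the boundary. Merged
regions are classified A-only / B-only / co-bound by ≥ 1 bp overlap with
each factor's consensus set; the three counts are exhaustive and disjoint
by construction.

Genomic context uses a promoter window of TSS ± 2000 bp
(strand-independent width; the window itself is placed at the strand-aware
5′ end). The source study does not define "promoter"; ±2 kb is a common
cistrome convention and the width is a parameter everywhere it is used.
Precedence is promoter > intragenic > intergenic, so every region gets
exactly one context.

Chromatin evidence (H3K27ac, H3K27me3, ATAC, CTCF) is a boolean flag per
region (≥ 1 bp overlap) plus a signal value: the *maximum* −log10 p among
overlapping mark peaks, chosen over the mean for robustness to fragmented
mark peaks. Class-wise comparisons use Kruskal–Wallis (≥ 2 groups) or
two-sided Mann–Whitney (2 groups) with midrank ties. p-values are floored
at the smallest positive double and flagged, so "< floor" reporting is
reproducible and a p of exactly 0 is never emitted. Fully tied inputs are
special-cased to the null result because the rank statistics are undefined
at zero rank variance.

## DEG concordance

"Fold change ≥ 1.2" is interpreted on the linear scale and applied as
|log2FC| ≥ log2(1.2) ≈ 0.263, boundary inclusive, together with
FDR ≤ 0.05 (inclusive). The detection universe — genes detected in all
replicates of both contrasts — is applied *before* per-contrast
significance; the alternative (restricting only the intersection, not the
single-contrast sets) would change the a-only/b-only counts but not the
concordant/discordant classes, since a gene significant in both contrasts
must be detected in both. Sign pairs map to classes: (+,+) concordant-up
(repressed by both factors, since the contrasts are mutant vs control),
(−,−) concordant-down (activated by both), opposite signs discordant.
The DEG caller itself (edgeR/TMM) is upstream of this package; its output
schema (gene, log2FC, FDR, detection flag) is the input contract.

## Single-cell stage

QC keeps cells with total transcripts in [3000, 25000] (inclusive), at
least 1000 expressed genes, and mitochondrial fraction strictly below 10 %
("less than"). Normalization is ln(1 + 10⁴·count/total) per cell; this
replaces variance-stabilizing transforms whose regularized NB regression
is a package internal rather than a defined computation, and none of the
downstream statistics here depend on more than a monotone per-gene
transform.

Clustering is a pluggable contract `(reduced matrix, resolution, seed) →
labels`; the reference implementation builds a k-nearest-neighbor graph
(k = 15) on the top principal components (60 by default) and runs Leiden
community detection. The resolution grid 0.2–2.0 in steps of 0.1 is
scanned and the solution with the highest mean silhouette over cells
(Euclidean, on the PC representation) is kept, ties broken toward the
lowest resolution; a run where every resolution yields one cluster is an
error, not a silent answer.

Markers are Wilcoxon rank-sum tests per cluster versus the rest, testing a
gene only if it is expressed in ≥ 10 % of either compartment and the mean
log-expression difference is ≥ 0.25, with Benjamini–Hochberg correction
within cluster.

The co-expression statistic is the AUROC of a gene's normalized expression
classifying *double-positive* cells against background cells, computed as
the Mann–Whitney U divided by n₁·n₂ with midrank ties — hence invariant
under any strictly monotone transform of expression, which is tested.
Double positive is defined as raw count > 0 for Hand2 AND for at least one
of Pbx1/Pbx2, evaluated within the mesenchymal compartment; the expression
floor is configurable because the source analysis never formalizes the
definition. Genes pass at AUC ≥ 0.55. In the orchestrated pipeline the
background set is the double-positive cells' own cluster minus the double
positives: against a background spanning all mesenchymal clusters, every
marker of the co-expressing cluster would trivially exceed the threshold,
and the screen would measure cluster identity rather than co-expression
with the two factors.

Module scores are the mean normalized expression of a gene set minus that
of control genes sampled (seeded, without replacement) from the same
average-expression bins (24 bins, 100 controls per set gene, whole bin if
smaller) — the binned-control construction familiar from Seurat's
AddModuleScore. When the sampled controls coincide with the set the score
cancels to exactly zero, which is used as a correctness check.

## Enhancer prioritization and TAD scores

Within a TAD, each consensus TF peak becomes a candidate with six flags:
replicated binding (input contract), fold enrichment ≥ 15 (inclusive), no
promoter overlap, H3K27ac overlap, ATAC overlap, conserved-element
overlap, each by ≥ 1 bp; `passes` is their conjunction, and stricter
settings (higher fold floor, wider promoter windows) can only remove
candidates.

The TAD regulatory score is computed on the union-merged distal
(non-promoter) sites of the given consensus collections inside the TAD:
the site count and the summed per-site strength, where a merged site's
strength is its best member −log10 p. The source study reports "number and
individual strength" without a formula, so both quantities are reported
and the DEG-vs-non-DEG comparison (one-sided Mann–Whitney, DEG TADs
greater) is run on each. Transgenic reporter outcomes are ledger inputs
(element, previously-known flag, tested, any-tissue activity, reproducible
limb-domain activity), tallied by cardinality; previously known plus newly
reproducible gives the total validated count.

## Cross-tissue analysis

Overlap summaries are computed on the merged-region universe of all
tissues' cistromes: each universe region's tissue membership gives the
Venn counts; a tissue's shared fraction is the share of its own peaks that
touch an all-tissue core region. The cofactor-selection fraction uses the
cofactor-peak denominator — (cofactor peaks overlapping ≥ 1 factor peak) /
(all cofactor peaks) — with numerator and denominator exposed so the
alternative factor-peak denominator can be audited; the published
percentages do not disambiguate the denominator. Signal comparisons take a
normalized per-region signal table as given (normalization is an input
contract, per-million scaling recommended) and compute
log2((a + 1)/(b + 1)) with a pseudocount guarding zeros, followed by a
two-sided Mann–Whitney between region subsets.

## Mutagenesis planning

The substitution map T→C, A→C, C→A, G→A is total on {A,C,G,T} with no
fixed points, so every core base counts as altered and
`n_bases_altered` equals the number of distinct core positions
(overlapping cores are edited once). Printed 1-based site positions are
taken as core starts (offset 0) by default, with per-site core length and
offset as inputs — the exact PBX/PBX-HOX core boundaries are not
derivable from the published positions, so they are never invented
silently; the equal-altered-bases property across designs is *checked*
(`compare_designs`), not enforced. Application guards against stale plans
by verifying each edit's reference base.

## Synthetic data

The generator is a pure function of `SimConfig`; a fixed seed gives
byte-identical files, and truth labels live in sidecar TSVs only. Default
scale (chosen once as a realistic desk-scale analogue of the study
conditions): a 2 × 30 Mb genome, 300 genes on a regular grid inside 20
TADs, ~1300 TF binding regions with a 30 % planted co-binding rate on the
factor-A regions, +3 planted −log10 p accessibility/H3K27ac shift at
co-bound sites, replicates as jittered copies (centers N(0, 20 bp), scores
N(0, 0.5)) plus irreproducible single-replicate peaks for the consensus
stage to reject; DEG tables with 20/15/10 planted
concordant-up/concordant-down/discordant genes at |log2FC| ≥ 1 and 30+30
single-contrast genes; negative-binomial UMI counts (dispersion θ = 2) for
1000 cells × 1500 genes in three mesenchymal-like clusters with 20 markers
each, a 300-cell double-positive subpopulation (Hand2 mean 10 there, ~0
elsewhere; Pbx1/Pbx2 broad) and 7 planted co-expressed targets elevated by
1.5 log-units, 50 flagged mitochondrial genes at a 4 % baseline fraction,
and 20 planted QC-failing cells (low/high total, high mito); one TAD with
5 passing enhancer candidates and 10 candidates each violating exactly one
filter; three-tissue cistromes with a 600-region common core and cofactor
peaks planted at 48 % / 18 % selection rates; and a signal table with a +1
planted log2FC shift at cofactor-co-bound regions.

The subpopulation and group sizes were set so the statistical properties
the tests assert are actually decidable: with ~300 double positives
against ~300 within-cluster background cells the null AUC standard
deviation is ≈ 0.024, keeping well over 95 % of unplanted genes below the
0.55 threshold while planted targets sit near 0.85. The gene universe
(1500) exceeds the 1000-expressed-genes QC floor so the study's own QC
thresholds remain satisfiable.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: read-level noise and peak-caller artifacts (inputs
start at peak calls), correlated fragment structure and copy-number bias
in ChIP signal, ambient RNA and doublets in the single-cell matrix,
realistic gene-length/GC structure, promoter-proximal TF binding (TF
sites are placed distal to promoters by design, matching the analysis's
distal-element focus), and any dependence between the DEG tables and the
binding landscape beyond TAD co-location. Recovery results on this
landscape demonstrate correctness of the bookkeeping and statistics, not
robustness to real-data pathologies.

## Numerical choices and degenerate inputs

- p-values from rank tests are floored at the smallest positive double;
  fully tied groups short-circuit to the null result.
- −log10 p scores above 300 (p underflow) are clamped and logged.
- Silhouette ties break toward the lowest resolution; single-cluster
  grids raise.
- Zero-total cells stay zero under normalization (with a warning); a QC
  filter that removes every cell warns rather than errors.
- Empty peak collections partition to an empty labeled set with a warning;
  an empty cofactor set is an error because its fraction is undefined.
- All randomness flows from explicit integer seeds (NumPy Generator
  streams keyed by (seed, stream id)); the pipeline report contains no
  timestamps, so identical configurations reproduce byte-identical
  outputs.

## Problem sizes

The bundled tests and the acceptance script run the generator at the
default scale above (a full pipeline pass takes well under a minute on one
CPU); oracle-equivalence checks use 200-peak overlap instances, 1000
random replicate pairs for the Fisher/χ² comparison, vectors ≤ 20 for
AUROC pair counting, and n ≤ 8 per group for exact permutation
enumeration of the Mann–Whitney p.
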