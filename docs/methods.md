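# Methods

This note records the statistical models, algorithmic conventions and design
choices behind `balfkit`, at the level a maintainer or reviewer needs to
judge what the tests do and do not demonstrate.

## 3'-UTR extension

Droplet 3' chemistry concentrates reads at transcript 3' ends; when a
genome annotation truncates UTRs, reads just downstream of the annotated end
are not counted. The extension rule is deterministic: for a transcript on
the `+` strand with end *e*, the candidate extension interval is
[*e*+1, *e*+L] (L = 2,000 bp by default); on the `−` strand, with start *s*,
it is [*s*−L, *s*−1]. The interval is clamped at position 1 and, when the
sequence length is known, at the sequence end. If the interval overlaps any
*gene* record's span — on either strand by default, since an overlapping
gene on either strand makes read assignment ambiguous; a `same-strand` mode
is available for users who accept antisense overlap — the transcript is
skipped (`blocked_overlap`) or, under `on_overlap=truncate`, extended to
1 bp short of the nearest blocker. A transcript's own parent gene and its
sibling isoforms never block it; otherwise no multi-isoform gene could ever
extend. The transcript record, its 3'-most exon and the parent gene span move
together, because downstream UMI counting is exon-based: extending only the
transcript line would change nothing.

Where the original curation of such extensions was manual, this module
replaces judgment with the deterministic rule plus a per-transcript report
(status, old/new 3' end, blocking gene) so a curator can review or override
externally. Overlap queries use an interval tree; the test suite checks the
blocked/extended partition against an independent brute-force O(n²)
all-pairs oracle on randomized annotations, under both overlap scopes.

Coordinates are GFF3 throughout: 1-based, inclusive. GTF input is accepted
via a dialect flag that maps `gene_id`/`transcript_id` attributes onto the
same internal model.

## QC

Per-cell metrics are the detected-gene count, total counts, and the
mitochondrial percentage over a user-supplied gene list or symbol prefix
(default `MT-`, case-insensitive — the mitochondrial gene set of a non-model
species is a config input, not a hard-coded list). Cells are removed when
`n_genes < 200`, `n_genes > 6500` or `pct_mito > 15`; the inequalities are
strict, so boundary cells survive. "Fewer than 200 genes" and "more than
6,500 gene features" are treated as two thresholds on the same quantity
(detected features). An all-zero cell has `pct_mito` defined as 0; it is
removed by the gene floor regardless. Filtering is idempotent and
order-independent, and the report lists every barcode with the violated
criterion.

## Normalization, HVG selection, PCA

Normalization is global scaling: counts per 10,000 per cell, then natural
log1p; zero counts stay zero, so sparsity is preserved. HVG selection is the
variance-stabilizing procedure: per-gene mean and variance on raw counts; a
lowess trend of log₁₀(variance) on log₁₀(mean) fitted over non-constant
genes with span 0.3 (statsmodels' local-linear lowess; the quadratic
local fit used elsewhere differs negligibly at these gene counts); counts
standardized by the trend's predicted standard deviation and clipped above
at √n_cells; genes ranked by the variance of the clipped standardized
values, top 2,000 flagged. Constant genes get standardized variance 0 and
can never outrank a varying gene.

The HVG submatrix of the normalized data is z-scored per gene (ddof = 1),
clipped to ±10, and embedded with PCA (ARPACK solver with a seeded start
vector when n_pcs is below the smaller dimension, exact otherwise). Each
component's sign is fixed so its largest-magnitude loading is positive,
making the embedding solver-independent and bitwise reproducible. The number
of PCs is a config choice (elbow-plot selection is human judgment); the
shipped presets are 16 PCs at resolution 1.0 for a full BALF cohort and
13/1.2, 11/0.5, 8/0.7 for the Mo/Ma, T and B/plasma sub-analyses.

## SNN graph and Louvain

Exact Euclidean k-nearest neighbors (k = 20) with each cell included in its
own neighbor set — self-inclusion changes the Jaccard weights and is the
convention of the graph construction this mirrors. Edge weight between two
cells is the Jaccard similarity of their neighbor sets; edges with weight
≤ 1/15 are pruned. Community detection is Louvain (igraph's multilevel
algorithm) maximizing modularity under the resolution-parameterized
configuration null. Vertices are processed in canonical barcode order, so
permuting the input cells permutes the labels identically; the igraph RNG is
seeded through Python's `random` module, and labels are canonicalized by
decreasing community size with ties broken by lowest member index. Isolated
vertices become singleton communities.

A homogeneous population larger than a few hundred cells is routinely split
by modularity optimization at resolution 1.0 — that is expected behaviour,
mirrored in real cohorts where ~16 clusters collapse into six major types.
Recovery of planted structure is therefore evaluated on the *typed* labels
(clusters merged by marker-panel assignment), not on raw community ids.

## Module scores and type assignment

All genes are ranked by mean normalized expression and cut into 24
equal-size bins. For each panel gene, 100 control genes are drawn from its
bin (seeded; with replacement when the bin is smaller). The per-cell score
is the mean expression of the panel genes minus the mean of the drawn
controls (draws keep multiplicity). This cancels depth and baseline
effects: a random gene set has score ≈ 0.

Cluster assignment computes each panel's mean score over the cluster's
cells and takes the argmax, guarded two ways: the top score must be
positive, and must exceed the runner-up by a margin (default 0.05).
Otherwise the cluster is `unassigned`. The guard values are this package's
own device for making an otherwise subjective annotation step deterministic;
both are configurable. A convenient side effect: heterotypic doublet
clusters score high on two panels at once and fall into `unassigned` rather
than contaminating a class. Cell-cycle calling computes S and G2M module
scores and labels a cell `cycling` iff G2M > S (ties resting) — a two-state
convention; a three-phase mode (G1 when both scores ≤ 0) is available.
Ribosomal-protein genes are not filtered anywhere by default (filtering them
has been reported not to change clustering); a symbol-prefix exclusion is
available in config.

## Marker detection

One-vs-rest per cluster. Genes are pre-filtered to
`max(pct_in, pct_out) ≥ 0.1` and `avg_log2FC ≥ 0.25`, where
`avg_log2FC = log2(mean(expm1 x_in) + 1) − log2(mean(expm1 x_out) + 1)`
(de-logged means with pseudocount 1). The test is the two-sided Wilcoxon
rank-sum. For groups of ≤ 25 cells each, the p-value is exact: the
permutation distribution of the rank-sum statistic over all C(n, n₁)
assignments is computed by a generating-function dynamic program over
doubled midranks (integral even with ties), giving
P(|W − E[W]| ≥ |w − E[W]|) without enumerating subsets. For larger groups,
the normal approximation with tie-corrected variance (no continuity
correction) is used; the test suite verifies its empirical type-I error at
α = 0.05 under a seeded null stays within 0.05 ± 0.02 (observed ≈ 0.051). Benjamini–Hochberg adjustment runs
over the tested genes of each cluster; rows failing adj. P < 0.05 or
log₂FC > 0.25 are kept but flagged not-significant. Score comparisons
across groups use Kruskal–Wallis with tie correction (which reduces to the
rank-sum test for two groups).

## Synthetic cohort generator

The generator emulates the statistical structure of a droplet BALF
experiment; its defaults are the study conditions all planted-recovery tests
run under.

* **Composition**: six populations at the mean of the published per-horse
  scRNA-seq differential cell counts — lymphocytes 77.1% (split 0.95 T :
  0.05 B/plasma), macrophages 12.7% (split 0.9 Mo/Ma : 0.1 DC), neutrophils
  8.3%, mast cells 1.9%, eosinophils 0.
* **Expression**: gene baseline rates are log-normal (log-mean 0,
  log-sd 1). Each population's canonical panel plus 30 synthetic signature
  genes are multiplied 8-fold. Panels of 2–4 genes alone cannot make six
  populations separable in 16 PCs; the signature program stands in for the
  hundreds of co-regulated genes that distinguish real cell types. Marker
  and signature genes get a high baseline (log-mean +2.0, log-sd 0.25)
  because canonical markers — CD163 in alveolar macrophages, the CD3 complex
  in T cells, MS4A2 in mast cells — are among the most abundant transcripts
  of their cell types, not average genes.
* **Counts**: negative binomial with shared dispersion (size 10), mean =
  concentration × per-cell depth; depth is log-normal with median 2,500 UMIs
  (log-sd 0.35), matching the reported per-cell UMI medians. Shared
  dispersion is the minimal over-dispersed count model; per-gene dispersion
  is not modelled.
* **Mitochondria**: 13 mito genes (the protein-coding mitochondrial genome)
  receive a per-cell fraction of the library, normal around 4% (sd 1.5%,
  clipped to [0.5%, 10%]).
* **Planted QC failures**: at the observed failure rate of the sequenced
  cohort (777/5,408 ≈ 14.4%), half as cells down-sampled to 60–140 total
  counts (necessarily < 200 detected genes), half re-weighted to a 25–35%
  mitochondrial fraction. Background parameters leave non-planted cells many
  standard deviations away from every threshold, so the planted violations
  are exactly the removed cells; a dedicated 5,408-cell configuration
  reproduces the 777-removed / 4,631-kept arithmetic.
* **Doublets**: 2% of cells are monocyte×T "complexes" whose concentration
  vector is the normalized sum of the two parent programs, with depth
  inflated 1.5× — heterotypic rate-sums matching the observed
  halfway-between expression profile of monocyte–lymphocyte complexes.

What the generator does *not* model: ambient RNA, batch effects, per-gene
dispersion, within-type substructure (the 16-cluster fine structure of real
BALF is not quantitatively specified anywhere, so only the six major types
plus optional user-defined subtypes are planted), or read-level artifacts.
Passing recovery tests therefore demonstrate that the pipeline's
computations are unbiased and correctly wired on data of realistic size,
sparsity and noise — not that they overcome artifacts the generator omits.

Determinism: one `numpy` Generator seeded from the config drives every draw
in a fixed order (cells chunked in blocks of 512), so a fixed seed gives a
bitwise-identical matrix and truth table.

## Evaluation conventions

* Planted-type recovery is measured on QC-surviving singlet cells: ARI
  between planted populations and per-cell *typed* labels (clusters merged
  by panel assignment), plus the requirement that every cluster's assigned
  type equals its dominant planted population. Doublets are excluded from
  this metric — they have no single true class and the pipeline deliberately
  ships no doublet-removal stage; they are assessed by their own criterion
  (≥ 90% of planted doublets score positive on both parent panels).
* Class-proportion recovery (the differential-cell-count check) is likewise
  computed over singlets on both sides, isolating the question it answers:
  whether clustering, typing and the cytology-class collapse distort
  proportions. It does not certify the cytology-vs-scRNA-seq discrepancy
  itself, which on real data has upstream causes (cell-size selection,
  RNase content, counting bias) outside this package's scope.
* Ratios and percentages are displayed half-up rounded to 1 decimal, the
  convention of printed clinical tables; unrounded values are retained
  internally so rounding never compounds. Printed percentage columns may sum
  a few tenths off 100 (per-class rounding), so the validity band on a
  percentage vector is 100 ± 0.5.

## Problem sizes

Full-scale checks run at the study's scale: 5,000 cells × 10,000 genes
(5,408 for the QC-arithmetic cohort), five seeds for recovery. Unit tests
use 300–800-cell cohorts with the same composition. The calibration null
uses 200 cells × 2,000 genes per replicate.

## Known limitations

* The lowess trend is local-linear; extremely high-mean genes can get a
  slightly different predicted variance than a quadratic local fit would
  give, which can reorder genes near the HVG cutoff.
* The exact rank-sum p-value is exact for the *statistic's* permutation
  distribution given the observed (mid)ranks; like every rank test it
  conditions on the tie pattern.
* `unassigned` clusters are excluded from the DCC denominator with a
  warning; a cohort whose doublet rate is far above a few percent will
  shrink the denominator noticeably.
* GTF parsing requires explicit `gene` and `transcript` lines (as in
  Ensembl-style GTFs); implied parents are not synthesized.
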