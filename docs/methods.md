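# Methods

`spatlas` implements the analytical core of a whole-brain MERFISH cell-atlas
pipeline: barcode and panel design for the imaging experiment, QC and
normalization of the resulting cell-by-gene tables, transfer of a reference
taxonomy onto the imaged cells, and the downstream spatial statistics
(modules, gradients, proximity interactions, ligand–receptor screens).
This note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Barcode codebook

MERFISH encodes each gene as a binary word read out over sequential imaging
rounds. The codebook used here is the maximum-size binary code with
constant Hamming weight 4 and pairwise Hamming distance ≥ 4 — equivalently
a Steiner quadruple system SQS(n): a family of 4-subsets of n bit positions
covering every 3-subset exactly once, of size C(n,3)/4. We build SQS(n)
for n a power of two by the classical doubling construction: SQS(2n) is the
union of two relabeled copies of SQS(n) plus cross blocks pairing
same-index one-factors of K_n on each copy. The one-factorization is the
round-robin (circle) construction and the cross pairing is the identity, so
the output is deterministic. For n = 32 this yields 1,240 words; assigning
1,124 panel genes leaves 116 blank barcodes, whose decoded counts estimate
the false-positive rate. Gene-to-word assignment is random under a seed
and is not expected to match any particular experiment's mapping; only the
set sizes and the code's weight/distance properties are contractual, and
`verify_codebook` checks them exhaustively (O(size²), < 1 s at 1,240).

## Panel selection

Candidates come from an all-ordered-pairs differential-expression screen on
a clustered reference: fold change ≥ 2 between the clusters, p < 0.01,
foreground expressing fraction ≥ 0.5, and a > 3.3-fold enrichment of the
expressing fraction; the 50 smallest-p qualifiers are kept per pair and
direction. The screen's test statistic is not pinned down by the pipeline
definition; we use the two-sided Wilcoxon rank-sum test, the standard
choice for scRNA-seq DEG screens, and record it in the config so it can be
swapped. A background expressing fraction of zero gives an infinite
enrichment ratio (passes), the limiting case. Genes accommodating fewer
than 40 encoding probes or exceeding 3,000 mean counts in their top cluster
are excluded (boundary values retained: "fewer than 40" keeps 40). Panel
completion is greedy set cover over (cluster pair, direction) slots: add
the candidate covering the most slots still below the target of three,
breaking ties by aggregate p then gene name, until every slot is satisfied
or no gene helps; pairs with no candidates are reported as uncoverable.
Curated marker lists enter as seed genes — curation itself is not
algorithmic.

## Preprocessing

Five steps, in order: (1) volume filter — cells outside [50, 1500],
[80, 2500], [100, 3000] µm³ for 3-, 5-, 6-z-plane measurements are
segmentation artefacts or z-overlaps and are removed (boundaries retained);
(2) counts divided by imaged cell volume; (3) each experiment rescaled so
the mean per-cell total is 250; (4) cells in the top/bottom 1% total-count
quantiles removed, computed per experiment with linear-interpolation
quantiles (the convention shifts removals by at most one cell per tail);
(5) cells with precomputed doublet scores > 0.25 removed. Doublet scoring
itself is upstream and consumed as a column.

## Integration and imputation

Label transfer runs in two rounds because a single co-embedding cannot
resolve thousands of clusters at once.

* **Partitioning.** The reference, restricted to panel genes, is
  normalized (total 1,000, log1p, per-gene z-score), reduced to ≤ 100 PCs,
  and a 15-NN graph built. Subclasses become nodes of a connectivity graph
  whose edge weights count cross-subclass kNN edges; the graph is cut into
  K (default 50) partitions that balance cell counts while minimizing cut
  weight. We use recursive spectral bisection (Fiedler-vector ordering,
  balanced split point, greedy single-move refinement) under a ±20%
  balance constraint; any partitioner meeting the balance/cut contract is
  acceptable, and the result is deterministic under the seed.
* **Co-embedding.** Diagonal-covariance CCA, the convention of single-cell
  integration tools: truncated SVD of the cell-by-cell cross product of the
  two scaled matrices, fit on ≤ 100,000 downsampled cells per side, with
  all cells of both datasets projected through the induced linear maps from
  gene space and each embedding row L2-normalized.
* **Anchors and transfer.** Anchors are mutual 5-nearest-neighbour pairs
  across datasets in the co-embedding. A query cell's label is the
  plurality label among its 100 nearest anchor reference cells, its
  confidence that label's fraction (unweighted; ties break to the
  lexicographically smallest label). Round one transfers partition labels;
  round two repeats the embedding per partition on partition-specific
  highly variable genes (normalized log dispersion > 0, Seurat-style
  binning) and transfers subclass and cluster labels. Final confidences
  multiply the within-partition confidence by the partition confidence;
  cells pass at adjusted subclass confidence ≥ 0.8 and cluster confidence
  ≥ 0.5 (inclusive).
* **Imputation.** A query cell's transcriptome-wide profile is the
  weighted average of its 30 nearest anchor reference cells, with Gaussian
  weights exp(−d²/σ²), σ the distance to the 30th anchor. The kernel form
  is a choice (only "distance-based" is prescribed); imputed values are
  convex combinations of anchor profiles by construction.

## Annotation statistics

Neurotransmitter flags derive from canonical transporter genes (Slc17a7/6/8
for glutamate, Slc32a1 GABA, Slc6a4 serotonin, Slc6a3 dopamine, Slc18a3
acetylcholine, Slc6a5 glycine, Slc6a2 noradrenaline, Hdc histamine) at a
threshold of ≥ 2 counts per cell; flags are independent, so co-release
(e.g. glutamate/GABA) is representable. Regional enrichment of a subclass
is [n(s,r)/N(r)] / [n(s)/N] — cell counts proxy regional volume, which
cancels in the density ratio; a volume table can be supplied to override.
The density-weighted mean of a subclass's enrichment across regions is 1
by construction, which the tests assert. Local complexity is the number
of distinct neuronal subclasses among a cell's 50 nearest within-section
neighbours.

## Spatial modules

Each cell's neighbourhood is summarized by a weighted composition vector
over its 50 within-section nearest neighbours, neighbour j contributing
exp(−(D_ij/D_i⁰)²) to its type's entry. The bandwidth D_i⁰ adapts to
local density: 2× the distance to the cell's 5th nearest neighbour at
level 1, 1× at level 2. Vascular and immune cells are excluded (they are
near-uniformly distributed and dilute regional signal). Vectors are
L2-normalized, a 15-NN graph built, and Leiden applied (resolution 1.0 /
2.0 at levels 1/2 by default — the published analysis states none, so they
are config-exposed). Level 2 reruns per level-1 module on neurons only,
concatenating subclass- and cluster-level vectors.

Leiden systematically over-partitions regions of *uniform* composition:
nearly identical vectors have a kNN graph that mirrors spatial adjacency,
so uniform domains shatter into spatial chunks — the same phenomenon the
original analysis resolved by manually merging clusters without clear
spatial boundaries. We replace that curation with two programmatic steps:
first merge modules whose centroid composition vectors have cosine
similarity ≥ 0.98 (indistinguishable profiles), then absorb modules below
200 cells into the module holding the majority of their members' spatial
neighbours, iterated to a fixed point.

## Gradients

Cluster discreteness: a cell's neighbourhood purity is the fraction of its
50 nearest expression-space neighbours (50-dimensional PCA of the
log-normalized layer) sharing its cluster label; cluster discreteness is
the mean member purity and subclass discreteness the median over its
clusters. Spatial gradients are quantified by Pearson correlation between
a 1-D expression axis and a spatial coordinate. The axis is either PC1
(sign fixed so the largest-|loading| gene loads positively) or a
pseudotime, implemented as the first nontrivial eigenvector of a
symmetrized adaptive-Gaussian kNN diffusion kernel on the PCA embedding,
oriented to correlate positively with PC1. Both are centered, making
outputs reproducible despite the inherent sign ambiguity. Cortical depth
or any other coordinate is consumed as a column, not computed.

## Cell–cell interaction testing

Within each region, cells at subclass confidence ≥ 0.8 are tested for
every pair of shortlisted subclasses: neuronal subclasses need regional
enrichment above 6 in the six high-complexity split regions
(anterior/posterior hypothalamus and midbrain, pons, medulla) or 2
elsewhere; astrocytes need ≥ 1; other non-neuronal subclasses need > 50
cells. Hypothalamus and midbrain split anterior/posterior at the midpoint
of their ccfx range (ties anterior); the hindbrain splits into pons and
medulla via supplied anatomical labels.

Proximal pairs are cross-type centroid pairs within R_proximal (15 µm
strict — about one soma diameter — or 30 µm relaxed) in the same section.
The null redistributes every cell uniformly within a 100 µm disk of its
position, 1,000 times, recounting pairs each round and fitting a normal;
the observed count is scored one-sided (enrichment only), BH-adjusted
across all (region × pair) tests, and a pair is called at p_adj < 0.05
with ≥ 50 observed pairs; the relaxed regime additionally requires at
least one upregulated ligand–receptor pair. Displacements are *reflected
at the per-section bounding box* of the analyzed cells: without
reflection the randomized pattern spreads beyond the imaged tissue,
diluting the null density and producing systematic false enrichment
(~17% of CSR pair-tests at p < 0.05 in our measurements); a uniform
pattern is exactly invariant under reflected displacement, restoring
calibration. A degenerate null (std 0) reports p = 1/(rounds+1) when the
observed count exceeds the null mean, else 1. Depletion is visible as
fold change < 1 but never called significant.

## Ligand–receptor and gene upregulation screens

For LR pair k and cells i, j the score is S = log(1 + Π_{p,q} L_p·R_q)
(natural log) over all ligand × receptor component combinations, so any
absent component of a complex zeroes the score. Scores are computed on
imputed expression — continuous and zero-free — which is what makes
multiplicative folds interpretable. Proximal-pair scores are compared
with an equal-size uniform sample of non-proximal (> R_proximal) cross
pairs by a one-sided Welch t-test (hand-implemented with
Welch–Satterthwaite degrees of freedom; p = 0.5 when both samples are
constant and equal), BH-adjusted per run; a pair is called at fold ≥ 2,
p_adj < 0.01, and nonzero scores in ≥ 40% of proximal pairs. Both
orientations (A ligand → B receptor and the reverse) are tested. The gene
screen splits type-A cells by whether any type-B cell lies within
R_proximal and Welch-tests each highly variable gene at fold ≥ 2,
p_adj < 0.01. Pathway summaries report, per pathway, the significant pair
with the highest fold.

## Synthetic data

The generator produces every structure the analyses assume, with ground
truth: per-section homogeneous Poisson point patterns per type within
rectangular domains (intensity = base intensity × mixture weight; default
base ~1,200 cells/mm², matching adult mouse brain cell densities at the
10 µm section thickness); negative-binomial counts parameterized by
cluster mean and dispersion with Poisson as the infinite-dispersion limit,
means scaled by cell volume; log-linear expression gradients along a
configurable axis; doublet scores drawn directly on either side of the
0.25 threshold (scoring is out of scope); and a dissociated reference
sharing cluster means over a superset of the imaged panel.

Attraction between types relocates a configurable fraction of type-B cells
to uniform positions within a radius of type-A cells — relocation, not
thinning, so per-type densities are untouched and the interaction null
(which preserves density) is probed purely through pairing. Partners are
drawn *without replacement* where possible: letting several B cells share
one A target manufactures same-type B–B clumping as a side effect, which
the interaction test then detects as a real (but unintended) signal.
LR upregulation multiplies ligand components in type-A cells proximal to
type B (and receptor components reciprocally) by a configurable fold.

What the generator does not emulate: realistic brain geometry and region
shapes, segmentation errors, spatial autocorrelation of expression beyond
the injected gradients, batch effects between animals, and the long-tailed
subclass abundance spectrum of real tissue. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated models, not robustness to those real-data complications.

## Problem sizes and numerical choices

Tests and the recovery/calibration checks run at desk scale, chosen to
keep each scenario statistically powered: interaction fields of ~5,000
cells across 2 sections with 8 types and 200 randomization rounds (the
called-pair recovery check uses the full 1,000), 20 seeded calibration
runs pooling 720 pair-tests; integration at 5 subclasses × 3 clusters,
200 genes, ~2,000 + 2,000 cells; gradients at ~2,000 cells. Atlas-scale
quantities that depend on the full ~10-million-cell datasets (cluster
counts, global pass rates, module counts) are outside what synthetic
desk-scale runs can reproduce and are not claimed.

Numerical conventions: all thresholds implement their verbal definitions
literally (strict "less than"/"more than"/"higher than", inclusive
confidence thresholds); distance exactly R_proximal counts as proximal;
z-scoring guards zero-variance genes with a relative (1e-12) tolerance;
label ties break lexicographically; every stochastic step takes an
explicit seed and fixed seeds reproduce results bit-for-bit.
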