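# spatlas

Analysis toolkit for spatially resolved single-cell atlases of the kind
produced by whole-brain MERFISH surveys: millions of segmented cells, each
with a centroid position inside a thin tissue section and a count vector
over an imaging gene panel, to be classified against a dissociated
scRNA-seq reference and then interrogated for spatial organization.

The package covers the full analytical chain:

- **Experiment design** — construction of the maximal 32-bit
  Hamming-weight-4 / Hamming-distance-4 barcode codebook (a Steiner
  quadruple system built by the doubling construction) with blank-barcode
  assignment, and marker-panel selection via a differential-expression
  screen plus greedy set cover over cluster pairs.
- **QC and normalization** — volume filters per z-plane count, volume
  normalization, per-experiment mean-total rescaling to 250 counts,
  total-count quantile trimming, doublet-score thresholding.
- **Integration** — two-round anchor-based label transfer: balanced
  partitioning of the reference subclass graph, diagonal-covariance CCA
  co-embedding, mutual-nearest-neighbour anchors, plurality-vote transfer
  with multiplicative confidence adjustment, and anchor-weighted
  transcriptome imputation.
- **Spatial statistics** — neurotransmitter/region annotation scores,
  weighted-neighbourhood spatial modules at two levels (Leiden over local
  cell-type-composition vectors, Weight_ij = exp(−(D_ij/D_i⁰)²)),
  neighbourhood-purity/discreteness and PC1-or-pseudotime gradient
  correlations, proximity-based cell–cell interaction tests against
  local-randomization nulls, and ligand–receptor / gene upregulation
  screens with S = log(1 + Π L·R) scores and one-sided Welch tests.
- **Synthetic data** — a first-class generator (`spatlas.simulate`) that
  emits cell tables, expression matrices, paired references, and LR
  databases with known ground truth (domains, gradients, attractions,
  upregulation), so every stage is testable without any download.

## Worked example

Build the codebook and run an interaction test on synthetic data with an
injected attraction between subclasses A and B:

```python
from spatlas.codebook import build_max_codebook, verify_codebook
from spatlas.simulate import AttractionRule, apply_attraction
from spatlas.interactions import InteractionConfig, call_interactions
from tests.conftest import csr_cells

words = build_max_codebook(32)
print(verify_codebook(words))
# {'weight_ok': True, 'distance_ok': True, 'min_pairwise_distance': 4, 'size': 1240}

cells = csr_cells(seed=0)                       # ~5,300 cells, 8 types, 2 sections
cells = apply_attraction(cells, AttractionRule("A", "B", 10.0, 0.6), seed=100)
res = call_interactions(cells, {"field": list("ABCDEFGH")},
                        InteractionConfig(n_rounds=200, seed=0))
print(res[res.significant])
# region subclass1 subclass2  proximal_count  permutation_mean  fold_change  pval-adjusted
#  field         A         B             443            83.205     5.324199            0.0
```

The 1,240-word codebook passes exhaustive weight/distance verification, so
assigning a 1,124-gene panel leaves 116 blank barcodes. In the interaction
run, 36 subclass pairs are tested; only the injected A–B attraction is
called: 443 observed proximal pairs against a local-randomization null of
83.2 ± a normal fit, a 5.3-fold enrichment at adjusted p ≈ 0.

A thin CLI covers the file-oriented tools:

```bash
spatlas codebook --bits 32 --genes genes.txt --seed 1 --out codebook.csv
spatlas simulate --seed 3 --out sim/
spatlas preprocess --cells sim/cells.csv --expr sim/expression.mtx --out qc/
```

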