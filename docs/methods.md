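# Methods

This note documents the statistical procedures `stscore` implements, the
synthetic data they are validated on, the numerical choices, and the
limits of what passing tests demonstrate.

## Spot positivity and the scoring model

A Visium spot is a 55-µm barcoded capture area; its column of the count
matrix aggregates UMIs from the handful of cells it covers. The package's
core statistic is *panel positivity*: spot *s* is positive for panel
*G = {g₁…gₙ}* with rule *k* when at least *k* genes of *G* have raw UMI
count ≥ `min_count` (default 1) in *s*. Positivity is deliberately called
on raw post-QC counts, not normalized values: "the spot expresses gene
*g*" is read as a nonzero UMI observation, the only reading that needs no
tuned threshold. `min_count` and `k_required` are configurable per panel
(the apoptosis panel, for instance, is scored at k = 1, 2 and 5 of its
five genes).

Percentages are `100 · |positive ∧ scope| / |scope|`, always reported with
numerator and denominator; an empty scope yields a flagged missing record,
never a silent zero. Scopes: whole biopsy, compartment (epidermis /
dermis / other, derived from a cluster→compartment map), single cluster,
or anchor stratum (spots positive for an anchor panel such as CD68).
Because scopes partition spots, total numerators equal the sum of
compartment numerators exactly (tested).

**Conditional polarization** classifies anchor-positive spots by two
disjoint marker panels (M1-only / M2-only / both). The default denominator
is anchor⁺ spots positive for ≥ 1 polarization marker, so the three shares
are an exact partition; counts are kept as exact rationals and the last
share is emitted as the float complement, so the reported percentages sum
to exactly 100.0. The alternative denominator (all anchor⁺ spots, with a
"none" remainder) is available by flag.

Gene symbols are matched case-insensitively through a small alias table
(IL-1β→IL1B, TNFα→TNF, CD16→FCGR3A, TGFβ→TGFB1, …) because figure-style
panel definitions use protein names. M1/M2 marker orientation follows the
immunohistochemistry convention (CD16/FCGR3A = M1, CD163 = M2); the
literature is not unanimous, so the swapped orientation ships as
`m1_markers_alt` / `m2_markers_alt`.

## QC and normalization

Spots with fewer than 200 detected genes (UMI ≥ 1) are removed before any
analysis; the filter never alters retained counts and logs what it drops.
Normalization for marker detection is log CP10K, `ln(1 + 10⁴·c/colsum)`. A
clipped Pearson-residual variant — `(c − µ̂)/√(µ̂ + µ̂²/θ)` under a
depth × abundance product null with fixed θ = 100, clipped at ±√n_spots —
is provided as a declared simplification of regularized negative-binomial
variance stabilization. Downstream spot statistics depend only on raw
counts and cluster labels, so the choice of normalization affects
clustering and marker effect sizes, not positivity calls.

## Embedding, batch centering, clustering

Joint analysis merges samples on the intersection of gene symbols, with
sample-prefixed barcodes. The embedding is PCA on the 2,000 most variable
genes (variance ranking), with a fixed SVD sign convention (largest
|loading| positive) for determinism; batch correction is per-sample
mean-centering in PC space — each sample's rows are shifted so its PC mean
coincides with the global mean. This removes additive sample offsets, the
dominant batch artifact in the synthetic data, and is a documented,
much simpler stand-in for iterative mixture-based correction; it does not
handle batch-specific variance or nonlinear effects. Clustering is seeded
k-means with a fixed k (default 2, the epidermis/dermis split of the
generator; choose k to match the annotation granularity of real data).
Graph/resolution-based clustering is out of scope.

## Marker detection

One cluster vs rest, per gene: a gene is tested when detected in ≥ 25% of
spots inside or outside the cluster; the log₂ fold change is
`log2((mean expm1 in + ε)/(mean expm1 out + ε))` with ε = 1e-9 on the
log-normalized values; the p value is a two-sided Wilcoxon rank-sum —
tie-corrected normal approximation without continuity correction,
switching to exact enumeration when both groups have ≤ 10 observations
and no ties; constant genes score p = 1. Benjamini–Hochberg runs over
each cluster's tested genes. Records are retained when log₂FC ≥ 0.25
(upregulated only) and adjusted p ≤ 0.05. Top-N ranking breaks ties by
(higher log₂FC, then lexical symbol).

*Calibration note.* On heavily tied sparse counts (≤ ~1 UMI/cell/gene)
the normal approximation's far tail is inflated roughly twofold, which
pushes the observed FDR of a BH-0.05 screen toward ~10% even though
nominal control is 5%. The synthetic reference is therefore generated at
a realistic deep-reference baseline (~3 UMI/cell over its expressed-gene
panel, ≈18k UMIs/cell), where the tail is well calibrated; on very sparse
real data the same screen should be expected to run above its nominal
FDR.

## MIA correspondence and over-representation

Both marker tables are filtered (adjusted p ≤ 0.05, log₂FC > 0.25) and
capped at the top 300 upregulated markers per cluster. For set sizes m, n
with overlap k in a shared universe of N genes, the score is
−log₁₀ P(X ≥ k) when k ≥ m·n/N and +log₁₀ P(X ≤ k) (negative) otherwise,
with probabilities floored at 1e-300; ties at expectation break toward
enrichment. The default universe is genes detected in ≥ 1 spot of the
merged data intersected with the reference genes (configurable); one
shared universe is used for all cluster pairs. The same one-sided
hypergeometric tail powers a local over-representation analysis over
GMT-format gene-set libraries with BH across sets — a web-service-free
replacement for interactive enrichment portals.

## Deconvolution scores

Reference signatures are per-cluster mean profiles scaled to unit L1 norm.
Each spot's CP10K profile on the shared genes is regressed onto the
signature columns under nonnegativity (NNLS), and coefficients are
normalized to sum to one; identically zero solutions are flagged rather
than normalized. These scores are probability-like weights, not calibrated
posterior probabilities: this is a deliberately simple replacement for
anchor-based label transfer that keeps the same output contract (a score
in [0,1] per spot per reference cluster, thresholded at 0.5 with a strict
">") and is exactly testable by mixture recovery. Scores are invariant to
global rescaling of a spot's counts. Noise-free two-signature mixtures are
recovered to machine precision; under negative-binomial noise at
2,000 counts/spot the RMSE of recovered weights is ≈ 0.02.

## Group comparisons

Per-sample percentages are compared with a two-tailed Student t test
(pooled variance — the default of common Prism workflows) or Welch's test;
zero-variance degenerate cases are defined explicitly (t = 0, p = 1 for
equal means). A permutation alternative uses the difference of means:
exact over all C(n,k) relabelings when that enumeration fits the
requested budget (p is then a multiple of 1/C(n,k)), otherwise Monte
Carlo with the add-one estimator (1 + hits)/(1 + n_perm). No cross-panel
multiplicity correction is applied to the report tables; `bh_adjust` is
available when one is wanted.

## In vitro assays

**ΔΔCT.** ΔCT = Ct(target) − Ct(housekeeping); ΔΔCT subtracts the mean
reference-group ΔCT *per target gene*; RQ = 2^(−ΔΔCT), i.e. PCR
efficiency is fixed at 2 (no efficiency correction). RQ is invariant to
any global Ct shift, and a single-sample reference group has RQ exactly 1.

**Morphometry.** Label masks (0 = background, k > 0 = cell k) from any
segmenter are consumed as TIFF/PNG; cell area = pixel count × (µm/px)².
The EMT readout is the percent of cells with area strictly above
5,000 µm². Border-touching cells are excluded by default because partial
cells bias areas downward (configurable).

## The synthetic-data generator

The generator emulates the structure of a six-biopsy skin cohort: per
sample, a hex lattice (Visium array conventions: column parity matches row
parity, pixel coordinates an affine map of array coordinates) with an
epidermal band of rows and a dermal remainder; negative-binomial counts
with variance µ + µ²/θ, θ = 10 by default; ~6,000 background genes at mean
0.05 UMI/spot, giving ≈290 detected genes/spot so the 200-gene QC
threshold passes intact tissue.

Planted structure and defaults (the study conditions the tests probe):

- **ISG inflammation.** Per-sample inflamed fractions
  (0.05, 0.05, 0.05, 0.90, 0.61, 0.90) for 3 controls + 3 lesions;
  inflamed spots are planted by *exact count* (seeded permutation), since
  the fraction is the recovery target and Bernoulli draw noise would
  confound recovery with generator sampling. Panel genes use a separate
  background mean of 1e-4 in spots not flagged for them — biologically,
  ISGs are near-silent without interferon signaling — because a shared
  0.05 baseline would give a six-gene any-of panel a ~26% false-positive
  floor and make planted fractions unrecoverable. Flagged spots get mean
  `baseline_mean × positive_boost` = 2.5, which makes any-of-six
  positivity essentially deterministic (miss probability ~10⁻⁶) while
  single-gene detection is ~0.9.
- **Macrophages.** Anchor (CD68) spots at 25%; conditionally M1-only 5%,
  M2-only 75%, both 5% (controls are M2-dominated; lesional mixes are
  configured per experiment). Marker and cytokine panels are boosted
  jointly with the class flag. Optional rectangular hot-spot blocks force
  anchor positivity in a spatial patch.
- **Cell death.** Apoptosis-panel positivity at 60% given ISG-positive
  vs 20% given ISG-negative, planting the co-occurrence the scoring must
  detect.
- **Reference.** Five clusters × 100 cells, 40 disjoint planted markers
  per cluster at 8× fold over a 3 UMI/cell baseline (see calibration note
  above; 40 markers keep the observed-FDR ratio statistically stable).
- **Assays.** Ct tables with exact planted fold changes (a fold F shifts
  the target Ct by −log₂F); label masks of non-overlapping disks whose
  recorded truth is the rendered pixel area.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: spatial autocorrelation beyond the compartment
band and hot-spot blocks, per-spot cell-type mixtures beyond two-signature
mixing, gene–gene correlation beyond the planted programs, segmentation
errors in masks, amplification-efficiency variation in qPCR, and any
imaging content (H&E, scale factors) beyond pass-through.

## Numerical and interface choices

- Counts are genes × spots internally; MTX on disk is 1-based, internal
  indices 0-based. Round-trips through the Space Ranger layout are exact
  (integer equality), gzipped or plain, and both pre- and post-2.0
  position dialects are read.
- Duplicate gene symbols are disambiguated by suffixing the gene id;
  panel lookup matches the bare symbol first.
- Whether only in-tissue spots enter analysis is not universally agreed;
  the reader keeps `in_tissue == 1` spots by default with a flag to keep
  all.
- Hypergeometric p floored at 1e-300 before log₁₀; BH capped at 1;
  polarization shares exact by complement; k-means uses 10 seeded
  initializations.
- The pipeline writes CSV/JSON only, records a config hash and seed in
  its manifest, and is bit-reproducible for a fixed config and seed.
- Problem sizes in the validation suite (2,000-spot samples, 500-cell
  reference, 100-spot mixture panels, 200-cell masks) were chosen as the
  smallest sizes at which the 3-binomial-SE recovery bands are sharp
  enough to be informative.

## Known limitations

- The deconvolution scores sum to one per spot by construction; methods
  whose per-type prediction scores are independent probabilities will not
  match numerically, only at the level of threshold summaries.
- Batch centering cannot remove batch-specific scaling or nonlinear
  distortions.
- The Wilcoxon screen's observed FDR exceeds its nominal level on very
  sparse data (see calibration note).
- k-of-n positivity with n > 1 is asymmetric in detection efficiency: at
  single-gene detection ~0.9, a 5-of-5 rule recovers only ~0.57 of truly
  positive spots; rules with k close to n measure co-detection, not just
  co-occurrence.
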