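# Methods

This note documents the models, parameter choices and numerical decisions
behind `epidrift`, and what the synthetic-data generators do and do not
emulate.

## Study design being emulated

Four groups of CD34+ cells: (1) unstimulated control, (2) cytokine
stimulated, (3) cytokines + polybrene, (4) cytokines + polybrene +
lentiviral vector. Three kinds of readout are analyzed: per-nucleus image
cytometry of an epigenetically informative immunomarker, MeDIP enrichment
ratios on a tiling array (groups 1, 2, 4 only), and beta values from a
27k-style CpG methylation array (triplicates of all four groups).

## Synthetic image fields

`gen_nuclear_field` renders non-overlapping elliptical nuclei (rejection
placement on bounding circles, at most 200·n tries before an explicit
density error) on a square 8-bit field. Defaults: 512 px field, 80 nuclei,
major semi-axis 8–14 px, axis ratio 0.6–0.95 (bounded eccentricity, so the
shape features have non-degenerate covariance), background 10, DAPI level
170, Gaussian pixel noise σ = 3.

Group effects act on the marker channel through two parameters — mean
intensity and speckle texture (Poisson-placed Gaussian blobs whose density
scales with the texture factor): group 1 (60, 0.4), groups 2 and 3
identically (140, 1.2), group 4 (185, 3.0). Groups 2 and 3 are deliberately
indistinguishable, and group 4 differs from group 2/3 in texture more than
in mean, so that no single feature separates all four groups — the
discrimination has to be multivariate, which is the property the
discriminate stage is tested against.

Not emulated: confocal optics (PSF, z-stacks), chromatic aberration,
overlapping/touching nuclei, mitotic figures, uneven illumination. Passing
tests therefore demonstrate correctness of segmentation and feature
extraction on well-separated nuclei, not robustness to dense clumps.

## Segmentation and features

Adaptive Otsu: the threshold is computed per block (default 128 px), with
flat or foreground-free blocks falling back to the global Otsu value and
implausibly low local thresholds (< 0.5× global) clamped to it; the block
grid is bilinearly interpolated to a full-resolution threshold surface.
Objects are 8-connected; components with area outside [80, 5000] px² and
border-touching components are removed (truncated features would bias the
population statistics); labels are re-numbered contiguously.

The 25 features follow CellProfiler conventions. Shape (11): area,
compactness = P²/(4πA), eccentricity, Euler number, extent (area /
bounding box), form factor = 4πA/P², major/minor axis lengths, orientation
(radians in (−π/2, π/2]), perimeter, solidity. Intensity (14): {integrated,
mean, std, min, max} over the full mask and over its edge (mask minus its
8-connected erosion), plus mass displacement (pixel distance between
binary and intensity-weighted centroids; defined as 0 for a zero-intensity
object) and the lower-quartile, median and upper-quartile over the full
mask. Note the edge set carries no median/quartiles — that is what makes
the count 14 rather than 16.

## Discrimination

Features are standardized (zero mean, unit variance per column;
zero-variance columns dropped with a warning) before PCA — the features mix
px², radians and intensity units, so unscaled PCA would be dominated by
area. PCA uses SVD with a deterministic sign convention (largest-magnitude
loading positive). LDA solves the generalized eigenproblem Sb·w = λ·Sw·w
with ridge regularization Sw + εI, ε = 1e-6·trace(Sw)/d, because integrated
and mean intensity are nearly collinear; the training-set nearest-centroid
reclassification rate is reported. MANOVA uses Wilks' lambda with Rao's F
approximation; the implementation is cross-checked against statsmodels in
the tests, and its null behaviour (type-I error, p-value uniformity) is
verified by simulation. Degenerate inputs (fewer rows than features +
groups, or rank-deficient SSCP) raise errors naming the rank condition.

## MeDIP tag analysis

A tag is enriched in a group iff its log₂ precipitated/input ratio is
strictly greater than the threshold (default 2; the strict inequality is
deliberate and tested at the boundary). Tags are matched across groups by
tag id — the same array design measured under three conditions — not by
coordinate overlap. Venn decomposition is exact set arithmetic; top-N
matrices sort by the reference group's ratio descending with ties broken
lexicographically by tag id for determinism.

The tag generator plants a configurable fraction of forced triple-shared
tags and otherwise draws per-group membership independently at rates
adjusted so the configured marginals hold; the resulting analytic section
probabilities are exposed (`tag_section_probabilities`) and checked against
observed counts with binomial bounds. Enriched ratios are drawn strictly
above the threshold (2.05 + exponential), sub-threshold ratios strictly
below it, so thresholding recovers planted membership exactly. MeDIP's
CpG-density bias and its non-quantitative relation to absolute methylation
are not modelled — the analysis operates purely on the ratio scale, as the
assay itself does.

## Beta values and differential methylation

`compute_beta` implements β = max(M,0)/(max(M,0)+max(U,0)+100). The +100
offset stabilizes low-intensity probes and bounds β strictly below 1.

The generator inverts this formula exactly by fixing the total signal
s = M + U + 100 = 10,000 arbitrary fluorescence units and setting M = β·s,
U = s − 100 − M, so recomputed betas equal intended betas to machine
precision in the noise-free case (the representable maximum is
β = (s−100)/s = 0.99; baselines are clipped there). Baseline betas come
from a mixture — 60% unmethylated Beta(2,18), 30% methylated Beta(18,2),
10% intermediate Beta(5,5) — typical of promoter-biased CpG panels.
Replicate noise is Gaussian on the beta scale (σ = 0.05 by default; the
platform's replicate scatter is not published, so this is a free
parameter), clipped to the representable range. Detection failures are
independent per probe and sample (default rate 1%), drawing p-values from
U(0.05, 1) against U(0, 0.005) for detected measurements — this exercises
the "missing in any sample discards the probe" rule.

Planted changes shift one group's betas by a signed delta at gene level
(both probes of the gene). Planted genes draw their baseline from the
distribution extreme compatible with the shift direction (gains from
(0.05, 0.15), losses from (0.85, 0.93)), so a +0.3 shift lands in the
intermediate range — matching the interpretation of a partial-population
methylation change, where a 0.3 beta shift means ~30% of cells switched
state, and producing the transduced group's characteristic enrichment in
intermediately methylated loci.

The default four-group effect structure scales the study's gene counts by
roughly 1:10 at 2000 genes: 1v2 plants 11 gains + 13 losses (balanced
cytokine remodelling), 1v3 plants 1 + 1 (near-null polybrene), 1v4 plants
75 gains + 10 losses (LV-dominated de-novo methylation), plus a 16-gene
clustered region on chr6 (histone-cluster analogue) changed in both the
1v2 contrast (6 genes) and the 1v4 contrast (13 genes, a superset) — same
region, higher changed fraction under transduction. About 5% of genes sit
on chrX/chrY so the allosome filter is always exercised.

Differential calling: per probe, delta = median(β, group B) − median(β,
group A); called iff |delta| ≥ 0.20 (inclusive; a 1e-12 guard absorbs
float representation of the medians). "20% of methylation" is interpreted
as an absolute beta difference of 0.20. Gene-level aggregation is
any-probe: a gene is called in the direction of its largest-|delta| called
probe and flagged if its probes disagree in direction (the source assay
typically carries one promoter and one first-exon probe per gene, which
need not move together). Calling is antisymmetric under group swap by
construction.

### Normalization

The three-step raw-intensity normalization — (1) per-sample color-bias
correction scaling each channel's median to the cross-channel geometric
mean, (2) per-sample, per-channel background subtraction of the 5th
percentile with clamping at 0, (3) quantile normalization across samples
within each channel (classic sorted-mean mapping, ties receiving
interpolated reference values) — is provided for raw channel exports that
carry dye bias and background offsets. The synthetic generator emits ideal
intensities (the exact-inversion contract above), and applying a
median-equalizing color correction to intrinsically asymmetric M/U
channels of ideal data distorts betas; the pipeline CLI therefore applies
normalization only on request (`--normalize`). The quantile step's
contracts (identical sorted vectors afterwards, within-sample rank
preservation, identity on identically distributed samples) are tested in
isolation.

### Clustering and density profiles

Samples are clustered on the betas of called probes with Euclidean
distance and average linkage; the leaf order is scipy's deterministic
tightest-cluster-first ordering, the tree is serialized as Newick with
branch lengths, and cophenetic distances are reported. Density profiles
reduce each group to per-probe medians and histogram them over [0,1] in 50
equal bins, normalized to integrate to 1.

## Positional enrichment

The region scan enumerates every run of 2..max_run (default 100; the CLI
examples use 30) consecutive analyzed genes per chromosome — a bounded
approximation of exhaustive positional gene-enrichment region enumeration,
chosen for desk-scale tractability. Each run is scored with the
hypergeometric upper tail P[X ≥ k] computed in log space (gammaln log-pmf,
suffix log-sum-exp), cached per (n, K, N), so extreme enrichments do not
underflow before adjustment. All candidates are adjusted together with
Benjamini–Hochberg (Bonferroni available), then selected greedily in
ascending adjusted-p order, discarding candidates whose gene-index span
overlaps an already selected region on the same chromosome; regions with
p_adj < α (default 0.05) are reported with the genomic span from first to
last member gene, 1-based inclusive. Ties in p are broken by (p_raw,
chromosome, start) for determinism.

## Problem sizes and defaults

- Image fields: 512² px, 80 nuclei/field, one field per group (~320 cells)
  for the discrimination analyses; MANOVA null calibration uses 1000
  simulated datasets of 4×30 rows × 10 features.
- Methylation: 2000 genes × 2 probes × 12 samples; parameter-recovery runs
  use 20 independent simulations of 100 planted genes.
- Tags: 10,000 tags × 3 groups.

These sizes keep the full test suite and the acceptance script in the
tens-of-seconds range while leaving every statistical margin wide (the
caller's theoretical miss rate per planted gene at these settings is
~3·10⁻⁴; the planted LDA separations exceed 100 within-group SDs).

## Known limitations

- The segmentation has no declumping; touching nuclei merge and are then
  usually removed by the size filter rather than split.
- The generator's noise is i.i.d. Gaussian per pixel/probe; no spatial
  correlation, batch effects, or probe-specific variance.
- Gene-level aggregation (any-probe with conflict flag) is a documented
  convention; the assay's vendor software does not prescribe one.
- The MeDIP generator controls section probabilities only in expectation;
  anti-correlated group memberships (which would be needed to push the
  triple-shared fraction below the product of the marginals) are not
  representable.
- Region enumeration is bounded by max_run; a true enrichment spanning
  more consecutive genes than max_run is reported as its best sub-window.
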