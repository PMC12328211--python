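# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the procedures left room.

## Contamination filtering

Index hopping on patterned flow cells lets a cell barcode from one
multiplexed 10x sample surface, with a small fraction of its reads, in
another sample of the same sequencing run. For every barcode assigned to
multiple samples we compare per-sample UMI totals: if the top sample has at
least `dominance_ratio` (default 10) times the UMIs of the *second* most
abundant sample, the dominant instance is kept but flagged
`potentially contaminated`; otherwise all instances are removed. Choices:

* a ratio of exactly 10 counts as dominant (the rule is "ten times or more");
* with ≥3 samples sharing a barcode, dominance is tested against the second
  most abundant only, and every non-dominant instance is removed;
* the filter is idempotent, and kept + removed instances always equal the
  input instances (tested).

## Cell QC and normalization

"Genes detected" means genes with count ≥ 1. Droplet data pass a permissive
annotation-stage filter (>100 genes OR >1,000 UMIs) so fragile cell types
survive clustering, and a stricter final filter (≥500 genes); plate data
require ≥500 genes AND ≥5,000 reads. Normalization is
`v = ln(count/total × 10⁴ + 1)` per cell and gene. The implementation
multiplies before dividing so the transform is *bitwise* invariant to
multiplying a cell's counts by an integer, and the per-cell identity
`Σ_g expm1(v) = 10⁴` holds to ~1e−16 relative.

Pseudobulk supports two conventions: `mean-of-lognorm` (mean of per-cell
ln(UP10K+1); the default for cross-species work, where the single-cell scale
is the object of comparison) and `log-of-mean` (ln(mean UP10K + 1); used for
the cell-type map). Cell-type minimum sizes differ by stage: 4 cells for the
cell-type map, 5 for DEG tables, 16 for cross-species profiles.

## DEG tables

Per cell type and scope, a two-tailed Wilcoxon rank-sum per gene against the
scope background, BH correction across genes within the comparison, and only
up-regulated genes (positive ln-fold-change of de-logged means, pseudocount
0.01) with adjusted p < 0.05 are tabled, ranked by adjusted p with
fold-change as tie-break, truncated to 300. The rank-sum test uses the
normal approximation with tie and continuity corrections for group sizes
over 20 and scipy's exact distribution below that; the vectorised
implementation is cross-checked against `scipy.stats.mannwhitneyu` in tests.
Ranking ties by fold-change (rather than mean expression) is a choice; the
alternative is not exposed.

## Density-ridge trajectories

The trajectory of a cell continuum is the density ridge of the 2D embedding:

1. **KDE**: 2D histogram on a *square-pixel* grid (longest side
   `grid_resolution` = 256 pixels) smoothed with an isotropic Gaussian of
   bandwidth `h = scale · mean(σ_x, σ_y) · n^(−1/6)` (Silverman-style,
   `scale` default 1). Square pixels matter: on an anisotropic grid an
   elongated cloud becomes a fat band whose medial axis collapses.
2. **Mask and skeleton**: pixels with density ≥ 10% of the maximum are
   skeletonized (scikit-image); the pixel graph's minimum spanning tree
   removes lattice-level cycles.
3. **Spur pruning**: side branches shorter than 3% of total skeleton length
   are removed iteratively.
4. **Gap bridging** (automating a manual step): endpoints of separate
   fragments closer than `gap_cap` (default 5% of the embedding diameter)
   are connected when both terminal tangents are collinear with the bridge
   (cosine > 0.7). Fragments further apart remain separate root branches.
5. **End extension**: skeletonizing a thresholded density retracts the ridge
   from the true ends by roughly the bandwidth, which would pile boundary
   cells into ties at s = 0 or 1; each free end is therefore extended
   outward by `1.5·h` along its local tangent.
6. **Junction retraction**: where two child bands merge, the smoothed
   density stays unimodal past the true bifurcation, so the skeleton
   junction lands downstream of it; each junction is pulled back along its
   parent by `3.5·h`, letting near-junction cells fall to their nearest
   child. Both corrections are symmetric consequences of kernel smoothing;
   their scales were set by geometry, not fitted per dataset.
7. **Anchoring**: the endpoint whose neighbourhood cells (radius 5% of the
   diameter, or the 15 nearest) maximize mean anchor-marker expression
   becomes the start; an exact tie raises an error rather than guessing.

Cells are aligned by segment-wise projection to the nearest branch (ties go
to the lower branch id — a documented deterministic tie-break), position
s = arc length from the root normalized by the branch's root-to-tip length.
Outliers are cells whose distance exceeds the sliding-window (10% of cells,
min 11) median + 3 × scaled MAD (1.4826·MAD, the normal-consistent scale).
Reversing the anchor of an unbranched trajectory maps s to 1 − s exactly.

PCA for embeddings standardizes the selected variable genes; PCs are dropped
when their score kurtosis exceeds 20 (a single extreme cell driving a
component) or when their top-5 loading genes intersect a caller-supplied
exclusion list (immediate-early genes). The 2D embedder is UMAP on Euclidean
distances over surviving PCs, deterministic given the seed. Variable genes
use a bin-standardized dispersion: log(var/mean) of de-logged expression,
z-scored within 20 mean-expression bins, threshold 0.5.

## Trajectory DEGs

Templates are 20 Gaussian bumps over s ∈ [0, 1] with peaks at
(i − 0.5)/20 and s.d. 1/(2·20) — the family is a choice (only "unimodal,
smoothly changing, uniformly spaced peaks" is prescribed), matched by the
generator so recovery is well-posed. Per gene, Spearman rho/p against every
template evaluated at the cell positions; Bonferroni over genes × templates
(the most conservative defensible universe); selection = top 1,000 by p ∩
p < 0.01 ∩ dispersion > 0.5. Selected genes are smoothed along s (moving
average, window 5% of cells, min 11), peak-normalized and k-means clustered
(k = 10 default, 25 restarts, fixed seed; genes enter clustering in gene-id
order so output is invariant to input column order). Clusters are ordered by
mean peak position; within a cluster genes rank by p, then mean expression.

## Orthology

NCBI-style (anchor, species, orthologue) rows and Ensembl rows joined
through the NCBI gene id are unioned per (anchor, species) with provenance
{ncbi, ensembl, both}. A source disagreement therefore yields two candidates
and the anchor fails the single-candidate rule — the implicit resolution of
conflicts. Drops, in order: missing orthologue in a required species;
more than one candidate in a required species; shared target (all anchors
sharing it are dropped, including the first seen). Ensembl's own
`ortholog_one2one` tag is deliberately not used as a filter (it misfires on
incompletely annotated genomes). Optional species (macaque) join through the
human id, keeping only human ids with a unique partner. Matching is
case-sensitive.

## Cross-species conservation

**r_c** is the Spearman correlation of two species' cell-type mean
expression over shared orthologous genes, after clamping values below 0.4 to
0.4 (average ranks neutralize rank noise among background-level genes; an
exclusion variant is available by flag, clamping is the default because it
preserves the gene set). CIs are Fisher-Z normal intervals with n = gene
count. Along trajectories the same statistic runs in moving windows (default
width 10% of the s axis, step 2%, ≥10 cells per species per window).

**Gene level**: E_max is a gene's maximum cell-type mean within a species;
the universe keeps genes with E_max > 0.5 in all species or E_max > 0.1 in
all with > 1.5 in one. Profiles are divided by E_max per species (making r_g
invariant to per-species rescaling) and Pearson-correlated per pair.
Δr_g = r_gHL − r_gHM is tested with a one-tailed Fisher-Z difference:
z = atanh(r), SE = √(1/(n₁−3) + 1/(n₂−3)), normal reference by default (a
t reference with df = n₁+n₂−6 is selectable; at n = 63 they agree to a few
per cent). The two correlations are treated as independent even though they
share the human profile — a simplification that makes the test slightly
conservative for positive dependence. HL requires Δr_g > 0.4 AND right-tail
p < 0.05 (strict inequalities; Δr_g = 0.4 exactly is untagged); HM is the
mirror on the left tail. The LM definition ("lemur–mouse conserved,
human-divergent") is implemented as r_gLM − max(r_gHL, r_gHM) > 0.4 with the
corresponding right-tailed test — an interpretation, since only the
human-anchored contrasts are given explicitly. Tiers come from the minimum
of the three r_g values: > 0.8 highly, < 0.3 lowly, else moderately
conserved; undefined correlations (zero-variance patterns) are
unclassifiable. These sections apply raw thresholds without FDR correction,
reproduced as such (an optional BH flag exists, off by default).

**Primate-selective genes** per orthologous cell type (>15 cells in every
species): enriched needs mean > 0.5 in human AND lemur, ≥5-fold vs the mouse
cell type (fold on de-logged means, pseudocount 0.01 — the log/linear space
was open; de-logged is the default with a flag) and two-tailed Wilcoxon
p < 10⁻⁵ in both primate-vs-mouse comparisons; depleted is the mirror;
cell-type-enriched compares the type against all other types pooled across
species with a one-tailed test. The fold threshold is inclusive (≥5);
exactly 4-fold genes are never called (tested with deterministic values).

## Synthetic-data generators

The generators define the conditions every recovery estimate is quoted
under; they are not tuning knobs.

* **Atlas**: 3 cell types × 50 cells, 200 genes, 5 disjoint markers per type
  at 8-fold expected enrichment; log-normal library sizes
  (ln L ~ N(ln 5000, 0.35)); Poisson counts by default, negative binomial
  (variance μ + μ²·0.5, typical droplet overdispersion) selectable. At least
  two cell types share each compartment so compartment-scoped DEG
  backgrounds are never empty.
* **Trajectories**: branches laid out in the plane (root along +x, children
  fanning ±40°); cells uniform along branches with isotropic Gaussian
  embedding noise of s.d. 5% of the longest root-to-tip path; program genes
  are Gaussian bumps of expected ln-expression (amplitude 2.5, width 0.1)
  in the latent position — the same family as the analysis templates, so
  recovery is well-posed; noise genes are position-independent.
* **Index hopping**: echoes are binomial thinnings of the source cell's
  counts at ratio U(0.005, 0.08) (decisively below the 1/10 dominance
  bound); an adversarial mode draws U(0.08, 0.3) to exercise the
  no-dominant-sample branch.
* **Species trios**: 63 shared cell types × 20 cells per species,
  1,000 genes. Per-gene cell-type patterns of expected ln-expression are
  Exp(0.8) draws capped at 4 (the cap keeps per-type library composition
  stable; uncapped exponential tails let a single gene dominate a type's
  library and distort everyone else's normalized scale). Conserved partners
  share a pattern plus N(0, 0.1) noise; divergent species draw independent
  patterns. Planted class proportions: 11% highly conserved, 10/8/8% HL/HM/
  LM, 2+2% primate enriched/depleted, rest unconserved. Primate-selective
  genes put ln-level 2.2 vs 0.05 in one designated cell type over a weak
  shared background.

What the generators do **not** emulate: ambient RNA, doublets, batch effects
other than index hopping, gene length/GC bias, realistic gene–gene
correlation structure, or dependence between conservation class and
expression level. Passing recovery tests therefore demonstrates that the
statistics and rules are implemented correctly and are well-calibrated under
their own assumptions — not that they are robust to artefacts these
simulations omit.

## Problem sizes and determinism

Recovery estimates use 20 replicate simulations for the Monte-Carlo checks
(hop-filter oracle, trajectory-DEG power and family-wise control,
conservation-class recovery, DEG false-discovery control), one simulation of
400 cells for linear-trajectory recovery and five pooled simulations of 600
cells for Y-branch assignment, a 200-anchor table for the orthology oracle
and 10⁶ draws for the Fisher-Z Monte-Carlo null. Every stochastic operation
takes an explicit seed; CLI stages write floats at 9 significant digits in
deterministic row order, so reruns are byte-identical.

## Known limitations

* Ridge detection assumes the continuum is visible as a ridge in a given 2D
  embedding; it does not attempt graph abstraction, principal curves or
  velocity, and crossing or cyclic topologies are out of scope.
* Branch assignment by nearest distance is intrinsically ambiguous near
  junctions; with embedding noise at 5% of the path and an 80° fan, roughly
  8% of cells are misassigned even with the true generating geometry, which
  bounds what any detector can achieve under these conditions.
* The Fisher-Z difference test ignores the dependence induced by the shared
  human profile in Δr_g (see above).
* Integration/embedding algorithms, clustering and annotation are accepted
  as inputs, not reimplemented.
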