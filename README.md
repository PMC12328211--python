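# crossatlas

A reusable pipeline for the computational stages behind a multi-organ,
multi-species single-cell transcriptomic atlas. It targets analysts building
or re-analysing droplet (UMI) and plate (read-count) scRNA-seq atlases who
need the bespoke steps that sit between raw count matrices and biological
conclusions:

* **Contamination filtering** of barcode index hopping among multiplexed 10x
  samples of one sequencing run: a barcode seen in several samples is kept
  only in its dominant sample when that sample has ≥10× the UMIs of the
  second most abundant one (and is flagged "potentially contaminated");
  otherwise every instance is removed.
* **Cell QC and normalization**: platform-specific cell filters, and per-cell
  scaling to `ln(UMI_g / UMI_total × 10⁴ + 1)` — the ln(UP10K + 1) scale
  (ln(CP10K + 1) for plate reads).
* **Pseudobulk and cell-type comparison**: cell-type mean expression
  profiles, per-gene max-normalization to [0, 1], cosine distances for
  cell-type maps, Pearson heatmaps of mean embedding coefficients, and
  ranked per-cell-type DEG tables (two-tailed Wilcoxon rank-sum with
  Benjamini–Hochberg correction; top 300 up-regulated genes with adjusted
  p < 0.05) at four comparison scopes: tissue-wide, tissue-compartment-wide,
  atlas-wide, atlas-compartment-wide.
* **Density-ridge trajectories**: a cell continuum's trajectory is detected
  as the probability density ridge of the cells in a 2D embedding
  (KDE → thresholding → skeletonization → spur pruning → gap bridging),
  anchored by marker-gene expression; cells are aligned to their shortest
  connecting point with adaptive (sliding median + MAD) outlier removal.
  Trajectory DEGs are scored by Spearman correlation against 20 preassigned
  unimodal templates with Bonferroni correction, then smoothed, k-means
  clustered into major patterns and ranked.
* **Orthology**: merging NCBI- and Ensembl-style ortholog tables and keeping
  strict one-to-one-to-one orthologues (anchors with missing, multi-mapped
  or shared targets are dropped).
* **Cross-species conservation**: per-cell-type Spearman similarity r_c
  (with a ≥0.4 expression floor and moving windows along trajectories),
  the E_max gene-universe filter, per-gene Pearson pattern correlations
  r_gHL / r_gHM / r_gLM on E_max-normalized profiles, Δr_g = r_gHL − r_gHM
  with one-tailed Fisher-Z tests, conservation tiers (r_g > 0.8 highly /
  < 0.3 lowly conserved), and primate-selective gene calls (mean > 0.5,
  ≥5-fold, p < 10⁻⁵ Wilcoxon batteries).

A synthetic-atlas module generates inputs with planted ground truth for every
stage (markers, branched trajectories with unimodal programs, hopped
barcodes, species trios with planted conservation classes), so the whole
pipeline is testable end to end without any external download.

## Worked example

Plant 8-fold markers in a three-type atlas, normalize, and rank DEGs:

```python
from crossatlas.simulate import AtlasSimSpec, simulate_atlas
from crossatlas.qc import normalize_up10k
from crossatlas.celltypes import ranked_degs

cm, meta, truth = simulate_atlas(AtlasSimSpec(), seed=1)
nm = normalize_up10k(cm)
table = ranked_degs(nm, meta, scope="tissue")
print(table[table.cell_type == "type00"].head(5)[["gene", "lnfc", "p_adj", "rank"]])
```

```
  gene     lnfc        p_adj  rank
G00118 2.202207 8.689017e-22     1
G00146 2.150565 8.689017e-22     2
G00135 2.144608 8.689017e-22     3
G00056 2.085886 8.689017e-22     4
G00187 2.065312 8.689017e-22     5
```

The five top-ranked genes are exactly the five planted markers of `type00`
(`G00056, G00118, G00135, G00146, G00187`): each is ~8-fold enriched
(lnfc ≈ 2.1 on de-logged means) with tiny BH-adjusted p-values.

The cross-species stage on a simulated human/lemur/mouse trio (63 shared
cell types, 1,000 genes, 11% planted highly conserved):

```python
from crossatlas.simulate import SpeciesTrioSimSpec, simulate_species_trio
from crossatlas.qc import pseudobulk_means
from crossatlas.conservation import (emax_filter, gene_pattern_correlations,
                                     classify_gene_conservation, conservation_summary)

per, _ = simulate_species_trio(SpeciesTrioSimSpec(), seed=1)
profiles = {sp: pseudobulk_means(normalize_up10k(c), lab, min_cells=16).profile
            for sp, (c, lab) in per.items()}
genes, emax = emax_filter(profiles)
corr = gene_pattern_correlations(profiles, genes, emax)
cls = classify_gene_conservation(corr["r_human_lemur"], corr["r_human_mouse"],
                                 corr["r_lemur_mouse"], n_cell_types=63)
print(conservation_summary(cls)["tier_fractions"])
```

```
{'highly_conserved': 0.11, 'moderately_conserved': 0.039, 'lowly_conserved': 0.851}
```

The recovered highly-conserved fraction matches the planted 11%, and the
HL/HM/LM tag counts (109/87/83 here) match the planted 100/80/80 class sizes
up to sampling noise.

Every stage is also available from the shell via the `crossatlas` CLI
(`simulate`, `hopfilter`, `qc`, `normalize`, `pseudobulk`, `degs`,
`trajectory`, `traj-degs`, `ortho-merge`, `conserve-celltypes`,
`conserve-genes`, `primate-select`), with `--seed` making every run
byte-reproducible.

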