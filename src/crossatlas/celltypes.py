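"""Global cell-type comparison: max-normalized profiles, cosine distances,
correlation heatmaps, and the four-scope ranked DEG tables.

DEG scheme: per cell type, a two-tailed Wilcoxon rank-sum per gene against a
scope-defined background, BH false-discovery correction across genes within
that comparison, and up-regulated genes with adjusted p < 0.05 ranked by
adjusted p (ties broken by ln-fold-change), truncated to the top 300. Scopes:
tissue-wide, tissue-compartment-wide, atlas-wide, atlas-compartment-wide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics.pairwise import cosine_similarity

from crossatlas.containers import NormalizedMatrix, PseudobulkProfiles
from crossatlas.exceptions import ConfigError, InputError
from crossatlas.io import log_stage
from crossatlas.stats import bh_adjust, rank_sum_test

SCOPES = ("tissue", "tissue_compartment", "atlas", "atlas_compartment")

#: pseudocount on the UP10K scale for fold-change tie-breaking
FC_PSEUDOCOUNT = 0.01


def max_normalize_profiles(pb: PseudobulkProfiles):
    """Scale each gene's pseudobulk profile by its maximum across cell types.

    Genes whose profile is all zero are dropped and reported. The operation is
    idempotent and leaves each kept gene with column max exactly 1.
    """
    profile = pb.profile if isinstance(pb, PseudobulkProfiles) else pd.DataFrame(pb)
    if profile.shape[0] < 2:
        raise InputError("max-normalization needs >= 2 cell types")
    maxima = profile.max(axis=0)
    dropped = maxima.index[maxima <= 0].tolist()
    kept = profile.loc[:, maxima > 0]
    normalized = kept / maxima[maxima > 0]
    log_stage("max_normalize", n_types=profile.shape[0], n_dropped=len(dropped))
    return normalized, dropped


def celltype_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distances (1 - cosine similarity) between cell types.

    The result feeds any 2D embedder; the embedding itself is delegated.
    """
    x = profiles.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        raise InputError("zero-vector cell-type profile")
    d = 1.0 - cosine_similarity(x)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def celltype_correlation_heatmap(coefficients: pd.DataFrame, cell_types):
    """Pearson correlation of cell-type mean embedding coefficients.

    ``coefficients`` holds externally supplied per-cell embedding coefficients
    (one row per cell); integration is out of scope here. Returns the Pearson
    matrix and an average-linkage dendrogram leaf order on 1 - r for display.
    """
    labels = pd.Series(np.asarray(cell_types, dtype=object), index=coefficients.index)
    sizes = labels.value_counts()
    if (sizes == 0).any() or labels.isna().any():
        raise InputError("every cell must carry a cell-type label")
    if sizes.size < 2:
        raise InputError("need >= 2 cell types")
    means = coefficients.groupby(labels).mean().sort_index()
    r = np.corrcoef(means.to_numpy())
    r_df = pd.DataFrame(r, index=means.index, columns=means.index)
    dist = 1.0 - r
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = sch.linkage(condensed, method="average")
    order = [means.index[i] for i in sch.leaves_list(link)]
    return r_df, order


def _fold_change(mean_focal, mean_bg):
    """ln-fold-change of de-logged means with a small pseudocount."""
    return np.log(
        (np.expm1(mean_focal) + FC_PSEUDOCOUNT) / (np.expm1(mean_bg) + FC_PSEUDOCOUNT)
    )


def ranked_degs(
    nm: NormalizedMatrix,
    metadata: pd.DataFrame,
    scope: str,
    top_n: int = 300,
    min_cells: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Ranked up-regulated DEGs per cell type for one comparison scope.

    The background set per focal (tissue, cell_type) unit is: other cell types
    of the same tissue (``tissue``); of the same tissue and compartment
    (``tissue_compartment``); all other cells (``atlas``); or other cells of
    the same compartment atlas-wide (``atlas_compartment``). Cell types with
    fewer than ``min_cells`` cells are skipped.
    """
    if scope not in SCOPES:
        raise ConfigError(f"unknown DEG scope {scope!r}; choose from {SCOPES}")
    meta = metadata.set_index("cell_id").reindex(nm.cell_ids)
    if meta[["tissue", "cell_type", "compartment"]].isna().any().any():
        raise InputError("metadata does not cover all cells in the matrix")
    dense = nm.to_dense()
    tissue = meta["tissue"].to_numpy()
    comp = meta["compartment"].to_numpy()
    ctype = meta["cell_type"].to_numpy()

    units = sorted(set(zip(tissue, ctype)))
    tables = []
    for tis, ct in units:
        focal = (tissue == tis) & (ctype == ct)
        if focal.sum() < min_cells:
            continue
        focal_comp = comp[focal][0]
        if scope == "tissue":
            bg = (tissue == tis) & ~focal
        elif scope == "tissue_compartment":
            bg = (tissue == tis) & (comp == focal_comp) & ~focal
        elif scope == "atlas":
            bg = ~focal
        else:
            bg = (comp == focal_comp) & ~focal
        if bg.sum() == 0:
            raise InputError(f"empty background for ({tis}, {ct}) under scope {scope}")
        a, b = dense[focal], dense[bg]
        _, p = rank_sum_test(a, b, alternative="two-sided")
        p_adj = bh_adjust(p)
        lnfc = _fold_change(a.mean(axis=0), b.mean(axis=0))
        up = (p_adj < alpha) & (lnfc > 0)
        if not up.any():
            continue
        tab = pd.DataFrame(
            {
                "tissue": tis,
                "cell_type": ct,
                "scope": scope,
                "gene": nm.gene_ids[up],
                "lnfc": lnfc[up],
                "p": p[up],
                "p_adj": p_adj[up],
            }
        )
        tab = tab.sort_values(["p_adj", "lnfc", "gene"], ascending=[True, False, True])
        tab = tab.head(top_n).reset_index(drop=True)
        tab["rank"] = np.arange(1, len(tab) + 1)
        tables.append(tab)
    log_stage("ranked_degs", scope=scope, n_units=len(units), n_tables=len(tables))
    if not tables:
        return pd.DataFrame(
            columns=["tissue", "cell_type", "scope", "gene", "lnfc", "p", "p_adj", "rank"]
        )
    return pd.concat(tables, ignore_index=True)
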