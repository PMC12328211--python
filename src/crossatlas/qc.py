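"""Contamination filtering, cell QC cutoffs, UP10K normalization, pseudobulk.

The contamination filter resolves barcode index hopping among multiplexed
droplet samples of one sequencing run: a barcode observed in several samples
is kept only in its dominant sample (flagged "potentially contaminated") when
the dominant sample's UMI count is ten times or more greater than the second
most abundant sample's; otherwise every instance is removed. Ties at exactly
the dominance ratio count as dominant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossatlas.containers import CountMatrix, NormalizedMatrix, PseudobulkProfiles
from crossatlas.exceptions import ConfigError, InputError
from crossatlas.io import log_stage

DECISIONS = (
    "kept_unique",
    "kept_dominant_flagged",
    "removed_no_dominant",
    "removed_minor_echo",
)


def filter_hopped_barcodes(
    matrices: dict[str, CountMatrix],
    metadata: pd.DataFrame | None = None,
    dominance_ratio: float = 10.0,
):
    """Resolve multi-sample barcodes within one sequencing run.

    Returns ``(filtered, report, metadata)``. The report has one row per
    (barcode, sample) instance with its decision and, for multi-sample
    barcodes, the dominance ratio (max UMIs / second-max UMIs). With >= 3
    samples sharing a barcode, dominance is tested against the second most
    abundant only; all non-dominant instances are removed.
    """
    if dominance_ratio <= 1:
        raise InputError("dominance_ratio must exceed 1")
    for sample, cm in matrices.items():
        if len(set(cm.cell_ids.tolist())) != len(cm.cell_ids):
            raise InputError(f"duplicated barcode within sample {sample}")

    totals: dict[str, dict[str, int]] = {}
    for sample in sorted(matrices):
        cm = matrices[sample]
        t = cm.cell_totals()
        for bc, umis in zip(cm.cell_ids, t):
            totals.setdefault(bc, {})[sample] = int(umis)

    decision: dict[tuple, tuple] = {}
    flagged: set[str] = set()
    for bc, per_sample in totals.items():
        if len(per_sample) == 1:
            (sample,) = per_sample
            decision[(bc, sample)] = ("kept_unique", np.nan)
            continue
        ranked = sorted(per_sample.items(), key=lambda kv: (-kv[1], kv[0]))
        top_sample, top = ranked[0]
        second = ranked[1][1]
        ratio = np.inf if second == 0 else top / second
        if ratio >= dominance_ratio:
            decision[(bc, top_sample)] = ("kept_dominant_flagged", ratio)
            flagged.add(bc)
            for sample, _ in ranked[1:]:
                decision[(bc, sample)] = ("removed_minor_echo", ratio)
        else:
            for sample, _ in ranked:
                decision[(bc, sample)] = ("removed_no_dominant", ratio)

    filtered = {}
    for sample in sorted(matrices):
        cm = matrices[sample]
        keep = np.array(
            [decision[(bc, sample)][0].startswith("kept") for bc in cm.cell_ids]
        )
        filtered[sample] = cm.subset_cells(keep)

    report = pd.DataFrame(
        [
            {"barcode": bc, "sample": sample, "decision": dec, "dominance_ratio": ratio}
            for (bc, sample), (dec, ratio) in sorted(decision.items())
        ]
    )
    if metadata is not None:
        metadata = metadata.copy()
        kept = {bc for (bc, s), (d, _) in decision.items() if d.startswith("kept")}
        metadata = metadata[metadata["cell_id"].isin(kept)].reset_index(drop=True)
        metadata.loc[metadata["cell_id"].isin(flagged), "contamination_flag"] = True
    log_stage(
        "hopfilter",
        n_samples=len(matrices),
        dominance_ratio=dominance_ratio,
        n_barcodes=len(totals),
        n_flagged=len(flagged),
        n_removed=int((~report["decision"].str.startswith("kept")).sum()),
    )
    return filtered, report, metadata


def apply_cell_qc(cm: CountMatrix, stage: str, platform: str) -> CountMatrix:
    """Apply the platform/stage-specific per-cell QC cutoffs.

    droplet/annotation keeps cells with >100 genes detected OR >1,000 UMIs (a
    permissive floor used while annotating); droplet/final keeps cells with
    >= 500 genes detected; plate keeps cells with >= 500 genes AND >= 5,000
    reads. "Genes detected" counts genes with count >= 1.
    """
    if stage not in ("annotation", "final"):
        raise ConfigError(f"unknown QC stage {stage!r}")
    if platform not in ("droplet", "plate"):
        raise ConfigError(f"unknown platform {platform!r}")
    genes = cm.genes_detected()
    totals = cm.cell_totals()
    if platform == "droplet":
        if stage == "annotation":
            keep = (genes > 100) | (totals > 1000)
        else:
            keep = genes >= 500
    else:
        keep = (genes >= 500) & (totals >= 5000)
    log_stage("cell_qc", stage=stage, platform=platform, n_in=cm.n_cells, n_kept=int(keep.sum()))
    return cm.subset_cells(keep)


def normalize_up10k(cm: CountMatrix) -> NormalizedMatrix:
    """Scale each cell to counts per 10,000 and log-transform.

    value = ln(count / total x 1e4 + 1) per cell and gene, i.e. the
    ln(UP10K + 1) scale (ln(CP10K + 1) for plate reads). The transform is
    invariant to multiplying a cell's counts by any positive integer.
    """
    totals = cm.cell_totals()
    if (totals == 0).any():
        raise InputError("cells with zero total counts must be removed by QC first")
    scaled = sp.csr_matrix(cm.counts, dtype=np.float64, copy=True)
    per_entry_totals = np.repeat(totals.astype(np.float64), np.diff(scaled.indptr))
    # exact-products-first order keeps the transform bitwise invariant to
    # integer rescaling of a cell's counts
    scaled.data = np.log1p(scaled.data * 1e4 / per_entry_totals)
    return NormalizedMatrix(scaled, cm.cell_ids, cm.gene_ids)


def pseudobulk_means(
    nm: NormalizedMatrix,
    cell_types,
    min_cells: int = 1,
    convention: str = "mean-of-lognorm",
) -> PseudobulkProfiles:
    """Average expression per cell type.

    Two conventions: ``mean-of-lognorm`` (mean of per-cell ln(UP10K+1); used
    for the cross-species stages) and ``log-of-mean`` (ln(mean UP10K + 1);
    used for the cell-type map). Cell types with fewer than ``min_cells``
    cells are dropped and reported in ``dropped``.
    """
    if convention not in ("mean-of-lognorm", "log-of-mean"):
        raise ConfigError(f"unknown pseudobulk convention {convention!r}")
    if min_cells < 1:
        raise InputError("min_cells must be >= 1")
    if isinstance(cell_types, pd.Series):
        labels = cell_types.reindex(nm.cell_ids).to_numpy()
    else:
        labels = np.asarray(cell_types, dtype=object)
        if len(labels) != nm.n_cells:
            raise InputError("cell_types length does not match the matrix")
    if pd.isna(labels).any():
        raise InputError("every cell must carry a cell-type label")

    order = pd.unique(labels)
    rows, kept, n_cells, dropped = [], [], [], {}
    for ct in sorted(order):
        idx = np.flatnonzero(labels == ct)
        if len(idx) < min_cells:
            dropped[str(ct)] = len(idx)
            continue
        block = nm.values[idx]
        if convention == "mean-of-lognorm":
            prof = np.asarray(block.mean(axis=0)).ravel()
        else:
            up10k = block.copy()
            up10k.data = np.expm1(up10k.data)
            prof = np.log1p(np.asarray(up10k.mean(axis=0)).ravel())
        rows.append(prof)
        kept.append(str(ct))
        n_cells.append(len(idx))
    profile = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, nm.n_genes)),
        index=pd.Index(kept, name="cell_type"),
        columns=nm.gene_ids,
    )
    log_stage(
        "pseudobulk",
        convention=convention,
        min_cells=min_cells,
        n_types=len(kept),
        n_dropped=len(dropped),
    )
    return PseudobulkProfiles(
        profile=profile,
        n_cells=pd.Series(n_cells, index=profile.index, dtype=int),
        convention=convention,
        min_cells=min_cells,
        dropped=dropped,
    )
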