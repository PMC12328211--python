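"""Core in-memory data model.

Counts are held as sparse cells x genes matrices (UMIs for droplet data, reads
for plate data); normalized expression is on the ln(UP10K + 1) scale, i.e.
``ln(count / total * 1e4 + 1)`` per cell and gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossatlas.exceptions import InputError

PLATFORMS = ("droplet", "plate")

#: Required columns of a per-cell metadata table.
METADATA_COLUMNS = (
    "cell_id",
    "individual",
    "tissue",
    "sample_index",
    "sequencing_run",
    "compartment",
    "cell_type",
    "contamination_flag",
)


def _as_int_csr(counts) -> sp.csr_matrix:
    m = sp.csr_matrix(counts)
    if m.nnz and m.data.min() < 0:
        raise InputError("count matrix has negative entries")
    if m.nnz and not np.allclose(m.data, np.round(m.data)):
        raise InputError("count matrix has non-integer entries")
    m = m.astype(np.int64)
    m.eliminate_zeros()
    return m


def _check_ids(ids, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr.tolist())) != len(arr):
        raise InputError(f"duplicate {what}")
    return arr.astype(str)


@dataclass
class CountMatrix:
    """Sparse cells x genes non-negative integer counts with identifiers.

    Internal coordinates are 0-based; the Matrix Market files on disk use the
    standard 1-based indices (genes x cells, 10x dialect).
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    platform: str = "droplet"

    def __post_init__(self) -> None:
        self.counts = _as_int_csr(self.counts)
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.platform not in PLATFORMS:
            raise InputError(f"unknown platform {self.platform!r}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs (or reads) per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count >= 1 per cell."""
        return np.diff(self.counts.indptr)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            self.counts[idx], self.cell_ids[idx], self.gene_ids, self.platform
        )

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.platform == other.platform
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class NormalizedMatrix:
    """Cells x genes expression on the ln(UP10K + 1) (or ln(CP10K + 1)) scale.

    For every cell, ``sum over genes of expm1(value)`` equals 1e4 (relative
    tolerance 1e-6); cells with zero totals must be removed upstream.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.cell_ids = _check_ids(self.cell_ids, "cell_ids")
        self.gene_ids = _check_ids(self.gene_ids, "gene_ids")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise InputError("values shape does not match id axes")
        if self.values.nnz and self.values.data.min() < 0:
            raise InputError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_idx)
        return NormalizedMatrix(self.values[idx], self.cell_ids[idx], self.gene_ids)


@dataclass
class PseudobulkProfiles:
    """Cell-type x gene mean normalized expression with per-type cell counts."""

    profile: pd.DataFrame  # index: cell_type, columns: gene ids
    n_cells: pd.Series  # index: cell_type
    convention: str = "mean-of-lognorm"
    min_cells: int = 1
    dropped: dict = field(default_factory=dict)  # cell_type -> n_cells below floor

    def __post_init__(self) -> None:
        if not self.profile.index.equals(self.n_cells.index):
            raise InputError("profile and n_cells indexed by different cell types")
        if (self.n_cells < self.min_cells).any():
            raise InputError("profiles retained below the min_cells floor")
        if self.profile.size and float(self.profile.to_numpy().min()) < 0:
            raise InputError("pseudobulk profile values must be non-negative")


def validate_cell_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Coerce a per-cell metadata table to the expected schema.

    ``contamination_flag`` is added (False) when absent; one row per cell_id is
    enforced.
    """
    from crossatlas.exceptions import SchemaError

    meta = meta.copy()
    if "contamination_flag" not in meta.columns:
        meta["contamination_flag"] = False
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"cell metadata missing required columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise SchemaError("cell metadata has duplicated cell_id records")
    meta["contamination_flag"] = meta["contamination_flag"].astype(bool)
    return meta


#: Alias kept for symmetry with the data model: a validated metadata table.
CellMetadata = pd.DataFrame
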