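"""Readers and writers for the standard on-disk containers.

Count matrices live as Matrix Market triplets in the 10x dialect: a
``matrix.mtx`` of genes x cells integer counts plus ``barcodes.tsv`` and
``genes.tsv`` (one id per line; a second gene-name column is tolerated).
Result tables are TSV; trajectory polylines are JSON. Reals are serialized
with 9 significant digits, which is the comparison tolerance for golden files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from crossatlas.containers import CountMatrix, NormalizedMatrix
from crossatlas.exceptions import FormatError, InputError, SchemaError

logger = logging.getLogger("crossatlas")

FLOAT_FORMAT = "%.9g"


def log_stage(_stage_name: str, **fields) -> None:
    """One structured log line per pipeline stage (shapes, parameters, counts)."""
    payload = " ".join(f"{k}={v}" for k, v in sorted(fields.items()))
    logger.info("stage=%s %s", _stage_name, payload)


def _read_id_file(path: Path) -> np.ndarray:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return np.asarray(ids, dtype=object)


def read_count_matrix(matrix_path, barcodes_path, genes_path, platform: str = "droplet") -> CountMatrix:
    """Read a genes x cells MTX triplet into a cells x genes CountMatrix.

    1-based on-disk MTX indices become internal 0-based axes.
    """
    try:
        mat = sio.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"invalid MTX file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    barcodes = _read_id_file(Path(barcodes_path))
    genes = _read_id_file(Path(genes_path))
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX header declares {mat.shape[0]} genes x {mat.shape[1]} cells but id "
            f"files have {len(genes)} genes and {len(barcodes)} barcodes"
        )
    if mat.nnz:
        if mat.data.min() < 0:
            raise InputError("MTX contains negative counts")
        if not np.allclose(mat.data, np.round(mat.data)):
            raise InputError("MTX contains non-integer counts")
    return CountMatrix(mat.T.tocsr(), barcodes, genes, platform=platform)


def write_count_matrix(cm: CountMatrix, out_dir) -> dict:
    """Write a CountMatrix as a matrix.mtx/barcodes.tsv/genes.tsv triplet.

    ``read_count_matrix(**write_count_matrix(cm))`` reproduces ``cm`` exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix_path": out / "matrix.mtx",
        "barcodes_path": out / "barcodes.tsv",
        "genes_path": out / "genes.tsv",
    }
    sio.mmwrite(str(paths["matrix_path"]), cm.counts.T.tocoo(), field="integer")
    paths["barcodes_path"].write_text("".join(f"{b}\n" for b in cm.cell_ids))
    paths["genes_path"].write_text("".join(f"{g}\n" for g in cm.gene_ids))
    return paths


def write_normalized_matrix(nm: NormalizedMatrix, out_dir) -> dict:
    """Write normalized values as a real-valued MTX triplet (9 sig. digits)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix_path": out / "matrix.mtx",
        "barcodes_path": out / "barcodes.tsv",
        "genes_path": out / "genes.tsv",
    }
    sio.mmwrite(str(paths["matrix_path"]), nm.values.T.tocoo(), field="real", precision=9)
    paths["barcodes_path"].write_text("".join(f"{b}\n" for b in nm.cell_ids))
    paths["genes_path"].write_text("".join(f"{g}\n" for g in nm.gene_ids))
    return paths


def read_normalized_matrix(matrix_path, barcodes_path, genes_path) -> NormalizedMatrix:
    mat = sp.coo_matrix(sio.mmread(str(matrix_path)))
    barcodes = _read_id_file(Path(barcodes_path))
    genes = _read_id_file(Path(genes_path))
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError("MTX dimensions do not match id files")
    return NormalizedMatrix(mat.T.tocsr(), barcodes, genes)


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a TSV with a header row, typing columns per ``schema``.

    ``schema`` maps required column names to dtypes; unknown extra columns are
    preserved as strings. A missing required column raises SchemaError.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"table {path} missing required columns: {missing}")
        for col, dtype in schema.items():
            if dtype is bool:
                df[col] = df[col].str.lower().map({"true": True, "false": False, "1": True, "0": False})
                if df[col].isna().any():
                    raise SchemaError(f"column {col} in {path} has non-boolean values")
            else:
                try:
                    df[col] = df[col].astype(dtype)
                except ValueError as exc:
                    raise SchemaError(f"column {col} in {path}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with reals at 9 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_trajectory_json(traj, path) -> None:
    """Serialize a Trajectory (branch polylines + tree) as JSON."""
    payload = {
        "branches": [
            {
                "id": b.id,
                "parent": b.parent,
                "arc_offset": round(float(b.arc_offset), 9),
                "points": [[float(f"{x:.9g}"), float(f"{y:.9g}")] for x, y in b.points],
            }
            for b in traj.branches
        ]
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_trajectory_json(path):
    from crossatlas.trajectory import Branch, Trajectory

    with open(path) as fh:
        payload = json.load(fh)
    branches = [
        Branch(
            id=b["id"],
            parent=b["parent"],
            points=np.asarray(b["points"], dtype=float),
            arc_offset=float(b["arc_offset"]),
        )
        for b in payload["branches"]
    ]
    return Trajectory(branches=branches)
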