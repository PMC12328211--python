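"""Merge NCBI- and Ensembl-style orthology tables and keep one-to-one-to-one
orthologues.

Anchor genes (the reference species' genes) are dropped when a required
species has no assigned orthologue in either source, when more than one
orthologue is assigned in any required species (union semantics: a
NCBI/Ensembl disagreement yields two candidates and hence a drop), or when
two anchors share the same orthologue in any species (both anchors are
dropped). Ensembl's own ``ortholog_one2one`` tag is deliberately not used as
a filter: imperfect genome annotation makes it unreliable, so the rules above
operate on the merged assignments directly. Id matching is case-sensitive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from crossatlas.exceptions import InputError, SchemaError
from crossatlas.io import log_stage

DROP_REASONS = ("missing_orthologue", "multi_mapped", "shared_target")


def _clean(df: pd.DataFrame, cols) -> tuple[pd.DataFrame, int]:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"ortholog table missing columns: {missing}")
    out = df[list(cols)].astype(str)
    bad = (out == "") | out.isin(["nan", "None", "NA"])
    n_bad = int(bad.any(axis=1).sum())
    return out[~bad.any(axis=1)], n_bad


def merge_ortholog_tables(
    ncbi: pd.DataFrame, ensembl: pd.DataFrame, anchors=None
) -> pd.DataFrame:
    """Union the per-(anchor, species) assignments of both sources.

    ``ncbi`` has columns (anchor_gene_id, species, ortholog_gene_id);
    ``ensembl`` has (ncbi_gene_id, species, ortholog_gene_id) and is joined to
    the anchor via its NCBI gene id column. Conflicting assignments survive as
    multiple candidate rows (dropped downstream as multi-mapped). Provenance
    is ``ncbi``, ``ensembl`` or ``both`` per candidate. Rows with malformed
    keys are skipped and counted in the ``skipped`` attribute.
    """
    n_rows, n_skipped_n = _clean(ncbi, ("anchor_gene_id", "species", "ortholog_gene_id"))
    e_rows, n_skipped_e = _clean(ensembl, ("ncbi_gene_id", "species", "ortholog_gene_id"))
    e_rows = e_rows.rename(columns={"ncbi_gene_id": "anchor_gene_id"})
    n_rows = n_rows.assign(source="ncbi")
    e_rows = e_rows.assign(source="ensembl")
    merged = pd.concat([n_rows, e_rows], ignore_index=True)
    cand = (
        merged.groupby(["anchor_gene_id", "species", "ortholog_gene_id"])["source"]
        .agg(lambda s: "both" if len(set(s)) == 2 else s.iloc[0])
        .rename("provenance")
        .reset_index()
        .sort_values(["anchor_gene_id", "species", "ortholog_gene_id"])
        .reset_index(drop=True)
    )
    if anchors is not None:
        extra = sorted(set(map(str, anchors)) - set(cand["anchor_gene_id"]))
        if extra:
            cand = pd.concat(
                [cand, pd.DataFrame({"anchor_gene_id": extra})], ignore_index=True
            )
    cand.attrs["skipped"] = n_skipped_n + n_skipped_e
    log_stage(
        "ortho_merge",
        n_candidates=len(cand),
        n_anchors=cand["anchor_gene_id"].nunique(),
        n_skipped=cand.attrs["skipped"],
    )
    return cand


def filter_one2one(
    candidates: pd.DataFrame,
    required_species=("human", "mouse"),
    anchors=None,
):
    """Apply the one-to-one-to-one filters to merged candidates.

    Drops anchors missing an orthologue in any required species, anchors with
    more than one candidate orthologue in a required species, and every pair
    of anchors that shares a per-species orthologue (both members dropped).
    Returns ``(table, ledger)``: a wide surviving table with one
    ``<species>_gene_id`` column per required species, and a per-anchor drop
    ledger with the first matching reason. Idempotent; survivors form an
    injective per-species matching.
    """
    required = list(required_species)
    cand = candidates.dropna(subset=["species", "ortholog_gene_id"]) if len(candidates) else candidates
    universe = set(candidates["anchor_gene_id"]) if len(candidates) else set()
    if anchors is not None:
        universe |= set(map(str, anchors))
    universe = sorted(universe)
    if not universe:
        return (
            pd.DataFrame(columns=["anchor_gene_id"] + [f"{s}_gene_id" for s in required]),
            pd.DataFrame(columns=["anchor_gene_id", "dropped", "reason"]),
        )

    per_anchor: dict[str, dict[str, list]] = {a: {} for a in universe}
    prov: dict[tuple, str] = {}
    if len(cand):
        for row in cand.itertuples(index=False):
            per_anchor.setdefault(row.anchor_gene_id, {}).setdefault(row.species, []).append(
                row.ortholog_gene_id
            )
            prov[(row.anchor_gene_id, row.species)] = getattr(row, "provenance", "ncbi")

    reason: dict[str, str] = {}
    for a in universe:
        sp_map = per_anchor.get(a, {})
        if any(len(sp_map.get(s, [])) == 0 for s in required):
            reason[a] = "missing_orthologue"
        elif any(len(set(sp_map.get(s, []))) > 1 for s in required):
            reason[a] = "multi_mapped"

    survivors = [a for a in universe if a not in reason]
    for s in required:
        targets: dict[str, list] = {}
        for a in survivors:
            targets.setdefault(per_anchor[a][s][0], []).append(a)
        for tgt, owners in targets.items():
            if len(owners) > 1:
                for a in owners:
                    reason.setdefault(a, "shared_target")
    survivors = [a for a in universe if a not in reason]

    rows = []
    for a in survivors:
        rec = {"anchor_gene_id": a}
        for s in required:
            rec[f"{s}_gene_id"] = per_anchor[a][s][0]
            rec[f"{s}_provenance"] = prov.get((a, s), "")
        rows.append(rec)
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["anchor_gene_id"] + [f"{s}_gene_id" for s in required]
    )
    ledger = pd.DataFrame(
        {
            "anchor_gene_id": universe,
            "dropped": [a in reason for a in universe],
            "reason": [reason.get(a, "") for a in universe],
        }
    )
    log_stage(
        "ortho_filter",
        n_anchors=len(universe),
        n_survivors=len(survivors),
        **{f"n_{r}": sum(v == r for v in reason.values()) for r in DROP_REASONS},
    )
    return table, ledger


def append_optional_species(
    table: pd.DataFrame, human_to_other: pd.DataFrame, species: str = "macaque"
) -> pd.DataFrame:
    """Join an optional species' one-to-one orthologues through the human id.

    ``human_to_other`` has columns (human_gene_id, ortholog_gene_id); only
    anchors whose human orthologue maps uniquely gain a ``<species>_gene_id``
    column (others get an empty value).
    """
    pairs, _ = _clean(human_to_other, ("human_gene_id", "ortholog_gene_id"))
    counts = pairs.groupby("human_gene_id")["ortholog_gene_id"].nunique()
    unique = pairs[pairs["human_gene_id"].map(counts) == 1].drop_duplicates()
    mapping = dict(zip(unique["human_gene_id"], unique["ortholog_gene_id"]))
    out = table.copy()
    if "human_gene_id" not in out.columns:
        raise InputError("table lacks a human_gene_id column to join through")
    out[f"{species}_gene_id"] = out["human_gene_id"].map(mapping).fillna("")
    return out
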