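"""Synthetic-atlas generators with planted ground truth.

Every downstream stage of the pipeline is exercised on data from this module:
discrete cell types with planted marker genes, branched trajectories with
unimodal gene programs, multi-sample sequencing runs with injected barcode
hopping, species trios with planted gene-conservation classes, and toy
ortholog tables with planted mapping conflicts. The generators emit ordinary
``CountMatrix`` containers plus truth tables sufficient to score each stage
without re-deriving the generator.

Counts are Poisson or negative-binomial (gamma-Poisson, variance
mu + mu^2 * dispersion) draws around per-cell expected rates; library sizes
are log-normal, the typical droplet regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from crossatlas.containers import CountMatrix, validate_cell_metadata
from crossatlas.exceptions import SpecError

_BASES = np.array(list("ACGT"))


def _barcodes(rng: np.random.Generator, n: int, length: int = 14) -> np.ndarray:
    """Unique random cell barcodes."""
    seen: set[str] = set()
    out = []
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n, length))
        for row in batch:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return np.asarray(out, dtype=object)


def _draw_counts(rng, mu: np.ndarray, noise: str, dispersion: float) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(mu)
    if noise == "negative_binomial":
        if dispersion <= 0:
            raise SpecError("negative_binomial requires dispersion > 0")
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu * dispersion)
        return rng.poisson(lam)
    raise SpecError(f"unknown count noise model {noise!r}")


# ---------------------------------------------------------------------------
# discrete cell types with planted markers
# ---------------------------------------------------------------------------


@dataclass
class AtlasSimSpec:
    """Conditions for a discrete-cell-type atlas simulation."""

    n_cell_types: int = 3
    cells_per_type: int = 50
    n_genes: int = 200
    n_markers: int = 5  # markers per cell type, disjoint gene sets
    marker_fold: float = 8.0  # fold elevation of expected expression
    library_log_mean: float = math.log(5000.0)
    library_log_sd: float = 0.35
    noise: str = "poisson"
    dispersion: float = 0.5
    tissue: str = "tissue1"
    platform: str = "droplet"

    def validate(self) -> None:
        if min(self.n_cell_types, self.cells_per_type, self.n_genes) < 1:
            raise SpecError("all counts must be >= 1")
        if self.marker_fold <= 1:
            raise SpecError("marker effect size must exceed 1")
        if self.n_markers * self.n_cell_types > self.n_genes:
            raise SpecError("n_markers x n_cell_types exceeds n_genes")


_COMPARTMENTS = ("epithelial", "immune", "stromal", "endothelial", "neural", "germ")


def simulate_atlas(
    spec: AtlasSimSpec,
    seed: int,
    sample_index: str = "S1",
    sequencing_run: str = "run1",
    individual: str = "ind1",
):
    """Simulate one sample of discrete cell types with planted markers.

    Returns ``(CountMatrix, metadata, truth)`` where ``truth['markers']`` maps
    each cell type to its planted marker gene ids. Each marker's expected
    relative expression is elevated ``marker_fold``-fold in its own type.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    gene_ids = np.array([f"G{i:05d}" for i in range(spec.n_genes)], dtype=object)
    base = rng.lognormal(0.0, 1.0, spec.n_genes)

    markers: dict[str, list[str]] = {}
    weights = []
    marker_idx = rng.permutation(spec.n_genes)[: spec.n_markers * spec.n_cell_types]
    for t in range(spec.n_cell_types):
        ct = f"type{t:02d}"
        idx = marker_idx[t * spec.n_markers : (t + 1) * spec.n_markers]
        w = base.copy()
        w[idx] *= spec.marker_fold
        weights.append(w / w.sum())
        markers[ct] = gene_ids[np.sort(idx)].tolist()

    n_cells = spec.n_cell_types * spec.cells_per_type
    libsizes = rng.lognormal(spec.library_log_mean, spec.library_log_sd, n_cells)
    labels = np.repeat([f"type{t:02d}" for t in range(spec.n_cell_types)], spec.cells_per_type)
    rows = []
    for i in range(n_cells):
        p = weights[i // spec.cells_per_type]
        rows.append(_draw_counts(rng, libsizes[i] * p, spec.noise, spec.dispersion))
    counts = sp.csr_matrix(np.vstack(rows))
    cell_ids = _barcodes(rng, n_cells)
    cm = CountMatrix(counts, cell_ids, gene_ids, platform=spec.platform)
    meta = validate_cell_metadata(
        pd.DataFrame(
            {
                "cell_id": cell_ids,
                "individual": individual,
                "tissue": spec.tissue,
                "sample_index": sample_index,
                "sequencing_run": sequencing_run,
                # at least two cell types share each compartment so that
                # compartment-scoped DEG backgrounds are never empty
                "compartment": [
                    _COMPARTMENTS[
                        int(lbl[4:]) % max(1, min(spec.n_cell_types // 2, len(_COMPARTMENTS)))
                    ]
                    for lbl in labels
                ],
                "cell_type": labels,
            }
        )
    )
    truth = {"markers": markers, "library_sizes": libsizes}
    return cm, meta, truth


def simulate_run(spec: AtlasSimSpec, n_samples: int, seed: int, run: str = "run1"):
    """Simulate ``n_samples`` multiplexed samples of one sequencing run.

    Barcodes are globally unique across samples before any hopping is
    injected. Returns ``(matrices, metadata, truths)`` keyed by sample index.
    """
    if n_samples < 1:
        raise SpecError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    matrices, metas, truths = {}, [], {}
    for k in range(n_samples):
        sample = f"S{k + 1}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cm, meta, truth = simulate_atlas(
            spec, sub_seed, sample_index=sample, sequencing_run=run
        )
        matrices[sample] = cm
        metas.append(meta)
        truths[sample] = truth
    # re-draw any barcode collisions across samples (vanishingly rare)
    seen: set[str] = set()
    for sample, cm in matrices.items():
        clash = [i for i, b in enumerate(cm.cell_ids) if b in seen]
        if clash:
            fresh = _barcodes(rng, len(clash) + len(seen))
            fresh = [b for b in fresh if b not in seen][: len(clash)]
            ids = cm.cell_ids.copy()
            for i, b in zip(clash, fresh):
                ids[i] = b
            matrices[sample] = CountMatrix(cm.counts, ids, cm.gene_ids, cm.platform)
        seen.update(matrices[sample].cell_ids.tolist())
    meta = pd.concat(metas, ignore_index=True)
    meta["cell_id"] = np.concatenate([matrices[s].cell_ids for s in matrices])
    return matrices, validate_cell_metadata(meta), truths


def inject_index_hopping(
    matrices: dict[str, CountMatrix],
    hop_rate: float,
    seed: int,
    adversarial: bool = False,
):
    """Add low-UMI barcode echoes across samples of one sequencing run.

    For a ``hop_rate`` fraction of barcodes, an echo is added under the same
    barcode in another sample, with a per-gene binomial thinning of the source
    counts at ratio Uniform(0.005, 0.08) (default) so the 10x dominance rule is
    decisively satisfied, or Uniform(0.08, 0.3) in adversarial mode to exercise
    the no-dominant-sample branch. Returns ``(contaminated, truth)``.
    """
    if len(matrices) < 2:
        raise SpecError("index hopping requires >= 2 multiplexed samples")
    if not 0.0 <= hop_rate <= 0.2:
        raise SpecError("hop_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    samples = sorted(matrices)
    out = {s: matrices[s] for s in samples}
    records = []
    if hop_rate == 0:
        truth = pd.DataFrame(
            columns=["barcode", "source_sample", "target_sample", "ratio", "source_umis", "echo_umis"]
        )
        return out, truth

    pool = [(s, i) for s in samples for i in range(matrices[s].n_cells)]
    n_hop = int(round(hop_rate * len(pool)))
    chosen = rng.choice(len(pool), size=n_hop, replace=False)
    lo, hi = (0.08, 0.3) if adversarial else (0.005, 0.08)

    extra_rows: dict[str, list] = {s: [] for s in samples}
    extra_ids: dict[str, list] = {s: [] for s in samples}
    for ci in sorted(chosen):
        src_sample, row = pool[ci]
        others = [s for s in samples if s != src_sample]
        tgt = others[int(rng.integers(len(others)))]
        barcode = matrices[src_sample].cell_ids[row]
        source = np.asarray(matrices[src_sample].counts[row].todense()).ravel()
        ratio = float(rng.uniform(lo, hi))
        echo = rng.binomial(source, ratio)
        if echo.sum() == 0:  # guarantee the barcode surfaces in the target sample
            echo[int(source.argmax())] = 1
        extra_rows[tgt].append(echo)
        extra_ids[tgt].append(barcode)
        records.append(
            {
                "barcode": barcode,
                "source_sample": src_sample,
                "target_sample": tgt,
                "ratio": ratio,
                "source_umis": int(source.sum()),
                "echo_umis": int(echo.sum()),
            }
        )
    for s in samples:
        if not extra_rows[s]:
            continue
        cm = out[s]
        stacked = sp.vstack([cm.counts, sp.csr_matrix(np.vstack(extra_rows[s]))])
        ids = np.concatenate([cm.cell_ids, np.asarray(extra_ids[s], dtype=object)])
        out[s] = CountMatrix(stacked.tocsr(), ids, cm.gene_ids, cm.platform)
    truth = pd.DataFrame.from_records(records)
    return out, truth


# ---------------------------------------------------------------------------
# branched trajectories with unimodal gene programs
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySimSpec:
    """Conditions for a branched-trajectory simulation.

    ``branches`` lists (parent index, length) pairs, parent -1 for the root.
    Program genes follow Gaussian bumps of expected ln-expression along the
    latent position s in [0, 1]; noise genes are position-independent.
    """

    branches: tuple = ((-1, 1.0),)
    n_cells: int = 400
    n_program_genes: int = 50
    n_noise_genes: int = 500
    peak_width: float = 0.1
    amplitude: float = 2.5  # peak ln(UP10K + 1) level of program genes
    noise_sd: float = 0.05  # embedding noise, fraction of the longest root-to-tip path
    library_log_mean: float = math.log(5000.0)
    library_log_sd: float = 0.3
    noise: str = "poisson"
    dispersion: float = 0.5

    def validate(self) -> None:
        if not self.branches:
            raise SpecError("at least one branch required")
        for parent, length in self.branches:
            if length <= 0:
                raise SpecError("branch lengths must be positive")
            if parent >= 0 and parent >= len(self.branches):
                raise SpecError("branch parent index out of range")
        if self.peak_width <= 0:
            raise SpecError("peak widths must be positive")


def _branch_geometry(spec: TrajectorySimSpec):
    """Lay branches out in the plane: root along +x, children fanning out."""
    starts, dirs, offsets = [], [], []
    angles = {}
    child_count: dict[int, int] = {}
    for bid, (parent, length) in enumerate(spec.branches):
        if parent < 0:
            start = np.zeros(2)
            angle = 0.0
            offset = 0.0
        else:
            p_start = starts[parent]
            p_len = spec.branches[parent][1]
            start = p_start + dirs[parent] * p_len
            k = child_count.get(parent, 0)
            child_count[parent] = k + 1
            angle = angles[parent] + (40.0 if k % 2 == 0 else -40.0) * math.pi / 180.0
            offset = offsets[parent] + p_len
        angles[bid] = angle
        starts.append(start)
        dirs.append(np.array([math.cos(angle), math.sin(angle)]))
        offsets.append(offset)
    return starts, dirs, offsets


def simulate_trajectory(spec: TrajectorySimSpec, seed: int):
    """Simulate cells along a branched 2D trajectory with gene programs.

    Returns ``(CountMatrix, truth)``. ``truth['cells']`` holds per-cell branch
    id, latent position s, and the noiseless/noisy 2D layout coordinates;
    ``truth['programs']`` lists each program gene's peak position and width.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    starts, dirs, offsets = _branch_geometry(spec)
    lengths = np.array([b[1] for b in spec.branches])
    tip_len = max(offsets[b] + lengths[b] for b in range(len(lengths)))

    branch_of = rng.choice(len(lengths), size=spec.n_cells, p=lengths / lengths.sum())
    u = rng.uniform(0.0, 1.0, spec.n_cells) * lengths[branch_of]
    s = (np.array([offsets[b] for b in branch_of]) + u) / tip_len
    xy = np.stack(
        [starts[b] + dirs[b] * ui for b, ui in zip(branch_of, u)]
    ) + rng.normal(0.0, spec.noise_sd * tip_len, (spec.n_cells, 2))

    n_genes = spec.n_program_genes + spec.n_noise_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    peaks = (np.arange(spec.n_program_genes) + 0.5) / max(spec.n_program_genes, 1)
    base = rng.uniform(0.5, 1.5, spec.n_noise_genes)

    # expected ln-expression per cell x gene
    m = np.empty((spec.n_cells, n_genes))
    for g in range(spec.n_program_genes):
        m[:, g] = spec.amplitude * np.exp(-((s - peaks[g]) ** 2) / (2 * spec.peak_width**2))
    m[:, spec.n_program_genes :] = base[None, :]

    lam = np.expm1(m)
    lam /= lam.sum(axis=1, keepdims=True)
    libsizes = rng.lognormal(spec.library_log_mean, spec.library_log_sd, spec.n_cells)
    counts = _draw_counts(rng, lam * libsizes[:, None], spec.noise, spec.dispersion)
    cell_ids = np.array([f"cell{i:05d}" for i in range(spec.n_cells)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, gene_ids)
    truth = {
        "cells": pd.DataFrame(
            {
                "cell_id": cell_ids,
                "branch": branch_of,
                "s": s,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        ),
        "programs": pd.DataFrame(
            {
                "gene": gene_ids[: spec.n_program_genes],
                "peak": peaks,
                "width": spec.peak_width,
                "amplitude": spec.amplitude,
            }
        ),
    }
    return cm, truth


# ---------------------------------------------------------------------------
# species trios with planted conservation classes
# ---------------------------------------------------------------------------

DEFAULT_CLASS_PROPORTIONS = {
    "highly_conserved": 0.11,
    "hl": 0.10,
    "hm": 0.08,
    "lm": 0.08,
    "primate_enriched": 0.02,
    "primate_depleted": 0.02,
    "unconserved": 0.59,
}


@dataclass
class SpeciesTrioSimSpec:
    """Conditions for a human/lemur/mouse (optionally macaque) trio simulation.

    Per-gene cell-type patterns of expected ln-expression are drawn once per
    conservation class: conserved partners share a pattern (plus independent
    Gaussian noise of sd ``noise_sd``), divergent species draw independent
    patterns. Primate-enriched/depleted genes obey the 5-fold construction in
    one designated cell type.
    """

    species: tuple = ("human", "lemur", "mouse")
    n_cell_types: int = 63
    cells_per_type: int = 20
    n_genes: int = 1000
    class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    pattern_scale: float = 0.8  # exponential scale of ln-expression patterns
    pattern_cap: float = 4.0  # cap on ln-expression; keeps library composition stable
    noise_sd: float = 0.1
    selective_high: float = 2.2  # ln-level in the designated type
    selective_low: float = 0.05
    library_log_mean: float = math.log(5000.0)
    library_log_sd: float = 0.3
    noise: str = "poisson"
    dispersion: float = 0.5

    def validate(self) -> None:
        if len(self.species) not in (3, 4):
            raise SpecError("species list must have 3 or 4 entries")
        if self.n_cell_types < 2:
            raise SpecError(">= 2 shared cell types required")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"class proportions sum to {total}, not 1")


def _class_counts(proportions: dict, n_genes: int) -> dict:
    counts = {k: int(math.floor(v * n_genes)) for k, v in proportions.items()}
    rem = n_genes - sum(counts.values())
    order = sorted(proportions, key=lambda k: -proportions[k])
    for k in order[:rem]:
        counts[k] += 1
    return counts


def simulate_species_trio(spec: SpeciesTrioSimSpec, seed: int):
    """Simulate per-species count matrices over shared cell types.

    Returns ``(per_species, truth)``: ``per_species`` maps species name to
    ``(CountMatrix, labels)`` with labels a Series of cell types indexed by
    cell id; ``truth`` is a per-gene table of planted class and, for
    primate-selective genes, the designated cell type.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    primates = [s for s in spec.species if s != "mouse"]
    if "mouse" not in spec.species:
        raise SpecError("the species list must include the mouse outgroup")
    n_t, n_g = spec.n_cell_types, spec.n_genes
    gene_ids = np.array([f"OG{i:05d}" for i in range(n_g)], dtype=object)
    types = [f"ct{t:02d}" for t in range(n_t)]

    counts_per_class = _class_counts(spec.class_proportions, n_g)
    classes = np.concatenate(
        [np.repeat(k, v) for k, v in sorted(counts_per_class.items())]
    )
    classes = classes[rng.permutation(n_g)]

    def pattern(scale=None):
        return np.minimum(rng.exponential(scale or spec.pattern_scale, n_t), spec.pattern_cap)

    means = {s: np.zeros((n_g, n_t)) for s in spec.species}
    designated = np.full(n_g, "", dtype=object)
    for g in range(n_g):
        cls = classes[g]
        if cls == "highly_conserved":
            shared = pattern()
            for s in spec.species:
                means[s][g] = shared
        elif cls in ("hl", "hm", "lm"):
            pair = {"hl": ("human", "lemur"), "hm": ("human", "mouse"), "lm": ("lemur", "mouse")}[cls]
            shared, indep = pattern(), pattern()
            for s in spec.species:
                means[s][g] = shared if s in pair or (s == "macaque" and "human" in pair) else indep
        elif cls in ("primate_enriched", "primate_depleted"):
            shared = pattern(spec.pattern_scale * 0.3)
            t_star = int(rng.integers(n_t))
            designated[g] = types[t_star]
            for s in spec.species:
                prof = shared.copy()
                is_primate = s != "mouse"
                high_here = is_primate if cls == "primate_enriched" else not is_primate
                prof[t_star] = spec.selective_high if high_here else spec.selective_low
                means[s][g] = prof
        else:  # unconserved
            for s in spec.species:
                means[s][g] = pattern()
    for s in spec.species:
        means[s] = np.maximum(means[s] + rng.normal(0.0, spec.noise_sd, (n_g, n_t)), 0.0)

    per_species = {}
    for s in spec.species:
        lam = np.expm1(means[s])  # genes x types
        lam_frac = lam / lam.sum(axis=0, keepdims=True)
        rows, ids, labels = [], [], []
        for t, ct in enumerate(types):
            libs = rng.lognormal(spec.library_log_mean, spec.library_log_sd, spec.cells_per_type)
            mu = np.outer(libs, lam_frac[:, t])
            rows.append(_draw_counts(rng, mu, spec.noise, spec.dispersion))
            ids.extend(f"{s}_{ct}_c{i:03d}" for i in range(spec.cells_per_type))
            labels.extend([ct] * spec.cells_per_type)
        cm = CountMatrix(sp.csr_matrix(np.vstack(rows)), np.asarray(ids, dtype=object), gene_ids)
        per_species[s] = (cm, pd.Series(labels, index=ids, name="cell_type"))

    truth = pd.DataFrame({"gene": gene_ids, "cls": classes, "designated_type": designated})
    return per_species, truth


# ---------------------------------------------------------------------------
# toy ortholog tables with planted conflicts
# ---------------------------------------------------------------------------


def simulate_ortholog_tables(
    n_anchors: int = 200,
    seed: int = 0,
    frac_missing: float = 0.1,
    frac_multi: float = 0.1,
    frac_conflict: float = 0.05,
    frac_shared: float = 0.1,
):
    """Build NCBI- and Ensembl-style ortholog tables with planted conflicts.

    Planted categories per anchor gene: ``clean`` (one orthologue per species,
    agreed by both sources), ``missing`` (no orthologue in one species in
    either source), ``multi`` (NCBI lists two orthologues for one species),
    ``conflict`` (NCBI and Ensembl name different orthologues) and ``shared``
    (pairs of anchors assigned the same orthologue). Returns
    ``(ncbi, ensembl, truth)``.
    """
    rng = np.random.default_rng(seed)
    cats = np.array(["clean"] * n_anchors, dtype=object)
    idx = rng.permutation(n_anchors)
    n_missing = int(frac_missing * n_anchors)
    n_multi = int(frac_multi * n_anchors)
    n_conflict = int(frac_conflict * n_anchors)
    n_shared = 2 * (int(frac_shared * n_anchors) // 2)
    pos = 0
    for cat, n in (("missing", n_missing), ("multi", n_multi), ("conflict", n_conflict), ("shared", n_shared)):
        cats[idx[pos : pos + n]] = cat
        pos += n

    anchors = [f"LG{i:05d}" for i in range(n_anchors)]
    ncbi_rows, ens_rows = [], []
    shared_partner: dict[int, str] = {}
    shared_ids = [i for i in range(n_anchors) if cats[i] == "shared"]
    for a, b in zip(shared_ids[::2], shared_ids[1::2]):
        target = f"HS{a:05d}"
        shared_partner[a] = target
        shared_partner[b] = target

    for i, anchor in enumerate(anchors):
        human, mouse = f"HS{i:05d}", f"MM{i:05d}"
        cat = cats[i]
        if cat == "missing":
            drop = "human" if rng.random() < 0.5 else "mouse"
            if drop != "human":
                ncbi_rows.append((anchor, "human", human))
                ens_rows.append((anchor, "human", human))
            if drop != "mouse":
                ncbi_rows.append((anchor, "mouse", mouse))
                ens_rows.append((anchor, "mouse", mouse))
            continue
        if cat == "shared":
            human = shared_partner[i]
        ncbi_rows.append((anchor, "human", human))
        ncbi_rows.append((anchor, "mouse", mouse))
        if cat == "multi":
            ncbi_rows.append((anchor, "human", f"HSX{i:05d}"))
        if cat == "conflict":
            ens_rows.append((anchor, "human", f"HSY{i:05d}"))
        else:
            ens_rows.append((anchor, "human", human))
        ens_rows.append((anchor, "mouse", mouse))

    ncbi = pd.DataFrame(ncbi_rows, columns=["anchor_gene_id", "species", "ortholog_gene_id"])
    ens = pd.DataFrame(ens_rows, columns=["ncbi_gene_id", "species", "ortholog_gene_id"])
    ens.insert(0, "ensembl_gene_id", ["ENSMIC" + a[2:] for a in ens["ncbi_gene_id"]])
    truth = pd.DataFrame({"anchor_gene_id": anchors, "planted": cats})
    return ncbi, ens, truth
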