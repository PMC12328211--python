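"""Cross-species conservation framework.

Cell-type similarity r_c is the Spearman correlation of two species'
pseudobulk profiles for one orthologous cell type, after clamping mean
expression below a floor (default 0.4) to the floor to mute background noise.
Gene-pattern similarity r_g is the Pearson correlation of a gene's
E_max-normalized cell-type pattern between two species; delta r_g =
r_gHL - r_gHM separates human-lemur-conserved/mouse-divergent (HL) genes from
human-mouse-conserved/lemur-divergent (HM) genes. Differences between
correlations are tested in Fisher-Z space (atanh), where they are
approximately normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

from crossatlas.containers import NormalizedMatrix
from crossatlas.exceptions import InputError
from crossatlas.io import log_stage
from crossatlas.stats import rank_sum_test

R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Fisher-Z inference
# ---------------------------------------------------------------------------


@dataclass
class StatTestResult:
    """Fisher-Z difference test between two correlation coefficients."""

    z1: float
    z2: float
    delta_z: float
    se: float
    statistic: float
    p: float
    tail: str
    delta_r: float  # tanh(delta_z), display value in [-1, 1]
    ci_low: float  # back-transformed 95% CI on delta_z
    ci_high: float


def _clip_r(r: float) -> float:
    if abs(r) >= 1.0:
        warnings.warn("correlation at the boundary clipped to +/-(1 - 1e-7)")
        return float(np.sign(r)) * R_CLIP
    return float(r)


def fisher_z_difference_test(
    r1: float, n1: int, r2: float, n2: int, tail: str = "right", reference: str = "normal"
) -> StatTestResult:
    """Test whether r1 differs from r2 after Fisher-Z transformation.

    z = atanh(r); SE = sqrt(1/(n1-3) + 1/(n2-3)); the statistic
    (z1 - z2)/SE is referred to a normal (default) or t distribution with
    df = n1 + n2 - 6. ``tail`` is 'right' (r1 > r2), 'left' or 'two'. The 95%
    CI on z1 - z2 is back-transformed through tanh for display.
    """
    if n1 <= 3 or n2 <= 3:
        raise InputError("Fisher-Z test needs n > 3 in both samples")
    z1, z2 = np.arctanh(_clip_r(r1)), np.arctanh(_clip_r(r2))
    dz = z1 - z2
    se = float(np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3)))
    stat = dz / se
    if reference == "normal":
        dist = ss.norm
        crit = ss.norm.ppf(0.975)
    elif reference == "t":
        df = n1 + n2 - 6
        dist = ss.t(df)
        crit = ss.t(df).ppf(0.975)
    else:
        raise InputError(f"unknown reference distribution {reference!r}")
    if tail == "right":
        p = float(dist.sf(stat))
    elif tail == "left":
        p = float(dist.cdf(stat))
    elif tail == "two":
        p = float(2.0 * dist.sf(abs(stat)))
    else:
        raise InputError(f"unknown tail {tail!r}")
    return StatTestResult(
        z1=float(z1),
        z2=float(z2),
        delta_z=float(dz),
        se=se,
        statistic=float(stat),
        p=p,
        tail=tail,
        delta_r=float(np.tanh(dz)),
        ci_low=float(np.tanh(dz - crit * se)),
        ci_high=float(np.tanh(dz + crit * se)),
    )


# ---------------------------------------------------------------------------
# cell-type similarity (r_c)
# ---------------------------------------------------------------------------


def _clamped_spearman(a: np.ndarray, b: np.ndarray, floor: float, mode: str):
    if mode == "clamp":
        a = np.maximum(a, floor)
        b = np.maximum(b, floor)
    elif mode == "drop":
        keep = (a >= floor) | (b >= floor)
        a, b = a[keep], b[keep]
    else:
        raise InputError(f"unknown floor mode {mode!r}")
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        # all-tied vectors: identical after clamping -> perfectly concordant
        return (1.0 if np.array_equal(a, b) else np.nan), len(a)
    rho = float(ss.spearmanr(a, b).statistic)
    return rho, len(a)


def celltype_similarity(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    floor: float = 0.4,
    floor_mode: str = "clamp",
    species_pair: str = "",
) -> pd.DataFrame:
    """Spearman r_c per shared cell type over the orthologous gene axis.

    Expression below ``floor`` is clamped to the floor (average ranks resolve
    the resulting ties), muting rank noise among background-level genes.
    95% CIs come from the Fisher-Z normal approximation with n = gene count.
    """
    genes = profiles_a.columns.intersection(profiles_b.columns)
    if len(genes) < 10:
        raise InputError("fewer than 10 shared orthologous genes")
    shared = profiles_a.index.intersection(profiles_b.index)
    records = []
    for ct in shared:
        a = profiles_a.loc[ct, genes].to_numpy(dtype=float)
        b = profiles_b.loc[ct, genes].to_numpy(dtype=float)
        rho, n = _clamped_spearman(a, b, floor, floor_mode)
        if np.isnan(rho) or n <= 3:
            records.append({"cell_type": ct, "species_pair": species_pair, "r_c": rho, "n_genes": n, "ci_low": np.nan, "ci_high": np.nan})
            continue
        z = np.arctanh(min(max(rho, -R_CLIP), R_CLIP))
        half = ss.norm.ppf(0.975) / np.sqrt(n - 3)
        records.append(
            {
                "cell_type": ct,
                "species_pair": species_pair,
                "r_c": rho,
                "n_genes": n,
                # the interval always contains the point estimate, also when
                # rho sits at the boundary and had to be clipped for atanh
                "ci_low": min(float(np.tanh(z - half)), rho),
                "ci_high": max(float(np.tanh(z + half)), rho),
            }
        )
    log_stage("celltype_similarity", n_types=len(records), floor=floor, mode=floor_mode)
    return pd.DataFrame.from_records(records)


def trajectory_similarity(
    positions: dict[str, np.ndarray],
    expression: dict[str, np.ndarray],
    gene_ids,
    window_frac: float = 0.1,
    step_frac: float = 0.02,
    floor: float = 0.4,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Moving-window r_c along species-aligned trajectories.

    ``positions[species]`` are normalized positions s in [0, 1] on a common
    axis (from the species-integrated embedding, supplied by the caller);
    ``expression[species]`` the matching cells x genes normalized matrices.
    Windows with fewer than ``min_cells`` cells in any species are omitted.
    ``window_frac = 1`` degenerates to the whole-trajectory similarity.
    """
    species = sorted(positions)
    if len(species) < 2:
        raise InputError("need >= 2 species")
    centers = (
        np.arange(window_frac / 2, 1 - window_frac / 2 + 1e-12, step_frac)
        if window_frac < 1
        else np.array([0.5])
    )
    records = []
    for c in centers:
        lo, hi = c - window_frac / 2, c + window_frac / 2
        prof = {}
        for sp_name in species:
            s = np.asarray(positions[sp_name])
            mask = (s >= lo) & (s <= hi)
            if mask.sum() < min_cells:
                prof = None
                break
            x = expression[sp_name]
            x = x[mask].toarray() if hasattr(x, "toarray") else np.asarray(x)[mask]
            prof[sp_name] = x.mean(axis=0)
        if prof is None:
            continue
        for i, s1 in enumerate(species):
            for s2 in species[i + 1 :]:
                rho, n = _clamped_spearman(prof[s1], prof[s2], floor, "clamp")
                records.append(
                    {
                        "center_s": float(c),
                        "window_frac": window_frac,
                        "species_pair": f"{s1}-{s2}",
                        "r_c": rho,
                        "n_genes": n,
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# gene-level conservation (E_max, r_g, delta r_g, classes)
# ---------------------------------------------------------------------------


def emax_filter(profiles: dict[str, pd.DataFrame], low: float = 0.1, mid: float = 0.5, high: float = 1.5):
    """Select the analysable gene universe from per-species pseudobulk.

    E_max is a gene's maximum cell-type mean expression within a species. A
    gene passes iff E_max > 0.5 in all species, or E_max > 0.1 in all species
    with E_max > 1.5 in at least one.
    """
    species = sorted(profiles)
    if len(species) < 3:
        raise InputError("emax_filter expects >= 3 species")
    axis = profiles[species[0]].index
    genes = profiles[species[0]].columns
    for sp_name in species[1:]:
        if not profiles[sp_name].index.equals(axis):
            raise InputError(f"species {sp_name} has a different cell-type axis")
        genes = genes.intersection(profiles[sp_name].columns)
    emax = pd.DataFrame(
        {sp_name: profiles[sp_name][genes].max(axis=0) for sp_name in species}
    )
    passed = (emax > mid).all(axis=1) | ((emax > low).all(axis=1) & (emax > high).any(axis=1))
    emax["passed_filter"] = passed
    log_stage("emax_filter", n_genes=len(genes), n_passed=int(passed.sum()))
    return genes[passed].tolist(), emax


def gene_pattern_correlations(
    profiles: dict[str, pd.DataFrame], genes, emax: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r_g per gene and species pair on E_max-normalized patterns."""
    species = sorted(profiles)
    norm = {}
    for sp_name in species:
        e = emax.loc[genes, sp_name].to_numpy(dtype=float)
        if (e <= 0).any():
            raise InputError("E_max must be positive for normalization")
        norm[sp_name] = profiles[sp_name][genes].to_numpy(dtype=float) / e  # types x genes
    out = {"gene": list(genes)}
    for i, s1 in enumerate(species):
        for s2 in species[i + 1 :]:
            a, b = norm[s1], norm[s2]
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (ac * bc).sum(axis=0) / denom
            r[denom == 0] = np.nan  # zero-variance pattern: r undefined
            out[f"r_{s1}_{s2}"] = r
    n_types = profiles[species[0]].shape[0]
    df = pd.DataFrame(out)
    df.attrs["n_cell_types"] = n_types
    return df


def classify_gene_conservation(
    r_hl,
    r_hm,
    r_lm,
    n_cell_types: int,
    delta_threshold: float = 0.4,
    p_threshold: float = 0.05,
    high: float = 0.8,
    low: float = 0.3,
) -> pd.DataFrame:
    """Assign selective tags (HL/HM/LM) and conservation tiers per gene.

    HL: delta r_g = r_gHL - r_gHM > 0.4 with right-tailed Fisher-Z p < 0.05;
    HM symmetric on the left tail; LM: r_gLM exceeds the larger of the
    human-involving correlations by > 0.4 with p < 0.05 (interpreting
    "lemur-mouse-conserved and human-divergent"). Thresholds are strict
    inequalities; a gene at delta r_g exactly 0.4 is untagged. The tier comes
    from the minimum of the three r_g values: > 0.8 highly, < 0.3 lowly,
    otherwise moderately conserved; any undefined r makes the gene
    unclassifiable.
    """
    r_hl = np.asarray(r_hl, dtype=float)
    r_hm = np.asarray(r_hm, dtype=float)
    r_lm = np.asarray(r_lm, dtype=float)
    n = len(r_hl)
    delta = r_hl - r_hm
    tags = np.full(n, "none", dtype=object)
    tiers = np.full(n, "moderately_conserved", dtype=object)
    p_right = np.full(n, np.nan)
    p_left = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(r_hl[i]) or np.isnan(r_hm[i]) or np.isnan(r_lm[i]):
            tiers[i] = "unclassifiable"
            continue
        test = fisher_z_difference_test(r_hl[i], n_cell_types, r_hm[i], n_cell_types, tail="right")
        p_right[i] = test.p
        p_left[i] = fisher_z_difference_test(
            r_hl[i], n_cell_types, r_hm[i], n_cell_types, tail="left"
        ).p
        if delta[i] > delta_threshold and p_right[i] < p_threshold:
            tags[i] = "HL"
        elif -delta[i] > delta_threshold and p_left[i] < p_threshold:
            tags[i] = "HM"
        else:
            r_best_h = max(r_hl[i], r_hm[i])
            if r_lm[i] - r_best_h > delta_threshold:
                lm_test = fisher_z_difference_test(
                    r_lm[i], n_cell_types, r_best_h, n_cell_types, tail="right"
                )
                if lm_test.p < p_threshold:
                    tags[i] = "LM"
        r_min = min(r_hl[i], r_hm[i], r_lm[i])
        if r_min > high:
            tiers[i] = "highly_conserved"
        elif r_min < low:
            tiers[i] = "lowly_conserved"
    out = pd.DataFrame(
        {
            "r_gHL": r_hl,
            "r_gHM": r_hm,
            "r_gLM": r_lm,
            "delta_r_g": delta,
            "p_right": p_right,
            "p_left": p_left,
            "tag": tags,
            "tier": tiers,
        }
    )
    log_stage(
        "classify_conservation",
        n_genes=n,
        n_hl=int((tags == "HL").sum()),
        n_hm=int((tags == "HM").sum()),
        n_lm=int((tags == "LM").sum()),
    )
    return out


# ---------------------------------------------------------------------------
# primate-selective genes
# ---------------------------------------------------------------------------


def primate_selective_genes(
    data: dict[str, tuple[NormalizedMatrix, pd.Series]],
    min_cells: int = 16,
    mean_floor: float = 0.5,
    fold_threshold: float = 5.0,
    p_threshold: float = 1e-5,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Call primate-enriched, primate-depleted and cell-type-enriched genes.

    Per orthologous cell type (with >15 cells in every species) and gene:
    primate_enriched requires mean > 0.5 in human AND lemur, and >= 5-fold
    greater de-logged expression than mouse with two-tailed Wilcoxon p < 1e-5
    in both primate-vs-mouse comparisons; primate_depleted is the mirror
    (mouse high, both primates >= 5-fold lower); celltype_enriched requires
    mean > 0.5 in all species and >= 5-fold enrichment with one-tailed
    p < 1e-5 versus all other cell types pooled across species. Fold changes
    are computed on de-logged means (expm1 scale) with a small pseudocount.
    """
    for sp_name in ("human", "lemur", "mouse"):
        if sp_name not in data:
            raise InputError(f"species {sp_name!r} missing from input")
    dense, labels = {}, {}
    gene_ids = None
    for sp_name, (nm, lab) in data.items():
        dense[sp_name] = nm.to_dense()
        labels[sp_name] = pd.Series(lab).reindex(nm.cell_ids).to_numpy()
        if pd.isna(labels[sp_name]).any():
            raise InputError(f"unlabeled cells in species {sp_name}")
        if gene_ids is None:
            gene_ids = nm.gene_ids
        elif not np.array_equal(gene_ids, nm.gene_ids):
            raise InputError("species matrices must share an orthologous gene axis")

    shared = sorted(
        set.intersection(*(set(labels[sp_name]) for sp_name in data))
    )
    calls = []
    skipped = []
    for ct in shared:
        blocks = {sp_name: dense[sp_name][labels[sp_name] == ct] for sp_name in data}
        if any(b.shape[0] < min_cells for b in blocks.values()):
            skipped.append(ct)
            continue
        means = {sp_name: b.mean(axis=0) for sp_name, b in blocks.items()}
        delog = {sp_name: np.expm1(m) + pseudocount for sp_name, m in means.items()}
        _, p_hm = rank_sum_test(blocks["human"], blocks["mouse"], "two-sided")
        _, p_lm = rank_sum_test(blocks["lemur"], blocks["mouse"], "two-sided")

        enr = (
            (means["human"] > mean_floor)
            & (means["lemur"] > mean_floor)
            & (delog["human"] / delog["mouse"] >= fold_threshold)
            & (delog["lemur"] / delog["mouse"] >= fold_threshold)
            & (p_hm < p_threshold)
            & (p_lm < p_threshold)
        )
        dep = (
            (means["mouse"] > mean_floor)
            & (delog["mouse"] / delog["human"] >= fold_threshold)
            & (delog["mouse"] / delog["lemur"] >= fold_threshold)
            & (p_hm < p_threshold)
            & (p_lm < p_threshold)
        )
        focal_all = np.vstack([blocks[sp_name] for sp_name in sorted(data)])
        rest_all = np.vstack(
            [dense[sp_name][labels[sp_name] != ct] for sp_name in sorted(data)]
        )
        _, p_ct = rank_sum_test(focal_all, rest_all, "greater")
        delog_focal = np.expm1(focal_all.mean(axis=0)) + pseudocount
        delog_rest = np.expm1(rest_all.mean(axis=0)) + pseudocount
        ct_enr = (
            np.all([means[sp_name] > mean_floor for sp_name in data], axis=0)
            & (delog_focal / delog_rest >= fold_threshold)
            & (p_ct < p_threshold)
        )
        for category, mask, pvals in (
            ("primate_enriched", enr, np.maximum(p_hm, p_lm)),
            ("primate_depleted", dep, np.maximum(p_hm, p_lm)),
            ("celltype_enriched", ct_enr, p_ct),
        ):
            for g in np.flatnonzero(mask):
                calls.append(
                    {
                        "cell_type": ct,
                        "gene": gene_ids[g],
                        "category": category,
                        "mean_human": float(means["human"][g]),
                        "mean_lemur": float(means["lemur"][g]),
                        "mean_mouse": float(means["mouse"][g]),
                        "p": float(pvals[g]),
                    }
                )
    log_stage(
        "primate_selective",
        n_types=len(shared),
        n_skipped=len(skipped),
        n_calls=len(calls),
    )
    cols = ["cell_type", "gene", "category", "mean_human", "mean_lemur", "mean_mouse", "p"]
    return pd.DataFrame(calls, columns=cols)


def conservation_summary(records: pd.DataFrame) -> dict:
    """Tier fractions, tag counts, and the paired r_gHL vs r_gHM comparison."""
    classified = records[records["tier"] != "unclassifiable"]
    n = len(classified)
    tiers = {
        t: float((classified["tier"] == t).sum()) / n if n else np.nan
        for t in ("highly_conserved", "moderately_conserved", "lowly_conserved")
    }
    tags = classified["tag"].value_counts().to_dict()
    diffs = classified["r_gHL"] - classified["r_gHM"]
    if n < 2 or float(diffs.abs().max()) == 0.0:
        paired_p = 1.0
    else:
        paired_p = float(ss.ttest_rel(classified["r_gHL"], classified["r_gHM"]).pvalue)
    return {"tier_fractions": tiers, "tag_counts": tags, "paired_p": paired_p, "n": n}
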