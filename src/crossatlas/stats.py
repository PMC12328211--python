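"""Shared statistical primitives: vectorized Wilcoxon rank-sum and BH-FDR.

The rank-sum test runs column-wise over gene matrices. For group sizes above
20 the normal approximation with tie and continuity corrections is used; for
smaller groups without ties the exact null distribution is evaluated through
scipy. This matches standard practice for scRNA-seq marker testing.
"""

from __future__ import annotations

import numpy as np
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

from crossatlas.exceptions import InputError

EXACT_MAX_N = 20


def _tie_term(combined: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tied groups, per column."""
    n, g = combined.shape
    out = np.zeros(g)
    cs = np.sort(combined, axis=0)
    has_ties = (cs[1:] == cs[:-1]).any(axis=0)
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(cs[:, j], return_counts=True)
        out[j] = np.sum(counts.astype(float) ** 3 - counts)
    return out


def rank_sum_test(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"):
    """Column-wise Wilcoxon rank-sum of ``a`` (n1 x G) vs ``b`` (n2 x G).

    ``alternative='greater'`` tests whether values in ``a`` are stochastically
    larger. Returns (u_statistic, p) arrays of length G.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[0], b.shape[0]
    if n1 == 0 or n2 == 0:
        raise InputError("rank_sum_test requires non-empty groups")
    if a.shape[1] != b.shape[1]:
        raise InputError("group matrices must share the gene axis")
    combined = np.vstack([a, b])
    ranks = ss.rankdata(combined, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if min(n1, n2) <= EXACT_MAX_N:
        tied = np.array(
            [len(np.unique(combined[:, j])) < n1 + n2 for j in range(combined.shape[1])]
        )
        if not tied.any():
            p = np.empty(a.shape[1])
            for j in range(a.shape[1]):
                res = ss.mannwhitneyu(a[:, j], b[:, j], alternative=alternative, method="exact")
                p[j] = res.pvalue
            return u1, p

    nn = n1 + n2
    mu = n1 * n2 / 2.0
    tie = _tie_term(combined)
    var = n1 * n2 / 12.0 * ((nn + 1) - tie / (nn * (nn - 1.0)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        if alternative == "two-sided":
            z = (np.abs(u1 - mu) - 0.5) / sigma
            p = 2.0 * ss.norm.sf(np.maximum(z, 0.0))
        elif alternative == "greater":
            z = (u1 - mu - 0.5) / sigma
            p = ss.norm.sf(z)
        elif alternative == "less":
            z = (u1 - mu + 0.5) / sigma
            p = ss.norm.cdf(z)
        else:
            raise InputError(f"unknown alternative {alternative!r}")
    # zero-variance columns (all values identical) carry no evidence
    p = np.where(sigma == 0, 1.0, p)
    return u1, np.clip(p, 0.0, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
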