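"""Density-ridge trajectory analysis.

The trajectory of a cell continuum is detected as the probability density
ridge of the cells in a 2D embedding: a kernel density estimate on a grid is
thresholded and morphologically skeletonized, spurious skeleton spurs are
pruned, nearby collinear ridge fragments are bridged, and the result becomes
an ordered polyline tree whose start end is anchored by marker-gene
expression. Cells are aligned to the trajectory by their shortest connecting
point (closest branch when the trajectory branches), positions are normalized
arc lengths along the root-to-tip path, and cells too distant from the ridge
are flagged as outliers by adaptive (sliding-window median + MAD)
thresholding along the trajectory.

Trajectory-dependent genes are scored by Spearman correlation against a bank
of preassigned unimodal templates (Gaussian bumps with peaks uniformly spaced
along the trajectory), Bonferroni-corrected over genes x templates; selected
genes are smoothed, peak-normalized, k-means clustered into major patterns,
and ranked by cluster peak position, then p-value, then mean expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as ss
from skimage.morphology import skeletonize
from sklearn.cluster import KMeans

from crossatlas.containers import NormalizedMatrix
from crossatlas.exceptions import DetectionError, InputError
from crossatlas.io import log_stage

# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    """One ordered polyline of the trajectory, oriented root -> tip."""

    id: int
    parent: int  # -1 for a component root
    points: np.ndarray  # (k, 2) embedding coordinates
    arc_offset: float = 0.0  # arc length from the component root to points[0]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise InputError("branch polyline needs >= 2 2D points")

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def cum_lengths(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.seg_lengths)])

    @property
    def length(self) -> float:
        return float(self.seg_lengths.sum())

    @property
    def root_to_tip(self) -> float:
        return self.arc_offset + self.length


@dataclass
class Trajectory:
    """Branch polylines plus their parent/child tree."""

    branches: list

    def __post_init__(self) -> None:
        ids = [b.id for b in self.branches]
        if ids != list(range(len(ids))):
            raise InputError("branch ids must be 0..n-1 in order")

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def children(self, bid: int) -> list:
        return [b.id for b in self.branches if b.parent == bid]

    def is_chain(self) -> bool:
        roots = [b for b in self.branches if b.parent == -1]
        return len(roots) == 1 and all(len(self.children(b.id)) <= 1 for b in self.branches)

    def chain_points(self) -> np.ndarray:
        """Concatenated polyline of an unbranched trajectory."""
        if not self.is_chain():
            raise InputError("trajectory is branched")
        pts = [self.branches[0].points]
        bid = self.branches[0].id
        while True:
            nxt = self.children(bid)
            if not nxt:
                break
            bid = nxt[0]
            pts.append(self.branches[bid].points[1:])
        return np.vstack(pts)


@dataclass
class TemplateBank:
    """Preassigned unimodal patterns over s in [0, 1].

    Gaussian bumps with peaks at (i - 0.5)/n uniformly covering the
    trajectory; the default width is 1/(2 n_templates) of the path.
    """

    n_templates: int = 20
    width: float = field(default=None)

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise InputError("need at least one template")
        if self.width is None:
            self.width = 1.0 / (2.0 * self.n_templates)
        if self.width <= 0:
            raise InputError("template width must be positive")

    @property
    def peaks(self) -> np.ndarray:
        return (np.arange(self.n_templates) + 0.5) / self.n_templates

    def values(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.exp(-((s[None, :] - self.peaks[:, None]) ** 2) / (2 * self.width**2))


# ---------------------------------------------------------------------------
# variable genes and embedding
# ---------------------------------------------------------------------------


def select_variable_genes(
    nm: NormalizedMatrix, dispersion_threshold: float = 0.5, n_bins: int = 20
) -> pd.DataFrame:
    """Highly variable genes by bin-standardized dispersion.

    Dispersion is log(variance/mean) of de-logged normalized expression,
    z-scored within 20 mean-expression bins so that the score measures excess
    variability at a given expression level. Genes with score above the
    threshold are marked ``selected``; constant genes never qualify.
    """
    if nm.n_cells < 50:
        raise InputError("variable-gene selection expects >= 50 cells")
    x = nm.values.copy()
    x.data = np.expm1(x.data)
    mu = np.asarray(x.mean(axis=0)).ravel()
    ex2 = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = np.maximum(ex2 - mu**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, np.nan)
        log_disp = np.log(np.where(disp > 0, disp, np.nan))
    df = pd.DataFrame({"gene": nm.gene_ids, "mean": mu, "dispersion_raw": disp, "log_disp": log_disp})
    df["score"] = -np.inf
    ok = df["log_disp"].notna() & (df["mean"] > 0)
    if ok.any():
        bins = pd.qcut(np.log1p(df.loc[ok, "mean"]), q=min(n_bins, ok.sum()), duplicates="drop")
        grouped = df.loc[ok].groupby(bins, observed=True)["log_disp"]
        center = grouped.transform("mean")
        spread = grouped.transform("std").fillna(0.0)
        z = (df.loc[ok, "log_disp"] - center) / spread.replace(0.0, 1.0)
        df.loc[ok, "score"] = z
    if not ok.any():
        warnings.warn("all genes constant; no variable genes")
    df["selected"] = df["score"] > dispersion_threshold
    return df.drop(columns="log_disp")


def embed_cells(
    nm: NormalizedMatrix,
    genes,
    max_pcs: int = 20,
    seed: int = 0,
    kurtosis_cutoff: float = 20.0,
    exclude_genes=None,
    n_top_loadings: int = 5,
):
    """PCA on standardized variable genes, PC quality screen, 2D embedding.

    PCs are flagged low-quality when the excess kurtosis of their scores
    exceeds ``kurtosis_cutoff`` (driven by extreme outlier cells) or when
    their top-loading genes intersect ``exclude_genes`` (immediate-early
    genes supplied by the caller). Surviving PC scores feed a neighbour
    embedding on Euclidean distances, deterministic given ``seed``.
    """
    genes = list(genes)
    if len(genes) < 10:
        raise InputError("embedding needs >= 10 genes")
    gene_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    idx = [gene_pos[g] for g in genes]
    x = nm.values[:, idx].toarray()
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    from sklearn.decomposition import PCA

    n_pc = min(max_pcs, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_pc, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    exclude = set(exclude_genes or [])
    report = []
    keep = []
    for k in range(n_pc):
        kurt = float(ss.kurtosis(scores[:, k]))
        top = np.argsort(-np.abs(pca.components_[k]))[:n_top_loadings]
        top_genes = [genes[i] for i in top]
        bad_kurt = kurt > kurtosis_cutoff
        bad_genes = bool(exclude.intersection(top_genes))
        if not (bad_kurt or bad_genes):
            keep.append(k)
        report.append(
            {
                "pc": k,
                "explained_variance_ratio": float(pca.explained_variance_ratio_[k]),
                "kurtosis": kurt,
                "top_genes": ",".join(top_genes),
                "kept": not (bad_kurt or bad_genes),
            }
        )
    if len(keep) < 3:
        raise InputError(f"only {len(keep)} high-quality PCs survive the screen")
    import umap

    coords = umap.UMAP(
        n_components=2, random_state=seed, metric="euclidean"
    ).fit_transform(scores[:, keep])
    return np.asarray(coords, dtype=float), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# ridge detection
# ---------------------------------------------------------------------------


def _kde_grid(xy: np.ndarray, grid_resolution: int, bandwidth_scale: float):
    """Histogram KDE with an isotropic Silverman-style bandwidth."""
    n = xy.shape[0]
    h = bandwidth_scale * float(xy.std(axis=0).mean()) * n ** (-1.0 / 6.0)
    if h <= 0:
        raise DetectionError("degenerate embedding (zero spread)")
    margin = 3.0 * h
    lo = xy.min(axis=0) - margin
    hi = xy.max(axis=0) + margin
    # square pixels: skeletonization operates on the pixel lattice, so the
    # grid must not distort aspect ratio (an elongated cloud would otherwise
    # become a fat band whose medial axis collapses)
    span = hi - lo
    pix = float(span.max()) / grid_resolution
    nx_bins = max(int(np.ceil(span[0] / pix)), 4)
    ny_bins = max(int(np.ceil(span[1] / pix)), 4)
    xe = lo[0] + np.arange(nx_bins + 1) * pix
    ye = lo[1] + np.arange(ny_bins + 1) * pix
    hist, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[xe, ye])
    px = (pix, pix)
    density = ndi.gaussian_filter(hist, sigma=(h / px[0], h / px[1]))
    centers = ((xe[:-1] + xe[1:]) / 2.0, (ye[:-1] + ye[1:]) / 2.0)
    return density, centers, px, h


def _pixel_graph(skel: np.ndarray, px) -> nx.Graph:
    g = nx.Graph()
    ii, jj = np.nonzero(skel)
    nodes = set(zip(ii.tolist(), jj.tolist()))
    for i, j in nodes:
        g.add_node((i, j))
    for i, j in nodes:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = (i + di, j + dj)
                if nb in nodes and not g.has_edge((i, j), nb):
                    w = float(np.hypot(di * px[0], dj * px[1]))
                    g.add_edge((i, j), nb, weight=w)
    return g


def _total_length(g: nx.Graph) -> float:
    return sum(d["weight"] for _, _, d in g.edges(data=True))


def _prune_spurs(g: nx.Graph, min_len: float) -> None:
    """Iteratively remove side branches shorter than ``min_len``."""
    changed = True
    while changed:
        changed = False
        for end in [n for n in g.nodes if g.degree(n) == 1]:
            if end not in g:
                continue
            path = [end]
            cur, prev = end, None
            length = 0.0
            while g.degree(cur) <= 2:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if not nbrs:
                    break
                prev, cur = cur, nbrs[0]
                length += g.edges[path[-1], cur]["weight"]
                path.append(cur)
            if g.degree(cur) >= 3 and length < min_len:
                g.remove_nodes_from(path[:-1])
                changed = True


def _node_xy(node, centers) -> np.ndarray:
    return np.array([centers[0][node[0]], centers[1][node[1]]])


def _end_tangent(g: nx.Graph, end, centers, steps: int = 5) -> np.ndarray:
    """Outward unit tangent at a degree-<=1 node."""
    cur, prev = end, None
    for _ in range(steps):
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs:
            break
        prev, cur = cur, nbrs[0]
    v = _node_xy(end, centers) - _node_xy(cur, centers)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else np.zeros(2)


def _bridge_gaps(g: nx.Graph, centers, gap_cap: float, min_cos: float = 0.7) -> None:
    """Connect endpoint pairs of separate fragments that continue the ridge."""
    comps = [frozenset(c) for c in nx.connected_components(g)]
    if len(comps) < 2:
        return
    comp_of = {}
    for k, c in enumerate(comps):
        for n in c:
            comp_of[n] = k
    ends = [n for n in g.nodes if g.degree(n) <= 1]
    candidates = []
    for i, a in enumerate(ends):
        for b in ends[i + 1 :]:
            if comp_of[a] == comp_of[b]:
                continue
            d = float(np.linalg.norm(_node_xy(a, centers) - _node_xy(b, centers)))
            if d >= gap_cap or d == 0:
                continue
            va = _end_tangent(g, a, centers)
            vb = _end_tangent(g, b, centers)
            u = (_node_xy(b, centers) - _node_xy(a, centers)) / d
            if float(va @ u) > min_cos and float(vb @ -u) > min_cos:
                candidates.append((d, a, b))
    merged = {k: k for k in range(len(comps))}

    def find(k):
        while merged[k] != k:
            k = merged[k]
        return k

    for d, a, b in sorted(candidates, key=lambda t: t[0]):
        ra, rb = find(comp_of[a]), find(comp_of[b])
        if ra == rb:
            continue
        g.add_edge(a, b, weight=d)
        merged[rb] = ra


def _decompose(g: nx.Graph, start, centers):
    """Walk the skeleton tree from ``start`` into ordered branches."""
    branches = []
    visited_edges = set()
    stack = [(start, -1, 0.0)]  # (node to start a branch at, parent branch, arc offset)
    while stack:
        origin, parent, offset = stack.pop(0)
        nbrs = sorted(n for n in g.neighbors(origin) if (origin, n) not in visited_edges)
        for nb in nbrs:
            if (origin, nb) in visited_edges:
                continue
            path = [origin, nb]
            visited_edges.add((origin, nb))
            visited_edges.add((nb, origin))
            cur, prev = nb, origin
            while g.degree(cur) == 2:
                nxt = [n for n in g.neighbors(cur) if n != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                visited_edges.add((prev, cur))
                visited_edges.add((cur, prev))
                path.append(cur)
            pts = np.array([_node_xy(p, centers) for p in path])
            bid = len(branches)
            branches.append(Branch(id=bid, parent=parent, points=pts, arc_offset=offset))
            length = branches[-1].length
            if g.degree(path[-1]) >= 3:
                stack.append((path[-1], bid, offset + length))
    return branches


def _cut_polyline_end(pts: np.ndarray, delta: float) -> np.ndarray:
    """Shorten a polyline by ``delta`` arc length from its far end (at most half)."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cut = max(cum[-1] - delta, cum[-1] / 2.0)
    k = int(np.searchsorted(cum, cut))
    if k >= len(pts) or k < 1:
        return pts
    frac = (cut - cum[k - 1]) / max(seg[k - 1], 1e-12)
    return np.vstack([pts[:k], pts[k - 1] + (pts[k] - pts[k - 1]) * frac])


def _retract_junctions(branches: list, delta: float) -> list:
    """Pull each detected junction back along its parent branch.

    Where two child bands merge, the smoothed density stays unimodal for
    roughly the kernel bandwidth past the true bifurcation, so the skeleton
    junction lands too far downstream; retracting the parent end compensates
    and lets near-junction cells fall to their nearest child instead.
    """
    has_child = {b.parent for b in branches if b.parent >= 0}
    out = []
    for b in branches:
        pts = _cut_polyline_end(b.points, delta) if b.id in has_child else b.points.copy()
        out.append(Branch(id=b.id, parent=b.parent, points=pts))
    for b in out:
        b.arc_offset = 0.0 if b.parent < 0 else out[b.parent].arc_offset + out[b.parent].length
    return out


def _extend_ends(branches: list, delta: float) -> list:
    """Prolong terminal polyline ends outward along their local tangent.

    Skeletonization of a thresholded density retracts the ridge from the true
    ends of the cell cloud by roughly the kernel bandwidth; extending each
    free end compensates, so that boundary cells project onto the extension
    instead of piling up in ties at s = 0 or 1.
    """
    has_child = {b.parent for b in branches}
    out = []
    for b in branches:
        pts = b.points.copy()
        if b.parent == -1:
            v = pts[0] - pts[min(5, len(pts) - 1)]
            norm = np.linalg.norm(v)
            if norm > 0:
                pts = np.vstack([pts[0] + v / norm * delta, pts])
        if b.id not in has_child:
            v = pts[-1] - pts[max(-6, -len(pts))]
            norm = np.linalg.norm(v)
            if norm > 0:
                pts = np.vstack([pts, pts[-1] + v / norm * delta])
        out.append(Branch(id=b.id, parent=b.parent, points=pts))
    for b in out:  # recompute arc offsets over the extended tree
        b.arc_offset = 0.0 if b.parent < 0 else out[b.parent].arc_offset + out[b.parent].length
    return out


def detect_density_ridge(
    embedding: np.ndarray,
    grid_resolution: int = 256,
    bandwidth_scale: float = 1.0,
    gap_cap: float | None = None,
    density_threshold: float = 0.1,
    anchor_expression=None,
    anchor_cells=None,
    spur_frac: float = 0.03,
    anchor_radius_frac: float = 0.05,
    end_extension: float = 1.5,
    junction_retract: float = 3.5,
) -> Trajectory:
    """Detect the cell-density ridge of a 2D embedding as a polyline tree.

    The start end is the skeleton endpoint whose neighbourhood cells maximize
    the mean of ``anchor_expression`` (per-cell marker scores), or the
    endpoint nearest the centroid of ``anchor_cells``. Disconnected ridge
    fragments closer than ``gap_cap`` (default 5% of the embedding diameter)
    and locally collinear are bridged; fragments further apart stay separate
    root branches.
    """
    xy = np.asarray(embedding, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InputError("embedding must be n x 2")
    if anchor_expression is None and anchor_cells is None:
        raise InputError("an anchor (marker expression or cells) is required")
    density, centers, px, h = _kde_grid(xy, grid_resolution, bandwidth_scale)
    mask = density >= density_threshold * density.max()
    if not mask.any():
        raise DetectionError("no density above threshold")
    skel = skeletonize(mask)
    if not skel.any():
        raise DetectionError("no ridge above density threshold")
    g = _pixel_graph(skel, px)
    g = nx.minimum_spanning_tree(g)  # break pixel-level cycles
    diameter = float(np.linalg.norm(xy.max(axis=0) - xy.min(axis=0)))
    if gap_cap is None:
        gap_cap = 0.05 * diameter
    _prune_spurs(g, spur_frac * _total_length(g))
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    if g.number_of_nodes() < 2:
        raise DetectionError("ridge collapsed after pruning")
    _bridge_gaps(g, centers, gap_cap)
    _prune_spurs(g, spur_frac * _total_length(g))
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])

    ends = sorted(n for n in g.nodes if g.degree(n) == 1)
    if not ends:
        raise DetectionError("ridge has no endpoints")
    if anchor_cells is not None:
        centroid = xy[np.asarray(anchor_cells)].mean(axis=0)
        scores = [-float(np.linalg.norm(_node_xy(e, centers) - centroid)) for e in ends]
    else:
        expr = np.asarray(anchor_expression, dtype=float)
        if expr.shape[0] != xy.shape[0]:
            raise InputError("anchor_expression must have one value per cell")
        radius = anchor_radius_frac * diameter
        scores = []
        for e in ends:
            d = np.linalg.norm(xy - _node_xy(e, centers), axis=1)
            near = d <= radius
            if near.sum() < 5:
                near = np.argsort(d)[:15]
            scores.append(float(expr[near].mean()))
    best = np.argsort(scores)[::-1]
    if len(ends) > 1 and scores[best[0]] == scores[best[1]]:
        raise DetectionError("ambiguous anchor: both candidate ends score equally")
    start = ends[best[0]]

    branches = _decompose(g, start, centers)
    # remaining components (not reachable from the anchored start)
    start_comp = nx.node_connected_component(g, start)
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        if comp == start_comp:
            continue
        sub_ends = sorted(n for n in comp if g.degree(n) == 1)
        if not sub_ends:
            continue
        sub = _decompose(g.subgraph(comp).copy(), sub_ends[0], centers)
        base = len(branches)
        for b in sub:
            branches.append(
                Branch(
                    id=base + b.id,
                    parent=b.parent if b.parent < 0 else base + b.parent,
                    points=b.points,
                    arc_offset=b.arc_offset,
                )
            )
    if junction_retract > 0:
        branches = _retract_junctions(branches, junction_retract * h)
    if end_extension > 0:
        branches = _extend_ends(branches, end_extension * h)
    log_stage(
        "detect_ridge",
        n_cells=xy.shape[0],
        grid=grid_resolution,
        n_branches=len(branches),
        gap_cap=round(gap_cap, 6),
    )
    return Trajectory(branches=branches)


def reverse_trajectory(traj: Trajectory) -> Trajectory:
    """Re-anchor an unbranched trajectory at its other end."""
    pts = traj.chain_points()
    return Trajectory(branches=[Branch(id=0, parent=-1, points=pts[::-1].copy())])


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _project_to_branch(xy: np.ndarray, branch: Branch):
    a = branch.points[:-1]
    d = np.diff(branch.points, axis=0)
    l2 = (d**2).sum(axis=1)
    l2 = np.where(l2 == 0, 1.0, l2)
    # (n, m) projection parameter per segment
    t = np.clip(((xy[:, None, :] - a[None, :, :]) * d[None, :, :]).sum(-1) / l2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(xy[:, None, :] - proj, axis=-1)
    seg = dist.argmin(axis=1)
    n_idx = np.arange(xy.shape[0])
    arc = branch.cum_lengths[seg] + t[n_idx, seg] * np.sqrt(l2[seg])
    return dist[n_idx, seg], arc


def align_cells_to_trajectory(
    embedding: np.ndarray,
    traj: Trajectory,
    outlier_k: float = 3.0,
    window: int | None = None,
    cell_ids=None,
) -> pd.DataFrame:
    """Align each cell to its nearest trajectory point.

    Position s is the normalized arc length along the branch's root-to-tip
    path; a cell equidistant to two branches goes to the lower branch id.
    Outliers are cells whose perpendicular distance exceeds the sliding-window
    median + ``outlier_k`` x scaled MAD of distances among cells ordered by
    position (window default: 10% of cells, at least 11).
    """
    xy = np.asarray(embedding, dtype=float)
    if traj.n_branches == 0:
        raise InputError("empty trajectory")
    n = xy.shape[0]
    best_d = np.full(n, np.inf)
    best_branch = np.zeros(n, dtype=int)
    best_arc = np.zeros(n)
    for b in traj.branches:  # ascending id: strict < keeps the lower id on ties
        d, arc = _project_to_branch(xy, b)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_branch[upd] = b.id
        best_arc[upd] = arc[upd]
    denom = np.array([traj.branches[b].root_to_tip for b in best_branch])
    offs = np.array([traj.branches[b].arc_offset for b in best_branch])
    s = np.clip((offs + best_arc) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)

    win = window or max(11, int(round(0.1 * n)))
    win = min(win if win % 2 else win + 1, n if n % 2 else n - 1)
    order = np.argsort(s, kind="stable")
    d_sorted = pd.Series(best_d[order])
    med = d_sorted.rolling(win, center=True, min_periods=1).median()
    mad = (d_sorted - med).abs().rolling(win, center=True, min_periods=1).median()
    thr = med + outlier_k * 1.4826 * mad
    outlier = np.zeros(n, dtype=bool)
    outlier[order] = (d_sorted > thr).to_numpy()

    return pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids, dtype=object) if cell_ids is not None else np.arange(n),
            "branch": best_branch,
            "s": s,
            "dist": best_d,
            "outlier": outlier,
        }
    )


# ---------------------------------------------------------------------------
# trajectory DEGs
# ---------------------------------------------------------------------------


def _spearman_vs_templates(x: np.ndarray, t: np.ndarray):
    """Spearman rho and two-sided p of each gene column vs each template row."""
    n = x.shape[0]
    rx = ss.rankdata(x, axis=0)
    rt = ss.rankdata(t, axis=1)
    sx = rx.std(axis=0)
    st = rt.std(axis=1)
    zx = (rx - rx.mean(axis=0)) / np.where(sx == 0, 1.0, sx)
    zt = (rt - rt.mean(axis=1, keepdims=True)) / np.where(st == 0, 1.0, st)[:, None]
    rho = (zt @ zx) / n  # (K, G)
    rho[:, sx == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * ss.t(n - 2).sf(np.abs(tstat))
    p[np.isnan(rho)] = np.nan
    p[np.abs(rho) >= 1.0] = 0.0
    return rho, p


def trajectory_degs(
    nm: NormalizedMatrix,
    alignment: pd.DataFrame,
    templates: TemplateBank | None = None,
    k_clusters: int = 10,
    seed: int = 0,
    top_n: int = 1000,
    p_threshold: float = 0.01,
    dispersion_threshold: float = 0.5,
    dispersions: pd.DataFrame | None = None,
    min_cells: int = 100,
    smooth_frac: float = 0.05,
) -> pd.DataFrame:
    """Detect, cluster and rank genes whose expression follows the trajectory.

    Per gene, Spearman correlation against every template evaluated at cell
    positions; Bonferroni correction over genes x templates; selection =
    (top ``top_n`` by p) with p < 0.01 and dispersion > 0.5. Selected genes
    are smoothed along s (moving average, window 5% of cells, min 11),
    peak-normalized and k-means clustered (fixed seed, 25 restarts); clusters
    are ordered by mean peak position, genes within a cluster by p then mean
    expression.
    """
    templates = templates or TemplateBank()
    aligned = alignment[~alignment["outlier"].astype(bool)]
    if len(aligned) < min_cells:
        raise InputError(f"need >= {min_cells} aligned cells, have {len(aligned)}")
    pos = {c: i for i, c in enumerate(nm.cell_ids)}
    rows = [pos[c] for c in aligned["cell_id"]] if aligned["cell_id"].dtype == object else aligned[
        "cell_id"
    ].to_numpy(dtype=int)
    s = aligned["s"].to_numpy(dtype=float)
    x = nm.values[np.asarray(rows)].toarray()
    n = x.shape[0]

    t_vals = templates.values(s)
    rho, p = _spearman_vs_templates(x, t_vals)
    tested = ~np.isnan(p).all(axis=0)
    n_tests = int(tested.sum()) * templates.n_templates
    best = np.argmin(np.where(np.isnan(p), np.inf, p), axis=0)
    g_idx = np.arange(x.shape[1])
    p_best = p[best, g_idx]
    rho_best = rho[best, g_idx]
    p_adj = np.clip(p_best * n_tests, 0.0, 1.0)

    if dispersions is None:
        sub = NormalizedMatrix(nm.values[np.asarray(rows)], nm.cell_ids[np.asarray(rows)], nm.gene_ids)
        dispersions = select_variable_genes(sub, dispersion_threshold)
    disp = dispersions.set_index("gene")["score"].reindex(nm.gene_ids).to_numpy(dtype=float)

    ok = tested & ~np.isnan(p_adj) & (p_adj < p_threshold) & (disp > dispersion_threshold)
    if ok.sum() > top_n:
        cutoff = np.sort(p_best[ok])[top_n - 1]
        ok &= p_best <= cutoff
    sel = np.flatnonzero(ok)
    if sel.size == 0:
        warnings.warn("no genes pass the trajectory-DEG selection")
        return pd.DataFrame(
            columns=["gene", "best_template", "rho", "p_adj", "cluster", "peak_s", "mean_expr", "rank"]
        )
    # cluster in gene-id order so the output is invariant to input gene order
    sel = sel[np.argsort(nm.gene_ids[sel])]

    order = np.argsort(s, kind="stable")
    win = max(11, int(round(smooth_frac * n)))
    kernel = np.ones(win) / win
    smoothed = np.empty((sel.size, n))
    for k, g in enumerate(sel):
        prof = x[order, g]
        pad = np.pad(prof, (win // 2, win - 1 - win // 2), mode="edge")
        smoothed[k] = np.convolve(pad, kernel, mode="valid")
    maxima = smoothed.max(axis=1)
    normed = smoothed / np.where(maxima == 0, 1.0, maxima)[:, None]
    s_sorted = s[order]
    peak_s = s_sorted[smoothed.argmax(axis=1)]

    k_eff = min(k_clusters, sel.size)
    km = KMeans(n_clusters=k_eff, n_init=25, random_state=seed)
    labels = km.fit_predict(normed)
    cluster_peak = pd.Series(peak_s).groupby(labels).mean()
    relabel = {old: new for new, old in enumerate(cluster_peak.sort_values().index)}
    cluster = np.array([relabel[v] for v in labels])

    out = pd.DataFrame(
        {
            "gene": nm.gene_ids[sel],
            "best_template": best[sel],
            "rho": rho_best[sel],
            "p_adj": p_adj[sel],
            "cluster": cluster,
            "peak_s": peak_s,
            "mean_expr": x[:, sel].mean(axis=0),
        }
    )
    out = out.sort_values(
        ["cluster", "p_adj", "mean_expr", "gene"], ascending=[True, True, False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    log_stage("trajectory_degs", n_cells=n, n_selected=len(out), k=k_eff)
    return out
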