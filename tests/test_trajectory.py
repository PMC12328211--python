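"""Ridge detection, cell alignment, variable genes, template DEGs."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as ss
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import directed_hausdorff

from crossatlas.containers import NormalizedMatrix
from crossatlas.exceptions import DetectionError, InputError
from crossatlas.qc import normalize_up10k
from crossatlas.simulate import TrajectorySimSpec, simulate_trajectory
from crossatlas.trajectory import (
    Branch,
    TemplateBank,
    Trajectory,
    align_cells_to_trajectory,
    detect_density_ridge,
    embed_cells,
    reverse_trajectory,
    select_variable_genes,
    trajectory_degs,
)


def _linear_case(seed=3, n=400):
    cm, truth = simulate_trajectory(TrajectorySimSpec(n_cells=n), seed)
    nm = normalize_up10k(cm)
    xy = truth["cells"][["x", "y"]].to_numpy()
    anchor = nm.to_dense()[:, 0]  # first program gene peaks near s = 0
    return cm, nm, truth, xy, anchor


class TestTemplates:
    def test_peaks_uniform_and_unimodal(self):
        bank = TemplateBank(20)
        assert np.allclose(np.diff(bank.peaks), 1 / 20)
        s = np.linspace(0, 1, 101)
        vals = bank.values(s)
        for row in vals:
            peak = row.argmax()
            assert (np.diff(row[: peak + 1]) >= 0).all()
            assert (np.diff(row[peak:]) <= 0).all()

    def test_invalid_bank(self):
        with pytest.raises(InputError):
            TemplateBank(0)
        with pytest.raises(InputError):
            TemplateBank(5, width=-1)


class TestVariableGenes:
    def test_constant_gene_excluded_and_planted_variance_scores_higher(self, rng):
        n = 200
        poisson_like = rng.poisson(5, n)
        bimodal = np.where(rng.random(n) < 0.5, 0, 10)  # same mean, larger variance
        constant = np.full(n, 3)
        filler = rng.poisson(rng.uniform(1, 9, 60), (n, 60))  # populate the mean bins
        values = np.log1p(
            np.column_stack([poisson_like, bimodal, constant, filler]).astype(float)
        )
        names = ["pois", "bimo", "const"] + [f"f{i}" for i in range(60)]
        nm = NormalizedMatrix(sp.csr_matrix(values), [f"c{i}" for i in range(n)], names)
        df = select_variable_genes(nm).set_index("gene")
        assert df.loc["bimo", "score"] > df.loc["pois", "score"]
        assert not df.loc["const", "selected"]

    def test_infinite_threshold_selects_nothing(self, atlas_norm):
        nm, _, _ = atlas_norm
        df = select_variable_genes(nm, dispersion_threshold=np.inf)
        assert not df["selected"].any()


class TestEmbedCells:
    def test_rank2_structure_flags_and_determinism(self, rng):
        n, g = 150, 30
        latent = rng.normal(size=(n, 2))
        w = rng.normal(size=(2, g))
        x = latent @ w + 1e-3 * rng.normal(size=(n, g))
        x = x - x.min()  # normalized values must be non-negative
        nm = NormalizedMatrix(sp.csr_matrix(x), [f"c{i}" for i in range(n)], [f"g{i}" for i in range(g)])
        coords, report = embed_cells(nm, nm.gene_ids, seed=0)
        assert report["explained_variance_ratio"].iloc[:2].sum() > 0.99
        coords2, _ = embed_cells(nm, nm.gene_ids, seed=0)
        assert np.array_equal(coords, coords2)

    def test_outlier_dominated_pc_flagged_by_kurtosis(self, rng):
        n, g = 120, 25
        x = rng.normal(size=(n, g))
        x[0, :5] += 50.0  # one extreme cell dominating a component
        x = x - x.min()
        nm = NormalizedMatrix(sp.csr_matrix(x), [f"c{i}" for i in range(n)], [f"g{i}" for i in range(g)])
        _, report = embed_cells(nm, nm.gene_ids, seed=0, max_pcs=10)
        assert not report["kept"].all()
        flagged = report.loc[~report["kept"], "kurtosis"]
        assert (flagged > 20).any()

    def test_excluded_gene_loadings_flag_pcs(self, rng):
        n, g = 120, 20
        x = rng.normal(size=(n, g))
        factor = rng.normal(size=n)  # genes 0/1 carry the dominant factor
        x[:, 0] = factor + 0.1 * rng.normal(size=n)
        x[:, 1] = factor + 0.1 * rng.normal(size=n)
        x = x - x.min()
        nm = NormalizedMatrix(sp.csr_matrix(x), [f"c{i}" for i in range(n)], [f"g{i}" for i in range(g)])
        _, report = embed_cells(nm, nm.gene_ids, seed=0, max_pcs=8, exclude_genes=["g0"])
        first = report.iloc[0]
        assert "g0" in first["top_genes"] and not first["kept"]


class TestRidgeDetection:
    def test_straight_segment_recovered_within_noise(self):
        _, _, truth, xy, anchor = _linear_case(seed=4, n=1000)
        traj = detect_density_ridge(xy, anchor_expression=anchor)
        noise_abs = 0.05  # generator: 5% of unit length
        detected = np.vstack([b.points for b in traj.branches])
        line = np.column_stack([np.linspace(0, 1, 200), np.zeros(200)])
        h = max(
            directed_hausdorff(detected, line)[0], directed_hausdorff(line, detected)[0]
        )
        assert h < 2 * noise_abs

    def test_two_distant_blobs_stay_separate(self, rng):
        a = rng.normal(scale=0.05, size=(400, 2)) + np.array([0, 0])
        a[:, 0] = rng.uniform(0, 1, 400)
        b = a.copy() + np.array([0, 5.0])  # far beyond any gap cap
        xy = np.vstack([a, b])
        anchor = np.concatenate([1.0 - a[:, 0], np.zeros(400)])  # gradient along blob a
        traj = detect_density_ridge(xy, anchor_expression=anchor)
        roots = [br for br in traj.branches if br.parent == -1]
        assert len(roots) >= 2

    def test_y_tree_topology(self):
        spec = TrajectorySimSpec(branches=((-1, 1.0), (0, 1.0), (0, 1.0)), n_cells=600)
        cm, truth = simulate_trajectory(spec, 6)
        nm = normalize_up10k(cm)
        xy = truth["cells"][["x", "y"]].to_numpy()
        traj = detect_density_ridge(xy, anchor_expression=nm.to_dense()[:, 0])
        assert traj.n_branches == 3
        assert sorted(b.parent for b in traj.branches) == [-1, 0, 0]

    def test_missing_anchor_rejected(self, rng):
        xy = rng.normal(size=(300, 2))
        with pytest.raises(InputError):
            detect_density_ridge(xy)

    def test_no_density_above_threshold(self, rng):
        xy = rng.normal(size=(250, 2))
        with pytest.raises(DetectionError):
            detect_density_ridge(xy, density_threshold=2.0, anchor_expression=np.ones(250))


class TestAlignment:
    def _segment(self):
        return Trajectory([Branch(0, -1, np.array([[0.0, 0.0], [1.0, 0.0]]))])

    def test_cell_on_polyline_never_outlier(self, rng):
        traj = self._segment()
        xy = np.column_stack([rng.uniform(0, 1, 50), np.zeros(50)])
        al = align_cells_to_trajectory(xy, traj)
        assert np.allclose(al["dist"], 0) and not al["outlier"].any()
        assert np.allclose(al["s"], xy[:, 0])

    def test_equidistant_cell_goes_to_lower_branch_id(self):
        traj = Trajectory(
            [
                Branch(0, -1, np.array([[0.0, 0.0], [1.0, 0.0]])),
                Branch(1, -1, np.array([[0.0, 1.0], [1.0, 1.0]])),
            ]
        )
        al = align_cells_to_trajectory(np.array([[0.5, 0.5]]), traj)
        assert al["branch"].iloc[0] == 0

    def test_linear_recovery_and_outliers(self):
        _, _, truth, xy, anchor = _linear_case()
        traj = detect_density_ridge(xy, anchor_expression=anchor)
        al = align_cells_to_trajectory(xy, traj)
        keep = ~al["outlier"]
        rho = ss.spearmanr(al.loc[keep, "s"], truth["cells"].loc[keep.to_numpy(), "s"]).statistic
        assert abs(rho) > 0.95

    def test_anchor_reversal_maps_s_to_one_minus_s(self):
        _, _, _, xy, anchor = _linear_case()
        traj = detect_density_ridge(xy, anchor_expression=anchor)
        fwd = align_cells_to_trajectory(xy, traj)
        rev = align_cells_to_trajectory(xy, reverse_trajectory(traj))
        assert np.allclose(fwd["s"] + rev["s"], 1.0, atol=1e-9)

    def test_rigid_rotation_invariance_of_positions(self):
        _, _, _, xy, anchor = _linear_case()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = xy @ rot.T + np.array([3.0, -2.0])
        s1 = align_cells_to_trajectory(xy, detect_density_ridge(xy, anchor_expression=anchor))["s"]
        s2 = align_cells_to_trajectory(xy2, detect_density_ridge(xy2, anchor_expression=anchor))["s"]
        assert ss.spearmanr(s1, s2).statistic > 0.99
        assert np.mean(np.abs(s1 - s2)) < 0.05


class TestTrajectoryDegs:
    def _alignment(self, nm, s):
        return pd.DataFrame(
            {"cell_id": nm.cell_ids, "branch": 0, "s": s, "dist": 0.0, "outlier": False}
        )

    def test_gene_equal_to_template_identified(self, rng):
        n = 200
        s = rng.uniform(0, 1, n)
        bank = TemplateBank(20)
        vals = bank.values(s)
        x = np.column_stack([vals[7], rng.uniform(0, 1, n)])
        nm = NormalizedMatrix(sp.csr_matrix(x), [f"c{i}" for i in range(n)], ["match", "noise"])
        disp = pd.DataFrame({"gene": ["match", "noise"], "score": [5.0, 5.0]})
        out = trajectory_degs(
            nm, self._alignment(nm, s), templates=bank, dispersions=disp, k_clusters=2
        )
        row = out.set_index("gene").loc["match"]
        assert row["best_template"] == 7
        assert row["rho"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_gene_excluded(self, rng):
        n = 150
        s = rng.uniform(0, 1, n)
        x = np.column_stack([np.full(n, 2.0), TemplateBank(20).values(s)[3]])
        nm = NormalizedMatrix(sp.csr_matrix(x), [f"c{i}" for i in range(n)], ["const", "prog"])
        disp = pd.DataFrame({"gene": ["const", "prog"], "score": [5.0, 5.0]})
        out = trajectory_degs(nm, self._alignment(nm, s), dispersions=disp, k_clusters=1)
        assert "const" not in set(out["gene"])

    def test_program_recovery_and_cluster_ordering(self):
        cm, truth = simulate_trajectory(TrajectorySimSpec(n_cells=400), 42)
        nm = normalize_up10k(cm)
        al = self._alignment(nm, truth["cells"]["s"].to_numpy())
        out = trajectory_degs(nm, al, seed=0)
        prog = truth["programs"].set_index("gene")
        recovered = set(out["gene"]) & set(prog.index)
        assert len(recovered) / len(prog) >= 0.9
        merged = out[out["gene"].isin(prog.index)].copy()
        merged["true_peak"] = prog.loc[merged["gene"], "peak"].to_numpy()
        tau = ss.kendalltau(merged["cluster"], merged["true_peak"]).statistic
        assert tau > 0.8
        assert merged.groupby("cluster").size().gt(0).all()
        assert (out["rank"].to_numpy() == np.arange(1, len(out) + 1)).all()

    def test_gene_order_permutation_invariance(self, rng):
        cm, truth = simulate_trajectory(
            TrajectorySimSpec(n_cells=200, n_program_genes=10, n_noise_genes=40), 11
        )
        nm = normalize_up10k(cm)
        al = self._alignment(nm, truth["cells"]["s"].to_numpy())
        base = trajectory_degs(nm, al, seed=1, min_cells=50)
        perm = rng.permutation(nm.n_genes)
        nm2 = NormalizedMatrix(nm.values[:, perm], nm.cell_ids, nm.gene_ids[perm])
        out = trajectory_degs(nm2, al, seed=1, min_cells=50)
        pd.testing.assert_frame_equal(base, out)
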