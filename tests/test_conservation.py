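"""r_c / r_g conservation scores, Fisher-Z inference, primate-selective calls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st

from crossatlas.containers import NormalizedMatrix
from crossatlas.conservation import (
    celltype_similarity,
    classify_gene_conservation,
    conservation_summary,
    emax_filter,
    fisher_z_difference_test,
    gene_pattern_correlations,
    primate_selective_genes,
    trajectory_similarity,
)
from crossatlas.exceptions import InputError


def _prof(arr, types=None, genes=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=types or [f"t{i}" for i in range(arr.shape[0])],
        columns=genes or [f"g{j}" for j in range(arr.shape[1])],
    )


class TestCelltypeSimilarity:
    def test_identical_profiles(self, rng):
        p = _prof(rng.random((3, 50)) * 3)
        out = celltype_similarity(p, p.copy())
        assert np.allclose(out["r_c"], 1.0)
        assert ((out["ci_low"] <= out["r_c"]) & (out["r_c"] <= out["ci_high"])).all()

    def test_subfloor_differences_are_invisible(self, rng):
        a = _prof(np.tile(rng.uniform(0.5, 3.0, 50), (2, 1)))
        b = a.copy()
        low = rng.random(50) < 0.4
        b.iloc[:, np.flatnonzero(low)] = rng.uniform(0, 0.39, (2, low.sum()))
        a.iloc[:, np.flatnonzero(low)] = rng.uniform(0, 0.39, (2, low.sum()))
        out = celltype_similarity(a, b, floor=0.4)
        assert np.allclose(out["r_c"], 1.0)

    def test_matches_bruteforce_clamped_spearman(self, rng):
        a = _prof(rng.exponential(1.0, (1, 500)), types=["t0"])
        b = _prof(rng.exponential(1.0, (1, 500)), types=["t0"])
        out = celltype_similarity(a, b, floor=0.4)
        expected = ss.spearmanr(
            np.maximum(a.to_numpy()[0], 0.4), np.maximum(b.to_numpy()[0], 0.4)
        ).statistic
        assert out["r_c"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputError):
            celltype_similarity(_prof(np.ones((2, 5))), _prof(np.ones((2, 5))))


class TestTrajectorySimilarity:
    def test_identical_species_give_unit_similarity(self, rng):
        n = 300
        s = rng.uniform(0, 1, n)
        expr = np.maximum(rng.normal(1.5, 0.5, (n, 40)), 0)
        out = trajectory_similarity({"a": s, "b": s.copy()}, {"a": expr, "b": expr.copy()}, None)
        assert len(out) and np.allclose(out["r_c"], 1.0)

    def test_full_window_degenerates_to_whole_trajectory(self, rng):
        n = 200
        s = rng.uniform(0, 1, n)
        ea, eb = rng.random((n, 30)) * 2, rng.random((n, 30)) * 2
        out = trajectory_similarity({"a": s, "b": s}, {"a": ea, "b": eb}, None, window_frac=1.0)
        assert len(out) == 1
        expected = ss.spearmanr(
            np.maximum(ea.mean(axis=0), 0.4), np.maximum(eb.mean(axis=0), 0.4)
        ).statistic
        assert out["r_c"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_planted_late_divergence_lowers_late_windows(self, rng):
        n = 600
        s = np.sort(rng.uniform(0, 1, n))
        base = rng.uniform(0.5, 3.0, 50)
        ea = np.tile(base, (n, 1)) + rng.normal(0, 0.05, (n, 50))
        eb = ea + rng.normal(0, 0.05, (n, 50))
        late = s > 0.7
        eb[late] = rng.uniform(0.5, 3.0, (late.sum(), 50))  # divergent programs late
        out = trajectory_similarity({"a": s, "b": s}, {"a": np.abs(ea), "b": np.abs(eb)}, None)
        early = out[out["center_s"] < 0.6]["r_c"].mean()
        latew = out[out["center_s"] > 0.8]["r_c"].mean()
        assert early > latew + 0.2


class TestEmaxFilter:
    @pytest.mark.parametrize(
        "emax,expected",
        [((0.6, 0.7, 0.55), True), ((0.2, 0.3, 1.6), True), ((2.0, 0.05, 0.4), False)],
    )
    def test_rule(self, emax, expected):
        profs = {
            sp_name: _prof(np.array([[v], [v / 2]]), genes=["g"])
            for sp_name, v in zip(("human", "lemur", "mouse"), emax)
        }
        genes, table = emax_filter(profs)
        assert (len(genes) == 1) is expected
        assert table["passed_filter"].iloc[0] is np.bool_(expected)


class TestGenePatternCorrelations:
    def _three(self, rng, n_types=10, n_genes=5):
        return {
            sp_name: _prof(rng.uniform(0.2, 3.0, (n_types, n_genes)))
            for sp_name in ("human", "lemur", "mouse")
        }

    def test_identical_patterns_and_bruteforce_reversal(self, rng):
        profs = self._three(rng)
        profs["lemur"] = profs["human"].copy()
        profs["mouse"] = profs["human"].iloc[::-1].set_axis(profs["human"].index)
        genes, emax = emax_filter(profs)
        out = gene_pattern_correlations(profs, genes, emax)
        assert np.allclose(out["r_human_lemur"], 1.0)
        for _, row in out.iterrows():
            h = profs["human"][row["gene"]] / emax.loc[row["gene"], "human"]
            m = profs["mouse"][row["gene"]] / emax.loc[row["gene"], "mouse"]
            assert row["r_human_mouse"] == pytest.approx(np.corrcoef(h, m)[0, 1], abs=1e-10)

    def test_scale_invariance(self, rng):
        profs = self._three(rng)
        genes, emax = emax_filter(profs)
        base = gene_pattern_correlations(profs, genes, emax)
        profs2 = dict(profs)
        profs2["lemur"] = profs["lemur"] * 3.0
        genes2, emax2 = emax_filter(profs2)
        out = gene_pattern_correlations(profs2, genes2, emax2)
        for col in ("r_human_lemur", "r_human_mouse", "r_lemur_mouse"):
            assert np.allclose(base[col], out[col], atol=1e-12)

    def test_zero_variance_pattern_flagged(self):
        profs = {
            sp_name: _prof(np.ones((4, 1)) * 2.0, genes=["g"]) for sp_name in ("human", "lemur", "mouse")
        }
        genes, emax = emax_filter(profs)
        out = gene_pattern_correlations(profs, genes, emax)
        assert out["r_human_lemur"].isna().all()


class TestFisherZ:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-0.999999, 0.999999))
    def test_tanh_atanh_roundtrip(self, r):
        assert np.tanh(np.arctanh(r)) == pytest.approx(r, abs=1e-12)

    def test_equal_correlations_give_half(self):
        assert fisher_z_difference_test(0.5, 63, 0.5, 63).p == pytest.approx(0.5)

    def test_left_and_right_tails_sum_to_one(self):
        right = fisher_z_difference_test(0.7, 40, 0.3, 50, tail="right").p
        left = fisher_z_difference_test(0.7, 40, 0.3, 50, tail="left").p
        assert right + left == pytest.approx(1.0, abs=1e-12)

    def test_against_monte_carlo_null(self, rng):
        r1, r2, n = 0.6, 0.3, 40
        res = fisher_z_difference_test(r1, n, r2, n)
        pooled = np.tanh((np.arctanh(r1) + np.arctanh(r2)) / 2)
        draws = 200_000
        obs = np.arctanh(r1) - np.arctanh(r2)

        def sample_r():
            x = rng.standard_normal((draws, n))
            y = pooled * x + np.sqrt(1 - pooled**2) * rng.standard_normal((draws, n))
            xc = x - x.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            return (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))

        dz = np.arctanh(sample_r()) - np.arctanh(sample_r())
        p_mc = (dz >= obs).mean()
        se = np.sqrt(max(p_mc, res.p) * (1 - min(p_mc, res.p)) / draws)
        assert abs(p_mc - res.p) <= 3 * se + 1e-12

    def test_boundary_and_small_n(self):
        with pytest.raises(InputError):
            fisher_z_difference_test(0.5, 3, 0.1, 63)
        with pytest.warns(UserWarning):
            res = fisher_z_difference_test(1.0, 20, 0.5, 20)
        assert np.isfinite(res.p)

    def test_t_reference_close_to_normal_at_n63(self):
        a = fisher_z_difference_test(0.6, 63, 0.4, 63, reference="normal").p
        b = fisher_z_difference_test(0.6, 63, 0.4, 63, reference="t").p
        assert a == pytest.approx(b, rel=0.05)


class TestClassification:
    def _classify(self, hl, hm, lm):
        return classify_gene_conservation([hl], [hm], [lm], n_cell_types=63).iloc[0]

    def test_uniformly_high_is_highly_conserved_untagged(self):
        row = self._classify(0.9, 0.9, 0.9)
        assert row["tier"] == "highly_conserved" and row["tag"] == "none"

    def test_hl_gene_tagged_via_fisher_test(self):
        row = self._classify(0.85, 0.2, 0.25)
        assert row["tag"] == "HL" and row["p_right"] < 0.05

    def test_small_delta_untagged(self):
        assert self._classify(0.5, 0.45, 0.4)["tag"] == "none"

    def test_boundary_delta_exactly_threshold_untagged(self):
        row = self._classify(0.8, 0.4, 0.1)
        assert row["delta_r_g"] == pytest.approx(0.4)
        assert row["tag"] == "none"  # strict inequality

    def test_hm_and_lm_tags(self):
        assert self._classify(0.2, 0.85, 0.2)["tag"] == "HM"
        assert self._classify(0.15, 0.2, 0.9)["tag"] == "LM"

    def test_undefined_r_unclassifiable(self):
        row = self._classify(np.nan, 0.5, 0.5)
        assert row["tier"] == "unclassifiable" and row["tag"] == "none"

    def test_summary_limits(self):
        rec = classify_gene_conservation([0.9] * 5, [0.9] * 5, [0.9] * 5, n_cell_types=63)
        out = conservation_summary(rec)
        assert out["tier_fractions"]["highly_conserved"] == 1.0
        assert out["paired_p"] == pytest.approx(1.0)


class TestPrimateSelective:
    def _nm(self, values):
        values = np.asarray(values, dtype=float)
        return NormalizedMatrix(
            sp.csr_matrix(values),
            [f"c{i}" for i in range(values.shape[0])],
            [f"g{j}" for j in range(values.shape[1])],
        )

    def _species_data(self, rng, focal_means, n_types=4, cells=20, base=0.1):
        data = {}
        for sp_name, mu in focal_means.items():
            blocks, labels = [], []
            for t in range(n_types):
                m = mu if t == 0 else base
                blocks.append(np.maximum(rng.normal(m, 0.25, (cells, 1)), 0))
                labels.extend([f"ct{t}"] * cells)
            vals = np.vstack(blocks)
            nm = self._nm(vals)
            data[sp_name] = (nm, pd.Series(labels, index=nm.cell_ids))
        return data

    def test_constant_gene_yields_no_calls(self):
        vals = np.full((40, 1), 1.0)
        data = {
            sp_name: (
                self._nm(vals),
                pd.Series(["a"] * 20 + ["b"] * 20, index=[f"c{i}" for i in range(40)]),
            )
            for sp_name in ("human", "lemur", "mouse")
        }
        assert primate_selective_genes(data).empty

    def test_planted_primate_enriched_called_and_p_verified(self, rng):
        data = self._species_data(rng, {"human": 2.0, "lemur": 2.0, "mouse": 0.1}, cells=60)
        calls = primate_selective_genes(data)
        enr = calls[(calls["category"] == "primate_enriched") & (calls["cell_type"] == "ct0")]
        assert len(enr) == 1
        h = data["human"][0].to_dense()[:60, 0]
        m = data["mouse"][0].to_dense()[:60, 0]
        assert ss.mannwhitneyu(h, m, alternative="two-sided").pvalue < 1e-5

    def test_planted_mouse_only_gene_called_depleted(self, rng):
        data = self._species_data(rng, {"human": 0.1, "lemur": 0.1, "mouse": 2.0}, cells=60)
        calls = primate_selective_genes(data)
        dep = calls[(calls["category"] == "primate_depleted") & (calls["cell_type"] == "ct0")]
        assert len(dep) == 1

    def test_fourfold_boundary_never_called(self):
        # deterministic groups at exactly 4-fold on the de-logged scale
        a = 0.7
        target = 4.0 * (np.expm1(a) + 0.01) - 0.01
        b = float(np.log1p(target))
        data = {}
        for sp_name in ("human", "lemur", "mouse"):
            mu = b if sp_name != "mouse" else a
            vals = np.concatenate([np.full(60, mu), np.full(60, 0.6)])[:, None]
            nm = self._nm(vals)
            data[sp_name] = (
                nm,
                pd.Series(["focal"] * 60 + ["other"] * 60, index=nm.cell_ids),
            )
        calls = primate_selective_genes(data)
        primate = calls[calls["category"].isin(["primate_enriched", "primate_depleted"])]
        assert primate.empty

    def test_small_cell_types_skipped(self, rng):
        data = self._species_data(rng, {"human": 2.0, "lemur": 2.0, "mouse": 0.1}, cells=10)
        assert primate_selective_genes(data, min_cells=16).empty
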