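"""Module scoring, expression-ratio compartments and bivariate coordination."""

import numpy as np
import pandas as pd
import pytest

from iscaging.io import NormalizedMatrix
from iscaging.scoring import (bivariate_coordination, compartment_summary,
                              expression_ratio, gaussian_ellipse_95,
                              mean_expression_by_condition,
                              mean_score_by_mouse, module_score)


def make_norm(values, conditions=None, mice=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = pd.DataFrame(index=pd.Index([f"g{i}" for i in range(n_genes)],
                                        name="gene"))
    cells = pd.DataFrame({
        "mouse": mice or ["m1"] * n_cells,
        "condition": conditions or ["Y"] * n_cells,
    }, index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell"))
    return NormalizedMatrix(values, genes, cells)


class TestModuleScore:
    def test_null_set_scores_near_zero(self, rng):
        # a set drawn from one expression bin is its own control law
        values = rng.gamma(2, 1, size=(400, 1000))
        norm = make_norm(values)
        avg = values.mean(axis=1)
        one_bin = np.argsort(avg)[100:117]  # 17 genes from the same bin
        genes = [f"g{i}" for i in one_bin]
        score = module_score(norm, genes, n_bins=24, n_ctrl=100, seed=0)
        assert abs(score.mean()) < 0.02

    def test_additive_shift_recovered_exactly(self, rng):
        # with a single bin, set genes = controls + c  =>  score == c
        base = rng.normal(5, 0.01, size=(1, 200)).repeat(50, axis=0)
        c = 0.73
        values = np.vstack([base[:10] + c, base[10:]])
        norm = make_norm(values)
        score = module_score(norm, [f"g{i}" for i in range(10)],
                             n_bins=1, n_ctrl=50, seed=3)
        np.testing.assert_allclose(score.to_numpy(), c, atol=1e-12)

    def test_translation_covariance(self, rng):
        values = rng.gamma(2, 1, size=(200, 50))
        norm = make_norm(values)
        genes = [f"g{i}" for i in range(0, 40, 4)]
        s1 = module_score(norm, genes, seed=1, n_bins=10)
        shifted = values.copy()
        idx = [int(g[1:]) for g in genes]
        shifted[idx] += 1.5
        # same bins must be used for the control draw to isolate translation
        norm2 = make_norm(shifted)
        s2 = module_score(norm2, genes, seed=1, n_bins=1)
        s1b = module_score(norm, genes, seed=1, n_bins=1)
        np.testing.assert_allclose((s2 - s1b).to_numpy(), 1.5, atol=1e-12)

    def test_seeded_determinism(self, rng):
        values = rng.gamma(2, 1, size=(100, 30))
        norm = make_norm(values)
        genes = ["g3", "g7", "g11"]
        a = module_score(norm, genes, seed=9)
        b = module_score(norm, genes, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_empty_intersection_raises(self, rng):
        norm = make_norm(rng.gamma(2, 1, size=(50, 10)))
        with pytest.raises(ValueError, match="intersection"):
            module_score(norm, ["nope"], n_bins=5)


class TestMeanScores:
    def test_single_mouse_mean(self):
        scores = pd.Series([0.1, 0.3], index=["c0", "c1"], name="pw")
        meta = pd.DataFrame({"mouse": ["m1", "m1"],
                             "condition": ["Y", "Y"]}, index=["c0", "c1"])
        by_mouse, by_cond = mean_score_by_mouse(scores, meta)
        assert by_mouse.loc[("Y", "m1"), "pw"] == pytest.approx(0.2)

    def test_condition_mean_is_mean_of_mice(self):
        scores = pd.Series([0.1, 0.2, 0.3], index=["c0", "c1", "c2"], name="pw")
        meta = pd.DataFrame({"mouse": ["m1", "m2", "m3"],
                             "condition": ["Y"] * 3}, index=scores.index)
        _, by_cond = mean_score_by_mouse(scores, meta)
        assert by_cond.loc["Y", "pw"] == pytest.approx(0.2)

    def test_cell_order_invariance(self, rng):
        scores = pd.Series(rng.normal(size=9),
                           index=[f"c{i}" for i in range(9)], name="pw")
        meta = pd.DataFrame({"mouse": list("aabbccdde"),
                             "condition": ["Y"] * 4 + ["O"] * 5},
                            index=scores.index)
        perm = rng.permutation(9)
        a = mean_score_by_mouse(scores, meta)[0]
        b = mean_score_by_mouse(scores.iloc[perm], meta)[0]
        pd.testing.assert_frame_equal(a, b)


class TestMeanExpression:
    def _setup(self, values, mice, conditions):
        norm = make_norm(values, conditions=conditions, mice=mice)
        meta = norm.cells.copy()
        meta["cell_type"] = "Stem"
        return norm, meta

    def test_constant_gene(self):
        norm, meta = self._setup(np.full((2, 6), 1.3), list("abcdef"),
                                 ["Y"] * 3 + ["O"] * 3)
        means = mean_expression_by_condition(norm, meta, "Stem", ["g0"],
                                             scale="log")
        np.testing.assert_allclose(means.loc["g0"].to_numpy(), 1.3)

    def test_zero_mouse_included_in_condition_average(self):
        # one mouse at 0 and two at 2v -> condition mean (0 + 2v + 2v) / 3
        v = 0.8
        values = np.array([[0.0, 2 * v, 2 * v]])
        norm, meta = self._setup(values, ["m1", "m2", "m3"], ["Y"] * 3)
        means = mean_expression_by_condition(norm, meta, "Stem", ["g0"],
                                             scale="log")
        assert means.loc["g0", "Y"] == pytest.approx((0 + 2 * v + 2 * v) / 3)

    def test_missing_cluster_raises(self):
        norm, meta = self._setup(np.ones((1, 2)), ["m1", "m2"], ["Y", "Y"])
        with pytest.raises(ValueError, match="cluster"):
            mean_expression_by_condition(norm, meta, "Paneth", ["g0"])


class TestRatios:
    def _means(self, data):
        return pd.DataFrame(data)

    def test_ratio_and_bottom_compartment_edge(self):
        means = self._means({"Y": {"g0": 1.0}, "O": {"g0": 0.5}})
        rt = expression_ratio(means, "O", "Y")
        assert rt.table.loc["g0", "ratio"] == pytest.approx(0.5)
        assert rt.table.loc["g0", "compartment"] == 1

    def test_zero_reference_excluded_and_reported(self):
        means = self._means({"Y": {"g0": 0.0, "g1": 1.0},
                             "O": {"g0": 0.4, "g1": 0.9}})
        rt = expression_ratio(means, "O", "Y")
        assert rt.excluded == ["g0"]
        assert list(rt.table.index) == ["g1"]

    def test_one_gene_per_compartment(self):
        ratios = [0.4, 0.6, 0.9, 1.1, 1.3, 2.0]
        means = self._means({"Y": {f"g{i}": 1.0 for i in range(6)},
                             "O": {f"g{i}": r for i, r in enumerate(ratios)}})
        rt = expression_ratio(means, "O", "Y")
        vec, below1 = compartment_summary(rt)
        np.testing.assert_allclose(vec.to_numpy(), 100 / 6, atol=1e-9)
        assert below1 == pytest.approx(50.0)

    def test_ratio_exactly_one_falls_in_third_compartment(self):
        means = self._means({"Y": {"g0": 2.0}, "O": {"g0": 2.0}})
        rt = expression_ratio(means, "O", "Y")
        vec, below1 = compartment_summary(rt)
        assert vec["compartment_3"] == pytest.approx(100.0)
        assert below1 == pytest.approx(100.0)

    def test_printed_compartment_vector_gives_71_below_one(self):
        # construct 100 genes matching the printed O/Y distribution
        counts = [12, 38, 21, 14, 10, 4]
        mids = [0.3, 0.65, 0.9, 1.1, 1.35, 1.7]
        ratios = np.repeat(mids, counts)
        means = self._means({
            "Y": {f"g{i}": 1.0 for i in range(len(ratios))},
            "O": {f"g{i}": r for i, r in enumerate(ratios)}})
        rt = expression_ratio(means, "O", "Y")
        vec, below1 = compartment_summary(rt)
        np.testing.assert_allclose(vec.to_numpy(),
                                   [12.12, 38.38, 21.21, 14.14, 10.10, 4.04],
                                   atol=0.01)
        assert below1 == pytest.approx(100 * 71 / 99, abs=0.01)


class TestBivariate:
    def _mouse_means(self, array, conditions):
        idx = pd.MultiIndex.from_tuples(
            [(c, f"{c}{i}") for c in conditions for i in range(3)],
            names=["condition", "mouse"])
        return pd.DataFrame(array, index=idx, columns=["A", "B"])

    def test_identical_mice_degenerate(self):
        mm = self._mouse_means(np.ones((12, 2)), ["Y", "O", "O_met", "O_rap"])
        res, ellipses = bivariate_coordination(mm, "A", "B")
        assert res.p == 1.0
        assert all(e["degenerate"] for e in ellipses.values())

    def test_separated_conditions_significant(self, rng):
        hits = 0
        for _ in range(40):
            base = rng.normal(size=(6, 2))
            base[3:] += 10.0
            mm = self._mouse_means(base, ["Y", "O"])
            res, _ = bivariate_coordination(mm, "A", "B")
            hits += res.p < 0.05
        assert hits >= 38

    def test_ellipse_limit_radius(self, rng):
        pts = rng.normal(size=(4000, 2))
        ell = gaussian_ellipse_95(pts)
        target = np.sqrt(5.991)  # chi2(0.95, df=2)
        assert ell["semi_axes"][0] == pytest.approx(target, abs=0.12)
        assert ell["semi_axes"][1] == pytest.approx(target, abs=0.12)
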