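"""Trajectory graph, dichotomization, delay and co-expression statistics."""

import numpy as np
import pandas as pd
import pytest

from iscaging.io import NormalizedMatrix
from iscaging.synthetic_data import SimConfig, sample_latent_cohort
from iscaging.trajectory import (CompartmentPartition, branchpoint_module_profile,
                                 coexpression_index,
                                 compartment_transition_test, emergence_delay,
                                 learn_trajectory, select_and_dichotomize)


def collinear_setup(rng, centers=(0.0, 1.0, 2.0), n=80, labels=None):
    labels = labels or [f"cl{i}" for i in range(len(centers))]
    coords, labs = [], []
    for c, l in zip(centers, labels):
        coords.append(np.column_stack([rng.normal(c, 0.05, n),
                                       rng.normal(0, 0.05, n)]))
        labs.extend([l] * n)
    coords = np.vstack(coords)
    idx = pd.Index([f"c{i}" for i in range(len(labs))])
    return coords, pd.Series(labs, index=idx)


class TestLearnTrajectory:
    def test_collinear_clusters_form_path_with_increasing_pseudotime(self, rng):
        coords, labels = collinear_setup(rng)
        traj = learn_trajectory(coords, labels, "cl0")
        edge_set = {frozenset((a, b)) for a, b, _ in traj.edges}
        assert edge_set == {frozenset(("cl0", "cl1")),
                            frozenset(("cl1", "cl2"))}
        means = traj.pseudotime.groupby(labels).mean()
        assert means["cl0"] < means["cl1"] < means["cl2"]

    def test_tree_has_k_minus_one_edges(self, rng):
        coords, labels = collinear_setup(rng, centers=(0, 1, 2, 3, 4))
        traj = learn_trajectory(coords, labels, "cl0")
        assert len(traj.edges) == 4

    def test_root_medoid_cells_have_zero_pseudotime(self, rng):
        coords, labels = collinear_setup(rng)
        traj = learn_trajectory(coords, labels, "cl0")
        assert traj.pseudotime.min() == 0.0
        assert traj.pseudotime[labels == "cl0"].min() == 0.0

    def test_rotation_invariance(self, rng):
        coords, labels = collinear_setup(rng)
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        a = learn_trajectory(coords, labels, "cl0").pseudotime
        b = learn_trajectory(coords @ rot.T, labels, "cl0").pseudotime
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_missing_root_raises(self, rng):
        coords, labels = collinear_setup(rng)
        with pytest.raises(ValueError, match="root"):
            learn_trajectory(coords, labels, "Paneth")


class TestDichotomize:
    def test_pure_path_all_main(self, rng):
        coords, labels = collinear_setup(rng)
        traj = learn_trajectory(coords, labels, "cl0")
        d = select_and_dichotomize(traj, "cl2")
        assert set(d) == {"main"}

    def test_y_graph_off_path_cluster_is_side(self, rng):
        coords, labels = collinear_setup(rng)
        side = np.column_stack([rng.normal(1.0, 0.05, 100),
                                rng.normal(1.5, 0.05, 100)])
        coords = np.vstack([coords, side])
        labels = pd.concat([labels, pd.Series(
            ["branch"] * 100, index=[f"s{i}" for i in range(100)])])
        traj = learn_trajectory(coords, labels, "cl0")
        d = select_and_dichotomize(traj, "cl2")
        assert (d[labels == "branch"] == "side").all()
        assert (d[labels != "branch"] == "main").all()

    def test_terminus_equals_root_keeps_only_root_cells(self, rng):
        coords, labels = collinear_setup(rng)
        traj = learn_trajectory(coords, labels, "cl0")
        d = select_and_dichotomize(traj, "cl0")
        assert (d[labels == "cl0"] == "main").all()
        assert (d[labels != "cl0"] == "excluded").all()

    def test_unknown_terminus_raises(self, rng):
        coords, labels = collinear_setup(rng)
        traj = learn_trajectory(coords, labels, "cl0")
        with pytest.raises(ValueError, match="terminus"):
            select_and_dichotomize(traj, "nope")


class TestTransitionTest:
    def test_identical_distributions_give_unit_p(self):
        types = np.tile(np.repeat(["A", "B", "C"], 30), 2)
        pt = np.tile(np.repeat([0.1, 0.5, 0.9], 30), 2)
        conds = np.repeat(["Y", "O"], 90)
        part = CompartmentPartition(boundaries=(1 / 3, 2 / 3))
        per_comp, joint = compartment_transition_test(types, pt, part, conds,
                                                      seed=0)
        assert joint.statistic == pytest.approx(0.0)
        assert joint.p == 1.0
        assert all(r.statistic == pytest.approx(0.0)
                   for r in per_comp.values())

    def test_empty_compartment_raises(self):
        part = CompartmentPartition(boundaries=(0.4, 0.6))
        with pytest.raises(ValueError, match="compartment"):
            compartment_transition_test(["A", "A"], [0.1, 0.9], part,
                                        ["Y", "O"], seed=0)

    def test_delay_gives_power(self):
        # single latent cohort with a strong delay: the joint test rejects
        cfg = SimConfig(seed=21, n_cells_per_mouse=1000)
        cfg.delay_per_condition["O"] = 0.15
        cells = sample_latent_cohort(cfg)
        main = cells[cells["branch"] == "main"]
        part = CompartmentPartition.tertiles(main["s"])
        _, joint = compartment_transition_test(
            main["cell_type"], main["s"], part, main["condition"], seed=3)
        assert joint.p < 0.05


class TestEmergenceDelay:
    def _latent(self, delta_o, seed=0, n=1000):
        cfg = SimConfig(
            seed=seed, n_cells_per_mouse=n,
            delay_per_condition={"Y": 0.0, "O": delta_o, "O_met": 0.0,
                                 "O_rap": 0.0})
        cells = sample_latent_cohort(cfg)
        return cells

    def test_null_delay_near_zero(self):
        cells = self._latent(0.0, seed=1)
        d = emergence_delay(cells["cell_type"], cells["s"],
                            np.where(cells["branch"] == "main", "main", "side"),
                            cells["condition"])
        delays = d.filter(like="delay_").to_numpy()
        assert np.nanmax(np.abs(delays)) < 0.02

    def test_recovers_generator_shift(self):
        cells = self._latent(0.1, seed=2)
        d = emergence_delay(cells["cell_type"], cells["s"],
                            np.where(cells["branch"] == "main", "main", "side"),
                            cells["condition"])
        post = d.loc[["R", "R-Div", "Div1", "Div2", "EC"], "delay_O"]
        assert (post > 0).all()
        assert post.between(0.05, 0.15).all()

    def test_full_reversal_restores_young_emergence(self):
        cfg = SimConfig(seed=3, n_cells_per_mouse=1000,
                        delay_per_condition={"Y": 0.0, "O": 0.1,
                                             "O_met": 0.0, "O_rap": 0.1})
        cells = sample_latent_cohort(cfg)
        d = emergence_delay(cells["cell_type"], cells["s"],
                            np.where(cells["branch"] == "main", "main", "side"),
                            cells["condition"])
        assert d["delay_O_met"].abs().max() < 0.02

    def test_sparse_type_reported_missing(self):
        cells = self._latent(0.0, seed=4, n=30)
        d = emergence_delay(cells["cell_type"], cells["s"],
                            np.where(cells["branch"] == "main", "main", "side"),
                            cells["condition"], min_cells=200)
        assert d.filter(like="emergence_").isna().any().any()


def make_norm(values, cell_ids=None):
    values = np.asarray(values, dtype=float)
    genes = pd.DataFrame(index=pd.Index(
        [f"g{i}" for i in range(values.shape[0])], name="gene"))
    ids = cell_ids or [f"c{i}" for i in range(values.shape[1])]
    cells = pd.DataFrame({"mouse": "m", "condition": "Y"},
                         index=pd.Index(ids, name="cell"))
    return NormalizedMatrix(values, genes, cells)


class TestCoexpression:
    def test_disjoint_positive_sets_zero(self, rng):
        n = 100
        early = np.concatenate([np.ones(10) * 9, rng.uniform(0, 1, 90)])
        late = np.concatenate([rng.uniform(0, 1, 90), np.ones(10) * 9])
        norm = make_norm(np.vstack([early, late]))
        out = coexpression_index(norm, "g0", "g1", norm.cell_ids,
                                 positivity_quantile=0.9)
        assert out["index"] == 0.0

    def test_identical_positive_sets_half(self, rng):
        base = rng.uniform(0, 1, 100)
        base[:5] = 9.0
        norm = make_norm(np.vstack([base, base + rng.uniform(0, 0.01, 100)]))
        out = coexpression_index(norm, "g0", "g1", norm.cell_ids,
                                 positivity_quantile=0.95)
        assert out["index"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.gamma(1, 1, size=(2, 50))
        norm = make_norm(values)
        q = 0.96
        out = coexpression_index(norm, "g0", "g1", norm.cell_ids,
                                 positivity_quantile=q)
        pos = [values[i] > np.quantile(values[i], q) for i in (0, 1)]
        co = int((pos[0] & pos[1]).sum())
        denom = int(pos[0].sum() + pos[1].sum())
        assert out["index"] == pytest.approx(co / denom)
        assert out["n_copositive"] == co

    def test_zero_variance_gene_raises(self):
        norm = make_norm(np.vstack([np.ones(30), np.arange(30.0)]))
        with pytest.raises(ValueError, match="variance"):
            coexpression_index(norm, "g0", "g1", norm.cell_ids)

    def test_index_monotone_in_delay_broadening(self):
        # more delay -> broader stage transitions -> more intermediate cells
        from iscaging import generate_cohort
        from iscaging.preprocess import normalize, qc_filter
        from iscaging.trajectory import coexpression_by_condition
        idx = []
        for delta in (0.0, 0.1, 0.2):
            cfg = SimConfig(seed=11, n_cells_per_mouse=400, n_genes=1400,
                            delay_per_condition={"Y": 0.0, "O": delta,
                                                 "O_met": 0.0, "O_rap": 0.0})
            counts, meta, truth = generate_cohort(cfg)
            kept, _ = qc_filter(counts)
            norm = normalize(kept)
            tc = truth.cells.loc[norm.cell_ids]
            scope = (tc["cell_type"].isin(["R", "R-Div", "Div1", "Div2"])
                     & (tc["branch"] == "main")).to_numpy()
            out = coexpression_by_condition(norm, norm.cells, "Uhrf1",
                                            "Ccnb1", scope)
            idx.append(out.loc["O", "index"])
        assert idx[0] <= idx[1] <= idx[2]
        assert idx[2] > 0


class TestBranchpointProfile:
    def _traj(self, rng):
        coords, labels = collinear_setup(rng, centers=(0, 1, 2, 3))
        return learn_trajectory(coords, labels, "cl0"), labels

    def test_constant_score_constant_profile(self, rng):
        traj, labels = self._traj(rng)
        scores = pd.Series(0.42, index=labels.index)
        conds = pd.Series("Y", index=labels.index)
        prof = branchpoint_module_profile(scores, traj, "cl3", conds)
        np.testing.assert_allclose(prof["Y"].to_numpy(), 0.42)

    def test_cell_order_invariance(self, rng):
        traj, labels = self._traj(rng)
        scores = pd.Series(rng.normal(size=len(labels)), index=labels.index)
        conds = pd.Series("Y", index=labels.index)
        a = branchpoint_module_profile(scores, traj, "cl3", conds)
        perm = rng.permutation(len(labels))
        b = branchpoint_module_profile(scores.iloc[perm], traj, "cl3", conds)
        pd.testing.assert_frame_equal(a, b)

    def test_unimodal_program_recovered(self, small_cohort):
        # the cell-cycle program rises and falls along the continuum
        from iscaging.preprocess import normalize, qc_filter
        from iscaging.scoring import module_score
        counts, meta, truth = small_cohort
        kept, _ = qc_filter(counts)
        norm = normalize(kept)
        tc = truth.cells.loc[norm.cell_ids]
        lab = tc["cell_type"].where(
            tc["branch"] == "main",
            tc["branch"].str.replace("side_", "Side"))
        from iscaging.preprocess import embed
        emb = embed(norm, n_components=20)
        traj = learn_trajectory(emb.coords, lab, "Stem")
        scores = module_score(norm, truth.gene_sets["CellCycle"], seed=0)
        prof = branchpoint_module_profile(scores, traj, "EC",
                                          norm.cells["condition"])
        y = prof["Y"].dropna().to_numpy()
        peak = int(np.argmax(y))
        assert 0 < peak < len(y) - 1  # interior peak: rise then fall
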