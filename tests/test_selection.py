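"""Performance clustering, co-clustering consensus and grid selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from inlinebc import simulate as sim
from inlinebc.selection import (
    METRIC_COLUMNS,
    assemble_metrics,
    co_clustering,
    mean_yield_by_domain,
    metacluster,
    pair_id,
    reduce_and_cluster,
    select_barcode_panel,
    select_panel,
    split_pair_id,
)


class TestAssemble:
    def _inputs(self, pairs):
        profiles = pd.DataFrame(
            {c: np.linspace(1, 2, len(pairs)) for c in ("q0", "q1", "q2", "J", "Eq1", "Eq2")},
            index=pairs,
        )
        yields = {p: 30.0 for p in pairs}
        bc_ref = {p: 0.1 for p in pairs}
        return yields, profiles, bc_ref

    def test_canonical_shape_and_order(self):
        pairs = ["F1__R1", "F1__R2", "F2__R1"]
        M = assemble_metrics(*self._inputs(pairs), sample="s1")
        assert M.shape == (3, 8)
        assert tuple(M.columns) == METRIC_COLUMNS

    def test_missing_metric_masks_row_with_warning(self):
        pairs = ["F1__R1", "F1__R2"]
        yields, profiles, bc_ref = self._inputs(pairs)
        yields["F1__R2"] = np.nan
        with pytest.warns(UserWarning, match="masked"):
            M = assemble_metrics(yields, profiles, bc_ref)
        assert M.loc["F1__R2"].isna().any()
        assert not M.loc["F1__R1"].isna().any()

    def test_pair_set_mismatch_raises(self):
        pairs = ["F1__R1", "F1__R2"]
        yields, profiles, bc_ref = self._inputs(pairs)
        del yields["F1__R2"]
        with pytest.raises(ValueError, match="F1__R2"):
            assemble_metrics(yields, profiles, bc_ref)

    def test_tsv_round_trip(self, tmp_path):
        pairs = ["F1__R1", "F2__R2"]
        M = assemble_metrics(*self._inputs(pairs))
        path = tmp_path / "m.tsv"
        M.to_csv(path, sep="\t")
        again = pd.read_csv(path, sep="\t", index_col="pair_id")
        assert np.allclose(again.to_numpy(), M.to_numpy())
        assert list(again.columns) == list(M.columns)

    def test_pair_id_round_trip(self):
        assert split_pair_id(pair_id("Forward_A_1", "Reverse_A_2")) == (
            "Forward_A_1", "Reverse_A_2",
        )


class TestReduceAndCluster:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(5)
        n = 30
        M = pd.DataFrame(
            rng.normal(0, 1, size=(n, 8)), columns=list(METRIC_COLUMNS),
            index=[f"p{i}" for i in range(n)],
        )
        M.iloc[: n // 2] += 12.0  # separation >> noise
        labels = reduce_and_cluster(M, seed=0)
        truth = [0] * (n // 2) + [1] * (n - n // 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_constant_matrix_degenerates_to_one_cluster(self):
        M = pd.DataFrame(
            np.ones((5, 8)), columns=list(METRIC_COLUMNS), index=[f"p{i}" for i in range(5)]
        )
        with pytest.warns(UserWarning, match="constant"):
            labels = reduce_and_cluster(M, seed=0)
        assert set(labels) == {0}

    def test_dominant_direction_retains_one_axis(self):
        # one metric carries ~99% of the variance after z-scoring is
        # avoided by construction: correlated columns -> single component
        rng = np.random.default_rng(6)
        t = rng.normal(size=60)
        M = pd.DataFrame(
            {c: t * (i + 1) + rng.normal(scale=0.01, size=60) for i, c in enumerate(METRIC_COLUMNS)},
            index=[f"p{i}" for i in range(60)],
        )
        # independent eigen check: top eigenvalue share of the z-scored data
        Z = (M - M.mean()) / M.std(ddof=0)
        eig = np.linalg.eigvalsh(np.cov(Z.to_numpy().T))
        assert eig[-1] / eig.sum() > 0.95
        labels = reduce_and_cluster(M, var_target=0.90, seed=1)
        assert set(labels) <= {0, 1}

    def test_fewer_rows_than_clusters_raises(self):
        M = pd.DataFrame([[1.0] * 8], columns=list(METRIC_COLUMNS), index=["p0"])
        with pytest.raises(ValueError, match="fewer unmasked rows"):
            reduce_and_cluster(M, k=2)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        M = pd.DataFrame(
            rng.normal(size=(20, 8)), columns=list(METRIC_COLUMNS),
            index=[f"p{i}" for i in range(20)],
        )
        a = reduce_and_cluster(M, seed=3)
        b = reduce_and_cluster(M, seed=3)
        assert a.equals(b)


class TestCoClustering:
    def test_always_and_never_co_clustered(self):
        maps = [
            pd.Series({"a": 0, "b": 0, "c": 1}),
            pd.Series({"a": 1, "b": 1, "c": 0}),
        ]
        F = co_clustering(maps)
        assert F.loc["a", "b"] == 1.0
        assert F.loc["a", "c"] == 0.0
        assert (np.diag(F) == 1.0).all()

    def test_three_of_four_samples(self):
        maps = [pd.Series({"a": 0, "b": 0})] * 3 + [pd.Series({"a": 0, "b": 1})]
        F = co_clustering(maps)
        assert F.loc["a", "b"] == 0.75

    def test_brute_force_equivalence_on_random_labels(self):
        rng = np.random.default_rng(9)
        items = [f"p{i}" for i in range(10)]
        maps = [pd.Series(rng.integers(0, 3, 10), index=items) for _ in range(5)]
        F = co_clustering(maps)
        for i, j in itertools.combinations(items, 2):
            expected = np.mean([m[i] == m[j] for m in maps])
            assert F.loc[i, j] == pytest.approx(expected)
            assert F.loc[j, i] == pytest.approx(expected)

    def test_masked_items_excluded_from_denominator(self):
        maps = [
            pd.Series({"a": 0, "b": 0}),
            pd.Series({"a": 0, "b": -1}),  # b masked here
        ]
        F = co_clustering(maps)
        assert F.loc["a", "b"] == 1.0  # 1 of 1 jointly-present samples

    def test_never_jointly_present_raises(self):
        maps = [pd.Series({"a": 0, "b": -1}), pd.Series({"a": -1, "b": 0})]
        with pytest.raises(ValueError, match="never jointly"):
            co_clustering(maps)


class TestMetacluster:
    def test_block_structure_recovers_blocks(self):
        items = ["a", "b", "c", "d"]
        F = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
            index=items, columns=items, dtype=float,
        )
        res = metacluster(F, n_meta=2)
        assert res.labels["a"] == res.labels["b"]
        assert res.labels["c"] == res.labels["d"]
        assert res.labels["a"] != res.labels["c"]

    def test_single_item(self):
        F = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        res = metacluster(F, n_meta=1)
        assert list(res.labels) == [0]

    def test_average_linkage_trace_matches_manual_oracle(self):
        # hand-executed agglomeration of D: AB merge at 0.1, CD at 0.3,
        # then (AB,CD) at mean(0.4, 0.9, 0.5, 0.8) = 0.65
        items = ["A", "B", "C", "D"]
        D = pd.DataFrame(
            [
                [0.0, 0.1, 0.4, 0.9],
                [0.1, 0.0, 0.5, 0.8],
                [0.4, 0.5, 0.0, 0.3],
                [0.9, 0.8, 0.3, 0.0],
            ],
            index=items, columns=items,
        )
        res = metacluster(1.0 - D, n_meta=2)
        heights = res.linkage[:, 2]
        assert np.allclose(heights, [0.1, 0.3, 0.65])
        # first merge joins A and B, second joins C and D
        assert set(res.linkage[0, :2]) == {0, 1}
        assert set(res.linkage[1, :2]) == {2, 3}
        assert res.labels["A"] == res.labels["B"] != res.labels["C"] == res.labels["D"]

    def test_newick_covers_all_leaves(self):
        items = ["a", "b", "c"]
        F = pd.DataFrame(np.eye(3) * 0.5 + 0.5, index=items, columns=items)
        res = metacluster(F, n_meta=2)
        assert res.newick.endswith(";")
        for it in items:
            assert it in res.newick

    def test_too_many_metaclusters_raise(self):
        F = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]) + 0.0
        np.fill_diagonal(F.values, 1.0)
        with pytest.raises(ValueError, match="n_meta"):
            metacluster(F, n_meta=3)

    def test_frequency_matrix_validation(self):
        bad = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            metacluster(bad)


def _labels_and_freq(cat, bad_pairs):
    """Perfect consensus: good pairs and bad pairs each fully cohesive."""
    pids = [pair_id(f, r) for f, r in cat.enumerate_pairs()]
    lab = pd.Series([1 if p in bad_pairs else 0 for p in pids], index=pids)
    F = pd.DataFrame(
        (lab.to_numpy()[:, None] == lab.to_numpy()[None, :]).astype(float),
        index=pids, columns=pids,
    )
    return lab, F


class TestSelectPanel:
    def test_homogeneous_panel_selects_full_grid(self):
        cat = sim.random_catalogue(12, 8, seed=51)
        lab, F = _labels_and_freq(cat, bad_pairs=set())
        res = select_panel(lab, F, cat, panel_size=96)
        assert len(res.grid) == 96
        assert res.score == 1.0
        assert sorted(res.forward_ids) == sorted(p.id for p in cat.forwards)

    def test_planted_bad_forward_is_excluded(self):
        cat = sim.random_catalogue(13, 12, seed=52)
        bad_fwd = cat.forwards[4].id
        bad = {pair_id(bad_fwd, r.id) for r in cat.reverses}
        lab, F = _labels_and_freq(cat, bad)
        res = select_panel(lab, F, cat, panel_size=96)
        assert bad_fwd not in res.forward_ids
        assert res.score == 1.0
        # brute-force confirmation over every feasible grid
        best = 0.0
        fids = [p.id for p in cat.forwards]
        rids = [p.id for p in cat.reverses]
        good = {pair_id(f, r) for f in fids for r in rids} - bad
        for f in (8, 12):
            r = 96 // f
            for fsub in itertools.combinations(fids, f):
                for rsub in itertools.combinations(rids, r):
                    score = sum(pair_id(a, b) in good for a in fsub for b in rsub) / 96
                    best = max(best, score)
        assert res.score == best

    def test_96_pair_grid_uses_20_primers(self, bacterial_catalogue):
        lab, F = _labels_and_freq(bacterial_catalogue, bad_pairs=set())
        res = select_panel(lab, F, bacterial_catalogue, panel_size=96)
        assert len(res.forward_ids) * len(res.reverse_ids) == 96
        assert res.n_primers == 20  # 8 x 12 from pools (8, 17)

    def test_selected_grid_is_subset_of_enumeration(self, archaeal_catalogue):
        lab, F = _labels_and_freq(archaeal_catalogue, bad_pairs=set())
        res = select_panel(lab, F, archaeal_catalogue, panel_size=96)
        assert set(res.grid) <= set(archaeal_catalogue.enumerate_pairs())

    def test_matches_exhaustive_optimum_with_scattered_bad_pairs(self):
        # random bad pairs, exact optimum confirmed by full enumeration
        cat = sim.random_catalogue(5, 6, seed=53)
        rng = np.random.default_rng(54)
        pids = [pair_id(f, r) for f, r in cat.enumerate_pairs()]
        bad = set(np.array(pids)[rng.permutation(len(pids))[:8]].tolist())
        lab, F = _labels_and_freq(cat, bad)
        res = select_panel(lab, F, cat, panel_size=12)
        best = 0.0
        fids = [p.id for p in cat.forwards]
        rids = [p.id for p in cat.reverses]
        for f in range(1, 6):
            if 12 % f or 12 // f > 6:
                continue
            r = 12 // f
            for fsub in itertools.combinations(fids, f):
                for rsub in itertools.combinations(rids, r):
                    score = sum(pair_id(a, b) not in bad for a in fsub for b in rsub) / 12
                    best = max(best, score)
        assert res.score == pytest.approx(best)

    def test_infeasible_panel_size_raises(self, tiny_catalogue):
        lab, F = _labels_and_freq(tiny_catalogue, set())
        with pytest.raises(ValueError, match="factorization"):
            select_panel(lab, F, tiny_catalogue, panel_size=97)


class TestPipeline:
    def test_planted_partition_recovery_and_determinism(self):
        cat = sim.random_catalogue(12, 8, seed=61)
        pids = [pair_id(f, r) for f, r in cat.enumerate_pairs()]
        tables, truth = sim.planted_metrics(pids, n_samples=4, bad_fraction=0.25,
                                            effect_size_sd=3.0, seed=62)
        res = select_barcode_panel(tables, cat, panel_size=48, seed=0)
        ari = adjusted_rand_score(truth[res.metacluster_labels.index], res.metacluster_labels)
        assert ari >= 0.9
        res2 = select_barcode_panel(tables, cat, panel_size=48, seed=0)
        assert res2.forward_ids == res.forward_ids
        assert res2.reverse_ids == res.reverse_ids
        assert np.allclose(res2.linkage, res.linkage)
        assert res2.newick == res.newick

    def test_pooled_mode_runs_and_selects_a_grid(self):
        cat = sim.random_catalogue(6, 4, seed=63)
        pids = [pair_id(f, r) for f, r in cat.enumerate_pairs()]
        tables, _ = sim.planted_metrics(pids, n_samples=3, seed=64)
        res = select_barcode_panel(tables, cat, panel_size=12, seed=1, mode="pooled")
        assert len(res.grid) == 12

    def test_frequency_matrix_invariants_under_random_labels(self):
        rng = np.random.default_rng(65)
        items = [f"p{i}" for i in range(15)]
        for _ in range(10):
            maps = [pd.Series(rng.integers(0, 2, 15), index=items) for _ in range(4)]
            F = co_clustering(maps)
            vals = F.to_numpy()
            assert np.allclose(vals, vals.T)
            assert np.allclose(np.diag(vals), 1.0)
            assert ((vals >= 0) & (vals <= 1)).all()


class TestYieldSummary:
    def test_per_domain_means(self):
        df = pd.DataFrame(
            {"domain": ["archaea"] * 3 + ["bacteria"] * 2,
             "yield": [30.0, 35.0, 40.0, 28.0, 33.0]}
        )
        means = mean_yield_by_domain(df)
        assert means["archaea"] == pytest.approx(35.0)
        assert means["bacteria"] == pytest.approx(30.5)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="domain"):
            mean_yield_by_domain(pd.DataFrame({"yield": [1.0]}))
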