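"""Quality control, clustering, annotation, proportions and sex inference."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from xspecies import qc
from xspecies.io import CountMatrix


class TestMadBounds:
    def test_worked_five_point_example(self):
        assert qc.mad_bounds([1, 2, 3, 4, 100], nmads=3) == (0.0, 6.0)

    def test_constant_vector_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="collapse"):
            lo, hi = qc.mad_bounds([5.0] * 10, nmads=3)
        assert lo == hi == 5.0

    def test_symmetric_data_symmetric_bounds(self):
        lo, hi = qc.mad_bounds([-2, -1, 0, 1, 2], nmads=2)
        assert lo == -hi

    def test_too_few_values_fatal(self):
        with pytest.raises(ValueError):
            qc.mad_bounds([1.0, 2.0], nmads=3)


class TestQCFlags:
    def test_high_mito_cell_flagged_and_median_cell_not(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 15, size=(30, 10))
        cm = CountMatrix(counts, [f"g{i}" for i in range(10)],
                         [f"c{i}" for i in range(30)])
        meta = pd.DataFrame({
            "cell_id": list(cm.cell_ids), "species": "human", "replicate": "r1",
            "timepoint": "0h", "low_quality": False,
            "mito_fraction": [0.5] + [0.02] * 29,
        })
        out = qc.qc_flags(cm, meta, qc.QCConfig(mito_threshold={"human": 0.15}))
        out = out.set_index("cell_id")
        assert out.at["c0", "low_quality"]
        median_cells = out.iloc[5:25]
        assert median_cells["low_quality"].sum() <= 2  # MAD band keeps typical cells

    def test_injected_lowq_cells_flagged(self, sim_artifacts):
        _, cms, meta, _, truth = sim_artifacts
        cfg = qc.QCConfig(mito_threshold={"cyno": 0.15, "human": 0.15})
        for cm in cms.values():
            meta = qc.qc_flags(cm, meta, cfg)
        flagged = set(meta.loc[meta["low_quality"], "cell_id"])
        frac = len(set(truth.lowq_ids) & flagged) / len(truth.lowq_ids)
        assert frac >= 0.8


class TestDoubletVote:
    @pytest.mark.parametrize("calls,k,expected", [
        ((1, 1, 0), 2, True),
        ((1, 0, 0), 2, False),
        ((1, 0, 0), 1, True),
    ])
    def test_vote_rules(self, calls, k, expected):
        tabs = [pd.Series({"c1": bool(v)}) for v in calls]
        out = qc.doublet_vote(tabs, ["c1"], k=k)
        assert bool(out["c1"]) is expected

    def test_single_table_passthrough(self):
        tab = pd.Series({"c1": True, "c2": False})
        out = qc.doublet_vote([tab], ["c1", "c2"], k=2)
        assert out.tolist() == [True, False]

    def test_missing_cell_negative_with_warning(self):
        tab = pd.Series({"c1": True})
        with pytest.warns(UserWarning, match="missing"):
            out = qc.doublet_vote([tab], ["c1", "c2"], k=1)
        assert out.tolist() == [True, False]


class TestDoubletScore:
    def test_zero_simulations_zero_scores(self, sim_small):
        _, cc, *_ = sim_small
        scores = qc.synthetic_doublet_score(cc, n_sim=0)
        assert (scores == 0).all()

    def test_deterministic_under_seed(self, sim_small):
        _, cc, *_ = sim_small
        a = qc.synthetic_doublet_score(cc, n_sim=200, seed=7)
        b = qc.synthetic_doublet_score(cc, n_sim=200, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_injected_doublets_score_higher(self, sim_artifacts):
        _, cms, _, _, truth = sim_artifacts
        cm = cms["human"]
        scores = qc.synthetic_doublet_score(cm, seed=0)
        doub = [c for c in truth.doublet_ids if c in scores.index]
        singlet = [c for c in cm.cell_ids
                   if c not in set(truth.doublet_ids) | set(truth.lowq_ids)]
        assert scores[doub].median() > scores[singlet].median()


class TestClusterGraph:
    def test_two_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 0.3, size=(100, 5))
        b = rng.normal(5, 0.3, size=(100, 5))
        emb = np.vstack([a, b])
        labels = qc.cluster_graph(emb, resolution=0.05, seed=0)
        true = np.array([0] * 100 + [1] * 100)
        assert adjusted_rand_score(true, labels) == 1.0

    def test_cluster_count_nondecreasing_in_resolution(self, rng):
        emb = rng.normal(0, 1, size=(150, 5))
        counts = [len(np.unique(qc.cluster_graph(emb, r, seed=0)))
                  for r in (0.1, 1.0, 5.0)]
        assert counts == sorted(counts)

    def test_deterministic_under_seed(self, rng):
        emb = rng.normal(0, 1, size=(80, 4))
        np.testing.assert_array_equal(qc.cluster_graph(emb, 1.0, seed=3),
                                      qc.cluster_graph(emb, 1.0, seed=3))

    def test_too_few_cells_fatal(self, rng):
        with pytest.raises(ValueError):
            qc.cluster_graph(rng.normal(size=(10, 3)), 1.0, k=15)


class TestPruneClusters:
    def test_bad_cluster_fully_removed(self):
        clusters = np.array([0] * 10 + [1] * 10)
        doublet = np.array([True] * 3 + [False] * 17)  # cluster 0: 0.3 > 0.25
        keep, dcl, _ = qc.prune_clusters(clusters, doublet, np.zeros(20, bool))
        assert keep[:10].sum() == 0 and dcl[:10].all()
        assert keep[10:].all()

    def test_below_threshold_only_flagged_removed(self):
        clusters = np.zeros(10, int)
        doublet = np.array([True, True] + [False] * 8)  # 0.2 <= 0.25
        keep, dcl, _ = qc.prune_clusters(clusters, doublet, np.zeros(10, bool))
        assert not dcl.any() and keep.sum() == 8

    def test_no_flags_all_kept_and_idempotent(self):
        clusters = np.array([0, 0, 1, 1])
        keep, *_ = qc.prune_clusters(clusters, np.zeros(4, bool), np.zeros(4, bool))
        assert keep.all()
        keep2, *_ = qc.prune_clusters(clusters[keep], np.zeros(4, bool)[keep],
                                      np.zeros(4, bool)[keep])
        assert keep2.all()


class TestAnnotate:
    def test_majority_label(self):
        out = qc.majority_annotate(np.zeros(10, int), ["A"] * 7 + ["B"] * 3)
        assert set(out) == {"A"}

    def test_tie_breaks_lexicographically(self):
        out = qc.majority_annotate(np.zeros(10, int), ["B"] * 5 + ["A"] * 5)
        assert set(out) == {"A"}

    def test_all_missing_becomes_unknown(self):
        out = qc.majority_annotate(np.zeros(3, int), [None, None, None])
        assert set(out) == {"unknown"}

    def test_never_invents_labels(self, rng):
        clusters = rng.integers(0, 4, 50)
        labels = rng.choice(["A", "B", "C"], 50)
        out = qc.majority_annotate(clusters, labels)
        assert set(out) <= {"A", "B", "C", "unknown"}

    def test_recovers_truth_under_label_noise(self, sim_small, rng):
        _, cc, _, meta, _, _ = sim_small
        cc.normalize()
        emb = qc.pca_embedding(cc, seed=0)
        clusters = qc.cluster_graph(emb, resolution=1.0, seed=0)
        midx = meta.set_index("cell_id")
        true = np.array([midx.at[c, "label"] for c in cc.cell_ids], dtype=object)
        noisy = true.copy()
        flip = rng.random(len(noisy)) < 0.10
        noisy[flip] = rng.choice(["T", "B", "Mono"], size=flip.sum())
        refined = qc.majority_annotate(clusters, noisy)
        assert (refined == true).mean() >= 0.95


class TestRelabelGranularity:
    @pytest.mark.parametrize("l1,l2,expected", [
        ("CD8 T", "MAIT", "MAIT"),
        ("CD4 T", "CD4 TCM", "CD4 T"),
    ])
    def test_whitelist_rules(self, l1, l2, expected):
        out = qc.relabel_granularity([l1], [l2])
        assert out[0] == expected

    def test_empty_keep_list_returns_level1(self):
        out = qc.relabel_granularity(["X"], ["MAIT"], keep_level2=[])
        assert out[0] == "X"


class TestProportions:
    def test_even_split_and_relative_change(self):
        meta = pd.DataFrame({
            "species": ["human"] * 20,
            "timepoint": ["0h"] * 10 + ["24h"] * 10,
            "label": ["A"] * 2 + ["B"] * 8 + ["A"] * 3 + ["B"] * 7,
        })
        tab = qc.proportions_table(meta)
        t0 = tab[(tab["timepoint"] == "0h")].set_index("label")
        t24 = tab[(tab["timepoint"] == "24h")].set_index("label")
        assert t0.at["A", "proportion"] == pytest.approx(0.2)
        assert t24.at["A", "rel_change_vs_0h"] == pytest.approx(0.5)
        for _, grp in tab.groupby(["species", "timepoint"]):
            assert grp["proportion"].sum() == pytest.approx(1.0)


class TestInferSex:
    def test_generator_truth_recovered(self, sim_default):
        _, cc, ch, meta, _, truth = sim_default
        for sp, cm in (("cyno", cc), ("human", ch)):
            calls = qc.infer_sex(cm, meta).set_index(["species", "replicate"])
            for (s, r), sex in truth.sexes.items():
                if s == sp:
                    assert calls.at[(s, r), "sex"] == sex

    def test_all_zero_y_is_female(self):
        cm = CountMatrix(np.zeros((5, 2), int), ["DDX3Y", "G1"],
                         [f"c{i}" for i in range(5)])
        meta = pd.DataFrame({"cell_id": list(cm.cell_ids), "species": "human",
                             "replicate": "r1"})
        out = qc.infer_sex(cm, meta)
        assert out["sex"].tolist() == ["female"]

    def test_markers_absent_undetermined(self):
        cm = CountMatrix(np.ones((5, 1), int), ["G1"], [f"c{i}" for i in range(5)])
        meta = pd.DataFrame({"cell_id": list(cm.cell_ids), "species": "human",
                             "replicate": "r1"})
        with pytest.warns(UserWarning, match="no Y-marker"):
            out = qc.infer_sex(cm, meta)
        assert out["sex"].tolist() == ["undetermined"]
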