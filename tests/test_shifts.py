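"""Shift vectors, humanization mechanics, splits, geometry, importance, sign test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xspecies import shifts
from xspecies.vae import ExpressionVAE, VAEConfig


@pytest.fixture(scope="module")
def toy_model(sim_small):
    from xspecies.orthology import harmonize_duplicating
    from xspecies.vae import select_hvg
    _, cc, ch, _, orth, _ = sim_small
    hc, hh, _ = harmonize_duplicating(cc, ch, orth)
    hc.normalize(); hh.normalize()
    hvg = select_hvg({"cyno": hc, "human": hh}, n_per_species=80)
    X = np.vstack([hc.subset_genes(hvg).normalize().normalized,
                   hh.subset_genes(hvg).normalize().normalized])
    cfg = VAEConfig(latent_dim=6, hidden_sizes=(32, 32), batch_size=64,
                    max_epochs=20, patience=8, seed=0)
    return X, ExpressionVAE(X, hvg, cfg).fit()


class TestComputeShift:
    def test_identical_groups_zero_vector(self, rng):
        Z = rng.normal(size=(20, 5))
        mask = np.ones(20, bool)
        sv = shifts.compute_shift(Z, mask, mask)
        assert sv.magnitude == 0.0

    def test_two_single_cells_difference(self, rng):
        Z = rng.normal(size=(2, 4))
        sv = shifts.compute_shift(Z, np.array([True, False]), np.array([False, True]))
        np.testing.assert_allclose(sv.vector, Z[1] - Z[0])

    def test_matches_brute_force_means(self, rng):
        Z = rng.normal(size=(100, 6))
        m1 = rng.random(100) < 0.4
        sv = shifts.compute_shift(Z, m1, ~m1)
        np.testing.assert_allclose(sv.vector, Z[~m1].mean(0) - Z[m1].mean(0))

    def test_translation_equivariance(self, rng):
        Z = rng.normal(size=(50, 4))
        m = rng.random(50) < 0.5
        sv1 = shifts.compute_shift(Z, m, ~m)
        sv2 = shifts.compute_shift(Z + 3.7, m, ~m)
        np.testing.assert_allclose(sv1.vector, sv2.vector)

    def test_empty_group_fatal(self, rng):
        Z = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="from_group"):
            shifts.compute_shift(Z, np.zeros(5, bool), np.ones(5, bool),
                                 from_group="cyno@0h")


class TestApplyShift:
    def test_zero_shift_equals_reconstruction(self, toy_model):
        X, res = toy_model
        zero = shifts.ShiftVector(np.zeros(res.config.latent_dim))
        np.testing.assert_allclose(shifts.apply_shift(res, X[:10], zero),
                                   res.reconstruct(X[:10]))

    def test_shift_then_negation_roughly_inverts(self, toy_model):
        X, res = toy_model
        v = shifts.ShiftVector(0.5 * np.ones(res.config.latent_dim))
        fwd = shifts.apply_shift(res, X[:20], v)
        back = res.decode(res.encode(fwd) - v.vector)
        recon_err = np.mean((res.reconstruct(X[:20]) - X[:20]) ** 2)
        assert np.mean((back - res.reconstruct(X[:20])) ** 2) < max(4 * recon_err, 0.5)

    def test_latent_mismatch_fatal(self, toy_model):
        X, res = toy_model
        with pytest.raises(ValueError, match="latent"):
            shifts.apply_shift(res, X[:2], shifts.ShiftVector(np.zeros(3)))


class TestMeanRankCorrelation:
    def test_identity_and_reversal(self, rng):
        A = rng.random(size=(5, 20))
        assert shifts.mean_rank_correlation(A, A) == pytest.approx(1.0)
        B = np.sort(A.mean(0))[::-1][None, :].repeat(3, axis=0)
        A2 = np.sort(A.mean(0))[None, :].repeat(3, axis=0)
        assert shifts.mean_rank_correlation(A2, B, nonzero_filter_on=False) \
            == pytest.approx(-1.0)

    def test_hand_computed_five_gene_example(self):
        # sum of squared rank differences is 4, so rho = 1 - 6*4/(5*24) = 0.8
        A = np.array([[1.0, 2, 3, 4, 5]] * 2)
        B = np.array([[2.0, 1, 3, 5, 4]] * 2)
        with pytest.raises(ValueError):
            shifts.mean_rank_correlation(A, B)  # < 10 genes guard
        rho, _ = stats.spearmanr(A.mean(0), B.mean(0))
        assert rho == pytest.approx(0.8)

    def test_matches_scipy_oracle_on_permuted_means(self, rng):
        perm = rng.permutation(12)
        A = np.tile(np.arange(12, dtype=float), (3, 1))
        B = np.tile(perm.astype(float) + 1.0, (3, 1))
        expected = stats.spearmanr(A.mean(0), B.mean(0)).statistic
        assert shifts.mean_rank_correlation(A, B, nonzero_filter_on=False) \
            == pytest.approx(expected)

    def test_zero_filter_drops_reference_zeros(self, rng):
        A = rng.random(size=(4, 12)) + 0.1
        B = A.copy()
        B[:, 0] = 0.0
        A_perturbed = A.copy()
        A_perturbed[:, 0] = 100.0  # huge discrepancy only in a filtered gene
        assert shifts.mean_rank_correlation(A_perturbed, B) == pytest.approx(1.0)


class TestVectorGeometry:
    def test_parallel_antiparallel_orthogonal(self):
        v = shifts.ShiftVector(np.array([1.0, 0.0]))
        w = shifts.ShiftVector(np.array([0.0, 1.0]))
        neg = shifts.ShiftVector(np.array([-1.0, 0.0]))
        assert shifts.vector_geometry(v, v)["cosine"] == pytest.approx(1.0)
        g = shifts.vector_geometry(v, neg)
        assert g["cosine"] == pytest.approx(-1.0)
        assert g["angle_rad"] == pytest.approx(np.pi)
        assert g["rescaled_similarity"] == pytest.approx(0.0)
        assert shifts.vector_geometry(v, w)["cosine"] == pytest.approx(0.0)

    def test_zero_vector_reports_missing(self):
        v = shifts.ShiftVector(np.array([1.0, 0.0]))
        z = shifts.ShiftVector(np.zeros(2))
        assert np.isnan(shifts.vector_geometry(v, z)["cosine"])

    def test_tmdt_has_human_magnitude_at_180deg(self):
        v = shifts.ShiftVector(np.array([3.0, 4.0]))
        g = shifts.vector_geometry(v, v)
        assert g["tmdt_xy"] == (-5.0, 0.0)


class TestSplitDataset:
    @pytest.fixture
    def meta(self):
        rows = []
        for sp in ("cyno", "human"):
            for rep in ("r1", "r2"):
                for i in range(50):
                    rows.append({"cell_id": f"{sp}:{rep}:{i}", "species": sp,
                                 "replicate": rep})
        return pd.DataFrame(rows)

    def test_replicate_split_is_clean_partition(self, meta):
        tr, te = shifts.split_dataset(meta, shifts.SplitSpec(mode="by_replicate"))
        assert set(tr) | set(te) == set(meta["cell_id"])
        assert not set(tr) & set(te)
        reps = meta.set_index("cell_id")["replicate"]
        assert set(reps[tr]) == {"r1"} and set(reps[te]) == {"r2"}

    def test_random_split_size_within_three_sigma(self):
        meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(10_000)],
                             "species": "human", "replicate": "r1"})
        _, te = shifts.split_dataset(meta, shifts.SplitSpec(mode="random", seed=0))
        sigma = np.sqrt(10_000 * 0.25)
        assert abs(len(te) - 5_000) < 3 * sigma

    def test_same_seed_same_split(self, meta):
        s = shifts.SplitSpec(mode="random", seed=5)
        assert shifts.split_dataset(meta, s) == shifts.split_dataset(meta, s)

    def test_single_replicate_fatal(self):
        meta = pd.DataFrame({"cell_id": ["a", "b"], "species": "cyno",
                             "replicate": "r1"})
        with pytest.raises(ValueError, match="replicate"):
            shifts.split_dataset(meta, shifts.SplitSpec(mode="by_replicate"))


class TestSignConcordance:
    def test_printed_value_11_of_13(self):
        assert shifts.sign_concordance_test(11, 13) == pytest.approx(0.022, abs=5e-4)

    def test_center_is_one(self):
        assert shifts.sign_concordance_test(5, 10) == pytest.approx(1.0)

    def test_all_positive_closed_form(self):
        assert shifts.sign_concordance_test(13, 13) == pytest.approx(2 * 0.5 ** 13)

    def test_equals_brute_force_enumeration_all_n_up_to_20(self):
        from math import comb
        for n in range(1, 21):
            pmf = [comb(n, i) * 0.5 ** n for i in range(n + 1)]
            for k in range(n + 1):
                lower = sum(pmf[: k + 1])
                upper = sum(pmf[k:])
                expected = min(1.0, 2 * min(lower, upper))
                assert shifts.sign_concordance_test(k, n) == pytest.approx(expected)

    def test_zero_total_fatal(self):
        with pytest.raises(ValueError):
            shifts.sign_concordance_test(0, 0)


class TestFeatureImportance:
    def test_noop_perturbation_zero_importance(self, toy_model):
        X, res = toy_model
        n, g = 20, X.shape[1]
        const = np.tile(X[:1], (n, 1))  # all cells identical => sd 0, at mean
        labels = np.array(["human"] * n)
        st = shifts.SpeciesGeneStats.from_matrix(const, labels, res.gene_ids)
        imp = shifts.feature_importance(res, const, labels, st)
        np.testing.assert_allclose(imp.values, 0.0, atol=1e-12)

    def test_importance_nonnegative(self, toy_model):
        X, res = toy_model
        labels = np.array(["cyno"] * (X.shape[0] // 2)
                          + ["human"] * (X.shape[0] - X.shape[0] // 2))
        st = shifts.SpeciesGeneStats.from_matrix(X, labels, res.gene_ids)
        imp = shifts.feature_importance(res, X[:50], labels[:50], st)
        assert (imp >= 0).all()


class TestImportanceVsDGE:
    def test_identical_ranking_rho_one(self):
        genes = [f"g{i}" for i in range(30)]
        imp = pd.Series(np.linspace(1, 30, 30), index=genes)
        tab = pd.DataFrame({"gene": genes, "p": 10.0 ** (-np.linspace(1, 30, 30)),
                            "logFC": np.zeros(30)})
        out = shifts.importance_vs_dge(imp, tab)
        assert out["rho"] == pytest.approx(1.0) and out["direction"] == 1

    def test_independent_rankings_near_zero(self, rng):
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        rejections = 0
        for _ in range(20):
            imp = pd.Series(rng.random(n), index=genes)
            tab = pd.DataFrame({"gene": genes, "p": rng.random(n)})
            if abs(shifts.importance_vs_dge(imp, tab)["rho"]) >= 0.08:
                rejections += 1
        assert rejections <= 1  # |rho| < 0.08 at ~95% of draws

    def test_aggregator_reproduces_binomial(self):
        corrs = [0.5] * 11 + [-0.2] * 2
        out = shifts.sign_aggregate(corrs)
        assert out["n_positive"] == 11 and out["n_total"] == 13
        assert out["p"] == pytest.approx(0.022, abs=5e-4)
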