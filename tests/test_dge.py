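"""DGE engine, pi0 estimator, cross-species statistics, enrichment, Jaccard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xspecies import dge as D
from xspecies.io import GeneSetCollection


def nb_counts(rng, mu, disp, n):
    return rng.negative_binomial(disp, disp / (disp + mu), size=(n, len(mu)))


class TestFilterGenes:
    def test_detection_rate_rule(self):
        counts = np.zeros((10, 3), int)
        counts[:8, 0] = 1          # 80% in the only group
        counts[:5, 1] = 1          # 50%
        kept = D.filter_genes(counts, ["a", "b", "c"], ["g1"] * 10, min_prop=0.7)
        assert kept == ["a"]

    def test_all_zero_gene_removed_even_at_zero_min_prop(self):
        counts = np.array([[1, 0], [2, 0], [1, 0]])
        kept = D.filter_genes(counts, ["a", "b"], ["g"] * 3, min_prop=0.0)
        assert kept == ["a"]

    def test_kept_if_any_group_passes(self):
        counts = np.vstack([np.ones((5, 1), int), np.zeros((15, 1), int)])
        labels = ["A"] * 5 + ["B"] * 15
        assert D.filter_genes(counts, ["a"], labels, min_prop=0.7) == ["a"]

    def test_nothing_survives_fatal(self):
        with pytest.raises(ValueError, match="no genes"):
            D.filter_genes(np.zeros((5, 2), int), ["a", "b"], ["g"] * 5)


class TestDGETest:
    def test_null_pvalues_uniform(self, rng):
        n, G = 150, 2000
        mu = np.exp(rng.normal(0, 1, G)); mu = 5 * mu / mu.mean()
        counts = nb_counts(rng, mu, 2.0, 2 * n)
        maskA = np.arange(2 * n) < n
        tab = D.dge_test(counts, [f"g{i}" for i in range(G)], maskA, ~maskA)
        ks = stats.kstest(tab["p"], "uniform").statistic
        assert ks < 0.05

    def test_planted_effects_recovered_with_correct_signs(self, rng):
        n, G = 200, 1000
        mu = np.exp(rng.normal(0, 1, G)); mu = 5 * mu / mu.mean()
        lfc = np.zeros(G)
        de = rng.choice(G, 200, replace=False)
        lfc[de] = rng.choice([-1.0, 1.0], 200)
        cA = nb_counts(rng, mu, 2.0, n)
        cB = nb_counts(rng, mu * np.exp(lfc), 2.0, n)
        counts = np.vstack([cA, cB])
        maskA = np.arange(2 * n) < n
        tab = D.dge_test(counts, [f"g{i}" for i in range(G)], maskA, ~maskA)
        sig = tab.iloc[de]
        recovered = sig["fdr"] <= 0.05
        assert recovered.mean() >= 0.8
        signs_ok = np.sign(sig.loc[recovered, "logFC"]) == np.sign(lfc[de][recovered.to_numpy()])
        assert signs_ok.mean() >= 0.95

    def test_group_below_minimum_fatal(self, rng):
        counts = rng.integers(0, 5, size=(10, 4))
        with pytest.raises(ValueError, match="too small"):
            D.dge_test(counts, list("abcd"), np.arange(10) < 2, np.arange(10) >= 2)

    def test_nb_glm_agrees_with_wilcoxon_on_strong_effect(self, rng):
        n, G = 60, 15
        mu = np.full(G, 8.0)
        lfc = np.zeros(G); lfc[:5] = 1.5
        counts = np.vstack([nb_counts(rng, mu, 2.0, n),
                            nb_counts(rng, mu * np.exp(lfc), 2.0, n)])
        maskA = np.arange(2 * n) < n
        genes = [f"g{i}" for i in range(G)]
        w = D.dge_test(counts, genes, maskA, ~maskA, method="wilcoxon")
        g = D.dge_test(counts, genes, maskA, ~maskA, method="nb_glm")
        assert (w["fdr"].iloc[:5] <= 0.05).all()
        assert (g["fdr"].iloc[:5] <= 0.05).all()


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_brute_force(self, ps):
        from statsmodels.stats.multitest import multipletests
        fdr = multipletests(ps, method="fdr_bh")[1]
        n = len(ps)
        order = np.argsort(ps, kind="stable")
        brute = np.empty(n)
        prev = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, ps[i] * n / rank_from_top)
            brute[i] = val
            prev = val
        np.testing.assert_allclose(fdr, brute, atol=1e-12)


class TestFractionRegulated:
    def test_uniform_null_small(self, rng):
        frac = D.fraction_regulated(rng.uniform(0, 1, 10_000))
        assert 0.0 <= frac <= 0.05

    def test_thirty_percent_mixture(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 7000), rng.beta(0.1, 10, 3000)])
        assert D.fraction_regulated(p) == pytest.approx(0.30, abs=0.05)

    def test_saturated_alternative(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert D.fraction_regulated(np.full(200, 1e-10)) == 1.0

    def test_monotone_in_planted_fraction(self, rng):
        est = []
        for f in (0.0, 0.1, 0.3):
            n_alt = int(10_000 * f)
            p = np.concatenate([rng.uniform(0, 1, 10_000 - n_alt),
                                rng.beta(0.1, 10, n_alt)])
            est.append(D.fraction_regulated(p))
        assert est[0] <= est[1] <= est[2]

    def test_too_few_pvalues_fatal(self):
        with pytest.raises(ValueError):
            D.fraction_regulated(np.linspace(0, 1, 50))


class TestCrossSpeciesOverlap:
    def _table(self, genes, fdr, lfc):
        return pd.DataFrame({"gene": genes, "fdr": fdr, "logFC": lfc,
                             "p": fdr})

    def test_identical_tables_fully_shared_same_direction(self):
        t = self._table(list("abcde"), [0.01] * 5, [1, -1, 2, -2, 1])
        out = D.cross_species_overlap(t, t)
        assert out["n_shared"] == 5 and out["frac_same_direction"] == 1.0

    def test_toy_nine_of_ten_exact_binomial(self):
        genes = [f"g{i}" for i in range(10)]
        a = self._table(genes, [0.01] * 10, [1.0] * 10)
        b = self._table(genes, [0.01] * 10, [1.0] * 9 + [-1.0])
        out = D.cross_species_overlap(a, b, exact=True)
        assert out["frac_same_direction"] == pytest.approx(0.9)
        assert out["p_direction"] == pytest.approx(2 * (10 + 1) / 1024)

    def test_disjoint_significant_sets(self):
        a = self._table(list("ab"), [0.01, 0.9], [1, 1])
        b = self._table(list("ab"), [0.9, 0.01], [1, 1])
        out = D.cross_species_overlap(a, b)
        assert out["n_shared"] == 0 and np.isnan(out["frac_same_direction"])

    def test_chisq_matches_r_prop_test_convention(self):
        # one-sample proportion test with continuity correction
        a = self._table([f"g{i}" for i in range(20)], [0.01] * 20, [1.0] * 20)
        b = self._table([f"g{i}" for i in range(20)], [0.01] * 20,
                        [1.0] * 16 + [-1.0] * 4)
        out = D.cross_species_overlap(a, b)
        chisq = (abs(16 - 10) - 0.5) ** 2 / (20 / 4)
        assert out["p_direction"] == pytest.approx(stats.chi2.sf(chisq, 1))


class TestSelectForeground:
    def test_fewer_than_cap_all_returned(self):
        tab = pd.DataFrame({"gene": list("abc"), "fdr": [0.1, 0.1, 0.5],
                            "logFC": [2.0, -1.0, 9.9], "p": [0.01] * 3})
        assert D.select_foreground(tab) == ["a", "b"]

    def test_tie_breaks_smaller_p_then_gene(self):
        tab = pd.DataFrame({"gene": ["z", "a", "m"], "fdr": [0.1] * 3,
                            "logFC": [1.0, 1.0, 1.0], "p": [0.02, 0.01, 0.01]})
        assert D.select_foreground(tab, top_n=2) == ["a", "m"]

    def test_invariant_to_row_order(self, rng):
        n = 50
        tab = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                            "fdr": rng.uniform(0, 0.4, n),
                            "logFC": rng.normal(0, 2, n),
                            "p": rng.uniform(0, 0.2, n)})
        fg1 = D.select_foreground(tab, top_n=10)
        fg2 = D.select_foreground(tab.sample(frac=1, random_state=1), top_n=10)
        assert fg1 == fg2


class TestEnrichFisher:
    def setup_method(self):
        self.bg = {f"b{i}" for i in range(100)}
        self.fg = {f"b{i}" for i in range(10)}

    def test_disjoint_pathway_dropped(self):
        gs = GeneSetCollection({"P": {f"b{i}" for i in range(50, 60)}}, "db")
        out = D.enrich_fisher(self.fg, self.bg, gs)
        assert len(out) == 0

    def test_hypergeometric_oracle(self):
        pw = {f"b{i}" for i in range(5)} | {f"b{i}" for i in range(50, 55)}
        gs = GeneSetCollection({"P": pw}, "db")
        out = D.enrich_fisher(self.fg, self.bg, gs, fdr_cut=1.0)
        expected = stats.hypergeom.sf(4, 100, 10, 10)  # = 6.716e-4 by summation
        brute = sum(stats.hypergeom.pmf(x, 100, 10, 10) for x in range(5, 11))
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert out["p"].iloc[0] == pytest.approx(brute, rel=1e-9)

    def test_fisher_matches_tail_summation_random_tables(self, rng):
        for _ in range(20):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            if min(min(row) for row in table) < 0:
                continue
            _, p = stats.fisher_exact(table, alternative="greater")
            brute = sum(stats.hypergeom.pmf(x, N, K, n)
                        for x in range(k, min(K, n) + 1))
            assert p == pytest.approx(brute, rel=1e-8, abs=1e-12)

    def test_identical_hit_sets_keep_highest_odds_ratio(self):
        hits = {"b0", "b1", "b2"}
        gs = GeneSetCollection({"small": hits, "big": hits | {f"b{i}" for i in range(40, 80)}}, "db")
        out = D.enrich_fisher(self.fg, self.bg, gs, fdr_cut=1.0)
        assert out["pathway"].tolist() == ["small"]  # tighter set => larger OR

    def test_min_hits_filter(self):
        gs = GeneSetCollection({"P": {"b0", "b50"}}, "db")
        out = D.enrich_fisher(self.fg, self.bg, gs, fdr_cut=1.0, min_hits=2)
        assert len(out) == 0  # only one foreground hit

    def test_foreground_not_subset_fatal(self):
        gs = GeneSetCollection({"P": {"b0"}}, "db")
        with pytest.raises(ValueError):
            D.enrich_fisher({"nope"}, self.bg, gs)


class TestCoEnrichmentJaccard:
    def _tab(self, d):
        return pd.DataFrame({"pathway": list(d), "hit_genes": [tuple(sorted(v))
                                                               for v in d.values()]})

    def test_identical_disjoint_and_partial(self):
        a = self._tab({"P": {"A", "B", "C"}, "Q": {"X"}, "R": {"M"}})
        b = self._tab({"P": {"B", "C", "D"}, "Q": {"X"}, "R": {"Z"}})
        tab, summary = D.co_enrichment_jaccard(a, b)
        jac = tab.set_index("pathway")["jaccard"]
        assert jac["P"] == pytest.approx(0.5)
        assert jac["Q"] == 1.0 and jac["R"] == 0.0
        assert summary == {"n_shared_pathways": 3, "n_identical_foreground": 1,
                           "n_disjoint_foreground": 1}

    def test_no_shared_pathways(self):
        a = self._tab({"P": {"A"}})
        b = self._tab({"Q": {"A"}})
        tab, summary = D.co_enrichment_jaccard(a, b)
        assert len(tab) == 0 and summary["n_shared_pathways"] == 0
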