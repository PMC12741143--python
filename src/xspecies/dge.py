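"""Differential expression and pathway statistics for cross-species comparison.

The DGE engine defaults to a per-gene Wilcoxon rank-sum test on the
log-normalized layer with log2 fold changes of depth-normalized means
(pseudocount 1) and Benjamini-Hochberg FDR; a plain negative-binomial GLM
with library-size offsets is available as an alternative, and externally
computed tables in the same schema can be fed into every downstream
operation. On top of per-species tables sit the cross-species statistics:
the regulated-transcriptome fraction (Storey's pi0), significant-gene overlap
with a same-direction proportion test, top-|logFC| foreground selection,
one-sided Fisher over-representation with FDR/min-hit/deduplication filters,
and the co-enrichment Jaccard of pathway hit sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "filter_genes",
    "eligible_cell_types",
    "dge_test",
    "fraction_regulated",
    "cross_species_overlap",
    "select_foreground",
    "enrich_fisher",
    "co_enrichment_jaccard",
]


def filter_genes(counts: np.ndarray, gene_ids, group_labels, min_prop: float = 0.7) -> list[str]:
    """Keep genes detected (count > 0) in >= min_prop of cells of some group.

    All-zero genes are always removed. Fatal when nothing survives.
    """
    counts = np.asarray(counts)
    labels = np.asarray(group_labels)
    detected = counts > 0
    keep = np.zeros(counts.shape[1], dtype=bool)
    for g in np.unique(labels):
        rate = detected[labels == g].mean(axis=0)
        keep |= rate >= min_prop
    keep &= detected.any(axis=0)
    if not keep.any():
        raise ValueError(f"no genes survive filtering (0 of {counts.shape[1]})")
    return [g for g, k in zip(gene_ids, keep) if k]


def eligible_cell_types(meta: pd.DataFrame, min_cells: int = 5,
                        label_col: str = "label") -> list[str]:
    """Cell types with >= min_cells at every timepoint in every replicate."""
    ok = []
    for ct, grp in meta.groupby(label_col, observed=True):
        sizes = grp.groupby(["replicate", "timepoint"], observed=True).size()
        n_samples = meta.groupby(["replicate", "timepoint"], observed=True).ngroups
        if len(sizes) == n_samples and (sizes >= min_cells).all():
            ok.append(ct)
    return sorted(ok)


def dge_test(counts: np.ndarray, gene_ids, maskA, maskB, method: str = "wilcoxon",
             normalized: np.ndarray | None = None, scale: float = 1e4,
             context: dict | None = None) -> pd.DataFrame:
    """Per-gene two-sided test of group B (to) vs group A (from).

    logFC is log2((mean_B + 1) / (mean_A + 1)) of depth-scaled counts. The
    default engine is the Wilcoxon rank-sum test on the log-normalized layer;
    ``method="nb_glm"`` fits a per-gene negative-binomial GLM with a
    log-library-size offset and reports the likelihood-ratio p.
    """
    counts = np.asarray(counts)
    maskA = np.asarray(maskA, dtype=bool)
    maskB = np.asarray(maskB, dtype=bool)
    if maskA.sum() < 3 or maskB.sum() < 3:
        raise ValueError(
            f"group too small for DGE (A={int(maskA.sum())}, B={int(maskB.sum())})"
            + (f" in {context}" if context else ""))

    totals = counts.sum(axis=1, keepdims=True).astype(float)
    cpm = counts * (scale / np.where(totals > 0, totals, 1.0))
    meanA = cpm[maskA].mean(axis=0)
    meanB = cpm[maskB].mean(axis=0)
    logfc = np.log2((meanB + 1.0) / (meanA + 1.0))

    if method == "wilcoxon":
        X = normalized
        if X is None:
            X = np.log1p(cpm)
        res = stats.mannwhitneyu(X[maskB], X[maskA], axis=0, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        # constant genes yield nan p under the rank test; they carry no signal
        p = np.where(np.isfinite(p), p, 1.0)
    elif method == "nb_glm":
        p = _nb_glm_pvalues(counts, maskA, maskB)
    else:
        raise ValueError("method must be 'wilcoxon' or 'nb_glm'")

    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"gene": list(gene_ids), "logFC": logfc, "p": p, "fdr": fdr,
                        "mean_from": meanA, "mean_to": meanB})
    for k, v in (context or {}).items():
        out[k] = v
    return out


def _nb_glm_pvalues(counts: np.ndarray, maskA, maskB) -> np.ndarray:
    import statsmodels.api as sm

    sel = maskA | maskB
    y_all = counts[sel]
    group = maskB[sel].astype(float)
    offset = np.log(np.clip(counts[sel].sum(axis=1), 1, None).astype(float))
    X1 = sm.add_constant(group)
    X0 = np.ones((sel.sum(), 1))
    p = np.ones(counts.shape[1])
    for g in range(counts.shape[1]):
        y = y_all[:, g]
        if y.max() == 0:
            continue
        # moment estimate of the dispersion (variance = mu + alpha * mu^2)
        mu = max(y.mean(), 1e-8)
        alpha = max((y.var() - mu) / mu ** 2, 1e-8)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(y, X1, family=fam, offset=offset).fit()
                null = sm.GLM(y, X0, family=fam, offset=offset).fit()
            lr = 2.0 * (full.llf - null.llf)
            p[g] = stats.chi2.sf(max(lr, 0.0), df=1)
        except Exception:
            p[g] = 1.0
    return p


def fraction_regulated(p_values, lambda_grid=None) -> float:
    """Fraction of the transcriptome regulated: 1 - pi0 by Storey's estimator.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid, with a
    cubic smoother evaluated at the largest lambda; the result is clipped to
    [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("fraction_regulated needs >= 100 p-values")
    if np.allclose(p, p[0]):
        warnings.warn("degenerate p-value distribution; estimate is clipped")
    lam = np.arange(0.05, 0.96, 0.05) if lambda_grid is None else np.asarray(lambda_grid)
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    try:
        # cubic smoother over the lambda grid, evaluated at the largest
        # lambda; weights ~ sqrt(1 - lambda) stabilize the tail variance
        # (Var pi0(lambda) grows like 1/(1 - lambda))
        w = np.sqrt(1.0 - lam)
        spline = UnivariateSpline(lam, pi0_lam, w=w, k=3, s=float(len(lam)))
        pi0 = float(spline(lam.max()))
    except Exception:
        pi0 = float(pi0_lam[-1])
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return float(np.clip(1.0 - pi0, 0.0, 1.0))


def cross_species_overlap(dge_cyno: pd.DataFrame, dge_human: pd.DataFrame,
                          fdr_cut: float = 0.20, exact: bool = False) -> dict:
    """Overlap of significantly regulated genes across species.

    Genes are matched on the shared 1:1 gene space (index intersection).
    Among genes significant in both species, the fraction with equal logFC
    sign is tested against 0.5 — by default a chi-square one-sample
    proportion test with continuity correction, or the exact two-sided
    binomial with ``exact=True``.
    """
    a = dge_cyno.set_index("gene") if "gene" in dge_cyno.columns else dge_cyno
    b = dge_human.set_index("gene") if "gene" in dge_human.columns else dge_human
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    sig_a = set(common[a["fdr"] <= fdr_cut])
    sig_b = set(common[b["fdr"] <= fdr_cut])
    shared = sorted(sig_a & sig_b)
    out = {
        "n_cyno_only": len(sig_a - sig_b),
        "n_human_only": len(sig_b - sig_a),
        "n_shared": len(shared),
        "frac_same_direction": float("nan"),
        "p_direction": float("nan"),
    }
    if shared:
        same = (np.sign(a.loc[shared, "logFC"]) == np.sign(b.loc[shared, "logFC"])).to_numpy()
        k, n = int(same.sum()), len(shared)
        out["frac_same_direction"] = k / n
        if exact:
            from .shifts import sign_concordance_test
            out["p_direction"] = sign_concordance_test(k, n)
        else:
            # one-sample proportion chi-square with Yates continuity correction
            chisq = (max(abs(k - n / 2.0) - 0.5, 0.0)) ** 2 / (n / 4.0)
            out["p_direction"] = float(stats.chi2.sf(chisq, df=1))
    return out


def select_foreground(dge_table: pd.DataFrame, fdr_cut: float = 0.20,
                      top_n: int = 200) -> list[str]:
    """Significant genes ranked by |logFC| desc (ties: smaller p, then id)."""
    tab = dge_table if "gene" in dge_table.columns else dge_table.reset_index()
    sig = tab[tab["fdr"] <= fdr_cut].copy()
    sig["abs_lfc"] = sig["logFC"].abs()
    sig = sig.sort_values(["abs_lfc", "p", "gene"], ascending=[False, True, True],
                          kind="stable")
    return sig["gene"].head(top_n).tolist()


def enrich_fisher(foreground, background, gene_sets: GeneSetCollection,
                  fdr_cut: float = 0.05, min_hits: int = 2) -> pd.DataFrame:
    """One-sided Fisher over-representation with the filtering conventions:
    FDR across pathways, a minimum foreground hit count, and — among pathways
    with identical hit sets — retention of only the highest odds ratio.

    The odds ratio uses a Haldane-Anscombe 0.5 correction when a cell is 0;
    the enrichment factor is log(odds ratio).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    rows = []
    for name in sorted(gene_sets.sets):
        members = gene_sets.sets[name] & bg
        if not members:
            continue  # pathway has no overlap with the tested universe
        hits = fg & members
        a = len(hits)
        b = len(fg) - a
        c = len(members) - a
        d = len(bg) - len(fg) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"pathway": name, "source_db": gene_sets.source_db,
                     "n_hits": a, "hit_genes": tuple(sorted(hits)),
                     "odds_ratio": float(orr),
                     "enrichment_factor": float(np.log(orr)) if orr > 0 else float("-inf"),
                     "p": float(p)})
    if not rows:
        return pd.DataFrame(columns=["pathway", "source_db", "n_hits", "hit_genes",
                                     "odds_ratio", "enrichment_factor", "p", "fdr"])
    tab = pd.DataFrame(rows)
    tab["fdr"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    tab = tab[(tab["fdr"] <= fdr_cut) & (tab["n_hits"] >= min_hits)]
    # deduplicate identical hit sets: keep the highest odds ratio
    tab = (tab.sort_values(["odds_ratio", "pathway"], ascending=[False, True], kind="stable")
              .drop_duplicates(subset="hit_genes", keep="first")
              .sort_values("p", kind="stable")
              .reset_index(drop=True))
    return tab


def co_enrichment_jaccard(tableA: pd.DataFrame, tableB: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Jaccard index of foreground hit sets for pathways enriched in both
    species, plus summary counts (shared, identical, disjoint)."""
    a = tableA.set_index("pathway")
    b = tableB.set_index("pathway")
    shared = sorted(a.index.intersection(b.index))
    rows = []
    for name in shared:
        ha = set(a.loc[name, "hit_genes"])
        hb = set(b.loc[name, "hit_genes"])
        union = ha | hb
        rows.append({"pathway": name,
                     "jaccard": len(ha & hb) / len(union) if union else float("nan"),
                     "n_hits_A": len(ha), "n_hits_B": len(hb)})
    tab = pd.DataFrame(rows, columns=["pathway", "jaccard", "n_hits_A", "n_hits_B"])
    summary = {
        "n_shared_pathways": len(shared),
        "n_identical_foreground": int((tab["jaccard"] == 1.0).sum()) if len(tab) else 0,
        "n_disjoint_foreground": int((tab["jaccard"] == 0.0).sum()) if len(tab) else 0,
    }
    return tab, summary
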