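"""Ligand-receptor cell-cell communication scoring and conservation.

One transparent scorer (CellPhoneDB-style): for every ordered pair of cell
types and every ligand-receptor pair whose genes are present, the magnitude
is mean ligand expression in the source type times mean receptor expression
in the target type, and specificity is a label-permutation p-value with
add-one correction. Both statistics are turned into fractional ranks
(ascending = stronger) so downstream filters can use uniform rank cutoffs.
Cross-species conservation is a Fisher exact test of the overlap of
significant interaction sets over the full scored background; network and
activity summaries aggregate surviving interactions per cell-type pair.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "score_interactions",
    "filter_significant",
    "conservation_test",
    "network_summaries",
]

KEY_COLS = ["source_type", "target_type", "ligand", "receptor"]


def _type_means(X: np.ndarray, type_codes: np.ndarray, n_types: int) -> np.ndarray:
    """Mean expression per cell type (n_types x n_genes)."""
    sums = np.zeros((n_types, X.shape[1]))
    np.add.at(sums, type_codes, X)
    counts = np.bincount(type_codes, minlength=n_types).astype(float)
    counts[counts == 0] = 1.0
    return sums / counts[:, None]


def score_interactions(X: np.ndarray, gene_ids, cell_types, lr_pairs: pd.DataFrame,
                       n_perm: int = 1_000, seed: int = 0,
                       context: dict | None = None) -> pd.DataFrame:
    """Score all (source type, target type, ligand, receptor) combinations.

    ``lr_pairs`` needs columns ligand/receptor; pairs with a missing gene are
    excluded (logged via warning) but remembered by the caller as background
    if desired. Specificity p = (b + 1) / (n_perm + 1) where b counts label
    permutations with magnitude >= observed.
    """
    X = np.asarray(X, dtype=float)
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    types = np.asarray(cell_types)
    uniq = sorted(set(types))
    code_of = {t: i for i, t in enumerate(uniq)}
    codes = np.array([code_of[t] for t in types])
    n_types = len(uniq)

    usable, dropped = [], []
    for lig, rec in lr_pairs[["ligand", "receptor"]].itertuples(index=False):
        if lig in gene_pos and rec in gene_pos:
            usable.append((lig, rec))
        else:
            dropped.append((lig, rec))
    if dropped:
        warnings.warn(f"{len(dropped)} ligand-receptor pairs dropped (gene missing)")
    if not usable:
        return pd.DataFrame(columns=KEY_COLS + ["magnitude", "specificity_p",
                                                "magnitude_rank", "specificity_rank"])

    genes_used = sorted({g for pair in usable for g in pair})
    cols = [gene_pos[g] for g in genes_used]
    used_pos = {g: j for j, g in enumerate(genes_used)}
    Xu = X[:, cols]

    obs_means = _type_means(Xu, codes, n_types)
    rows = []
    for lig, rec in usable:
        li, ri = used_pos[lig], used_pos[rec]
        for si, s in enumerate(uniq):
            for ti, t in enumerate(uniq):
                rows.append({"source_type": s, "target_type": t, "ligand": lig,
                             "receptor": rec,
                             "magnitude": obs_means[si, li] * obs_means[ti, ri],
                             "_si": si, "_ti": ti, "_li": li, "_ri": ri})
    tab = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tab), dtype=int)
    obs = tab["magnitude"].to_numpy()
    si = tab["_si"].to_numpy()
    ti = tab["_ti"].to_numpy()
    li = tab["_li"].to_numpy()
    ri = tab["_ri"].to_numpy()
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        means = _type_means(Xu, perm_codes, n_types)
        mag = means[si, li] * means[ti, ri]
        exceed += mag >= obs
    tab["specificity_p"] = (exceed + 1) / (n_perm + 1)
    n = len(tab)
    tab["magnitude_rank"] = stats.rankdata(-obs, method="average") / n
    tab["specificity_rank"] = stats.rankdata(tab["specificity_p"], method="average") / n
    tab = tab.drop(columns=["_si", "_ti", "_li", "_ri"])
    for k, v in (context or {}).items():
        tab[k] = v
    return tab


def filter_significant(table: pd.DataFrame, rank_cut: float = 0.01) -> pd.DataFrame:
    """Rows with both magnitude rank and specificity rank <= rank_cut."""
    if not 0.0 < rank_cut <= 1.0:
        raise ValueError("rank_cut must lie in (0, 1]")
    if table.empty:
        return table.copy()
    sel = (table["magnitude_rank"] <= rank_cut) & (table["specificity_rank"] <= rank_cut)
    return table[sel].copy()


def _keys(table_or_keys) -> set[tuple]:
    if isinstance(table_or_keys, pd.DataFrame):
        return set(map(tuple, table_or_keys[KEY_COLS].itertuples(index=False)))
    return set(map(tuple, table_or_keys))


def conservation_test(pairsA, pairsB, background_pairs) -> dict:
    """Cross-species overlap of significant interactions over a background.

    Fisher exact (one-sided, enrichment) on the 2x2 membership table of A
    and B within the background of all scored interactions. The shared
    percentage is reported against |A union B| and also per species.
    """
    A, B, bg = _keys(pairsA), _keys(pairsB), _keys(background_pairs)
    if not bg:
        raise ValueError("empty background")
    if not A <= bg or not B <= bg:
        raise ValueError("significant sets must be subsets of the background")
    inter = A & B
    union = A | B
    a = len(inter)
    b = len(A - B)
    c = len(B - A)
    d = len(bg) - len(union)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "shared_count": a,
        "shared_percent_union": 100.0 * a / len(union) if union else float("nan"),
        "shared_percent_of_A": 100.0 * a / len(A) if A else float("nan"),
        "shared_percent_of_B": 100.0 * a / len(B) if B else float("nan"),
        "fisher_p": float(p),
    }


def network_summaries(table: pd.DataFrame, edge_cut: float = 0.001) -> dict:
    """Directed cell-type network and per-type activity from significant rows.

    Edge weight is the sum of log10 magnitude ranks of surviving interactions
    (more negative = stronger); the absolute value is provided for display.
    Source activity counts interactions where a type emits ligands; target
    activity where it bears receptors.
    """
    surv = filter_significant(table, edge_cut)
    if surv.empty:
        edges = pd.DataFrame(columns=["source_type", "target_type", "n_interactions",
                                      "weight", "weight_abs"])
    else:
        grp = surv.groupby(["source_type", "target_type"], observed=True)
        edges = grp.agg(n_interactions=("magnitude_rank", "size"),
                        weight=("magnitude_rank", lambda r: float(np.log10(r).sum()))
                        ).reset_index()
        edges["weight_abs"] = edges["weight"].abs()
    all_types = sorted(set(table["source_type"]) | set(table["target_type"])) if len(table) else []
    act_rows = []
    for t in all_types:
        as_source = surv[surv["source_type"] == t] if len(surv) else surv
        as_target = surv[surv["target_type"] == t] if len(surv) else surv
        act_rows.append({
            "cell_type": t,
            "source_count": len(as_source),
            "target_count": len(as_target),
            "source_weight": float(np.log10(as_source["magnitude_rank"]).sum()) if len(as_source) else 0.0,
            "target_weight": float(np.log10(as_target["magnitude_rank"]).sum()) if len(as_target) else 0.0,
        })
    activity = pd.DataFrame(act_rows, columns=["cell_type", "source_count", "target_count",
                                               "source_weight", "target_weight"])
    return {"edges": edges, "activity": activity}
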