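"""Ortholog handling for cross-species expression comparison.

Three regimes, matching three downstream needs:

* ``harmonize_duplicating`` — the model-input regime: every ortholog pair
  becomes its own column in a unified nomenclature, so n:m relations are
  preserved by duplicating columns rather than discarding genes.
* ``collapse_one_to_one`` — the unique-gene regime (differential expression):
  when several source genes map to one target, only the highest-expressed
  source survives and takes the target name.
* ``map_sum_by_human`` — the communication regime: source rows are duplicated
  onto every mapped human name and entries sharing a human name are summed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix, OrthologTable

__all__ = [
    "harmonize_duplicating",
    "collapse_one_to_one",
    "map_sum_by_human",
    "mapping_report",
]


def harmonize_duplicating(cm_cyno: CountMatrix, cm_human: CountMatrix,
                          orthologs: OrthologTable):
    """Unified gene space with column duplication for n:m orthologs.

    Each usable ortholog pair (both genes present in their matrices) yields
    one unified column carrying the cyno gene's values on the cyno side and
    the human gene's values on the human side. Symbols present in both
    matrices but absent from the table are kept once under the (human)
    symbol. All other genes are dropped. Columns are sorted by
    (human name, source name); a human name appearing in several pairs is
    disambiguated as ``human|source`` so identifiers stay unique.

    Returns (cm_cyno', cm_human', unified_ids).
    """
    cyno_set = set(cm_cyno.gene_ids)
    human_set = set(cm_human.gene_ids)
    mapped_cyno: set[str] = set(orthologs.pairs["source_gene"])
    mapped_human: set[str] = set(orthologs.pairs["target_gene"])

    keys: list[tuple[str, str]] = []  # (human name, cyno source)
    for c, h in orthologs.pairs.itertuples(index=False):
        if c in cyno_set and h in human_set:
            keys.append((h, c))
    shared = (cyno_set & human_set) - mapped_cyno - mapped_human
    keys.extend((g, g) for g in shared)
    keys.sort()

    human_multiplicity = pd.Series([h for h, _ in keys]).value_counts()
    unified = [h if human_multiplicity[h] == 1 else f"{h}|{c}" for h, c in keys]

    cyno_pos = {g: j for j, g in enumerate(cm_cyno.gene_ids)}
    human_pos = {g: j for j, g in enumerate(cm_human.gene_ids)}
    cyno_cols = [cyno_pos[c] for _, c in keys]
    human_cols = [human_pos[h] for h, _ in keys]

    out_cyno = CountMatrix(counts=cm_cyno.counts[:, cyno_cols],
                           gene_ids=np.asarray(unified, dtype=object),
                           cell_ids=cm_cyno.cell_ids.copy())
    out_human = CountMatrix(counts=cm_human.counts[:, human_cols],
                            gene_ids=np.asarray(unified, dtype=object),
                            cell_ids=cm_human.cell_ids.copy())
    return out_cyno, out_human, unified


def collapse_one_to_one(cm: CountMatrix, orthologs: OrthologTable) -> CountMatrix:
    """1:1 collapse: per target gene keep the highest-expressed source ortholog.

    "Highest expressed" is the largest grand total of raw counts; exact ties
    break toward the lexicographically smallest source id. Source genes absent
    from the table are kept under their own name unless that name is already
    produced by the mapping.
    """
    pos = {g: j for j, g in enumerate(cm.gene_ids)}
    totals = cm.counts.sum(axis=0)

    chosen: dict[str, str] = {}  # target -> winning source
    usable = orthologs.pairs[orthologs.pairs["source_gene"].isin(pos)]
    for h, grp in usable.groupby("target_gene"):
        sources = sorted(grp["source_gene"])
        best = max(sources, key=lambda c: (totals[pos[c]], ))
        # max() keeps the first maximum in sorted order => lexicographic tie-break
        chosen[h] = best

    mapped_sources = set(orthologs.pairs["source_gene"])
    produced = set(chosen)
    cols: list[tuple[str, int]] = [(h, pos[c]) for h, c in chosen.items()]
    for g, j in pos.items():
        if g not in mapped_sources and g not in produced:
            cols.append((g, j))
    cols.sort()
    names = [g for g, _ in cols]
    idx = [j for _, j in cols]
    return CountMatrix(counts=cm.counts[:, idx],
                       gene_ids=np.asarray(names, dtype=object),
                       cell_ids=cm.cell_ids.copy())


def map_sum_by_human(cm: CountMatrix, orthologs: OrthologTable) -> CountMatrix:
    """Duplicate source rows onto every mapped human name and sum name-sharers.

    A source gene mapping to k human names contributes its full counts to each
    (output mass = k x input mass for that gene, by design); several source
    genes mapping to the same human name are summed. Genes without a mapping
    are dropped; an empty table yields a 0-gene matrix.
    """
    pos = {g: j for j, g in enumerate(cm.gene_ids)}
    usable = orthologs.pairs[orthologs.pairs["source_gene"].isin(pos)]
    targets = sorted(set(usable["target_gene"]))
    out = np.zeros((cm.n_cells, len(targets)), dtype=np.int64)
    t_pos = {h: j for j, h in enumerate(targets)}
    for c, h in usable.itertuples(index=False):
        out[:, t_pos[h]] += cm.counts[:, pos[c]]
    return CountMatrix(counts=out, gene_ids=np.asarray(targets, dtype=object),
                       cell_ids=cm.cell_ids.copy())


def mapping_report(cm_cyno: CountMatrix, orthologs: OrthologTable) -> pd.DataFrame:
    """Mapping-class counts (1:1, 1:m, m:1, unmapped) and coverage fraction."""
    cyno_genes = list(cm_cyno.gene_ids)
    src_counts = orthologs.pairs.groupby("source_gene")["target_gene"].nunique()
    tgt_counts = orthologs.pairs.groupby("target_gene")["source_gene"].nunique()
    classes = {"1:1": 0, "1:m": 0, "m:1": 0, "n:m": 0, "unmapped": 0}
    for g in cyno_genes:
        if g not in src_counts.index:
            classes["unmapped"] += 1
            continue
        n_targets = src_counts[g]
        targets = orthologs.pairs.loc[orthologs.pairs["source_gene"] == g, "target_gene"]
        n_back = int(tgt_counts[targets].max())
        if n_targets == 1 and n_back == 1:
            classes["1:1"] += 1
        elif n_targets > 1 and n_back == 1:
            classes["1:m"] += 1
        elif n_targets == 1 and n_back > 1:
            classes["m:1"] += 1
        else:
            classes["n:m"] += 1
    n = len(cyno_genes)
    rows = [{"class": k, "n_genes": v, "fraction": v / n if n else float("nan")}
            for k, v in classes.items()]
    coverage = 1.0 - classes["unmapped"] / n if n else float("nan")
    rows.append({"class": "covered", "n_genes": n - classes["unmapped"], "fraction": coverage})
    return pd.DataFrame(rows)
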