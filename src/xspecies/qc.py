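"""Quality control and cluster-based annotation.

QC follows a robust-statistics recipe: per-sample MAD thresholds on log
library metrics, a per-species mitochondrial-fraction cutoff, a doublet vote
across one or more callers, and cluster-level pruning that removes whole
high-resolution clusters whose doublet or low-quality fraction exceeds a
threshold (default 0.25) — the rationale being that cells embedded amid many
compromised cells are suspect themselves even when individually passing.

Annotation assigns every cluster its modal per-cell label and offers an
intermediate granularity ("level 1.5") that keeps a fixed list of fine
subtypes while falling back to coarse labels elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, normalize_log1p
from .synth import Y_MARKERS

__all__ = [
    "QCConfig",
    "mad_bounds",
    "qc_flags",
    "synthetic_doublet_score",
    "doublet_calls_from_scores",
    "doublet_vote",
    "cluster_graph",
    "prune_clusters",
    "majority_annotate",
    "relabel_granularity",
    "proportions_table",
    "infer_sex",
    "pca_embedding",
    "DEFAULT_KEEP_LEVEL2",
]

# fine subtypes kept at level 1.5; everything else falls back to level 1
DEFAULT_KEEP_LEVEL2 = [
    "Platelet", "NK Proliferating", "CD4 Proliferating", "CD8 Proliferating",
    "CD14 Mono", "CD16 Mono", "Plasmablast", "gdT", "MAIT", "dnT",
]


def _default_mito_thresholds() -> dict[str, float]:
    # per-species printed cutoffs (as fractions); the two differ by 100x in
    # the source protocol and both are exposed unresolved — override per run
    return {"cyno": 0.0015, "human": 0.15}


@dataclass
class QCConfig:
    nmads: float = 3.0
    mito_threshold: dict[str, float] = field(default_factory=_default_mito_thresholds)
    cluster_bad_fraction: float = 0.25
    doublet_vote_k: int = 2
    qc_cluster_resolution: float = 7.0
    annot_cluster_resolution: float = 4.0
    knn: int = 15
    expected_doublet_rate: float = 0.06
    n_pcs: int = 50

    def __post_init__(self) -> None:
        if self.nmads <= 0:
            raise ValueError("nmads must be positive")
        if not 0.0 <= self.cluster_bad_fraction <= 1.0:
            raise ValueError("cluster_bad_fraction must lie in [0,1]")


def mad_bounds(values, nmads: float) -> tuple[float, float]:
    """median +/- nmads * MAD with the unscaled MAD = median(|x - median|)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("mad_bounds needs at least 3 finite values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        warnings.warn("all values identical within MAD precision; bounds collapse to the median")
    return med - nmads * mad, med + nmads * mad


def qc_flags(cm: CountMatrix, meta: pd.DataFrame, config: QCConfig | None = None) -> pd.DataFrame:
    """Set the ``low_quality`` flag for cells of one species matrix.

    A cell is low-quality when log1p(genes detected) or log1p(total counts)
    leaves the MAD band computed within its sample (replicate x timepoint), or
    when its mitochondrial fraction exceeds the per-species threshold.
    """
    config = config or QCConfig()
    meta = meta.copy()
    sub = meta.set_index("cell_id")
    ids = list(cm.cell_ids)
    totals = cm.counts.sum(axis=1).astype(float)
    ngenes = (cm.counts > 0).sum(axis=1).astype(float)
    log_tot = np.log1p(totals)
    log_gen = np.log1p(ngenes)

    flag = pd.Series(False, index=ids)
    cell_meta = sub.loc[ids]
    for (rep, tp), grp in cell_meta.groupby(["replicate", "timepoint"], observed=True):
        pos = cell_meta.index.get_indexer(grp.index)
        if len(pos) < 3:
            warnings.warn(f"sample {rep}/{tp}: fewer than 3 cells, MAD bounds skipped")
            continue
        for metric in (log_tot, log_gen):
            lo, hi = mad_bounds(metric[pos], config.nmads)
            bad = (metric[pos] < lo) | (metric[pos] > hi)
            flag.iloc[pos] |= bad

    species = cell_meta["species"].iloc[0]
    thr = config.mito_threshold.get(species, 0.15)
    flag |= cell_meta["mito_fraction"].astype(float) > thr

    meta.loc[meta["cell_id"].isin(flag.index[flag]), "low_quality"] = True
    return meta


def pca_embedding(cm: CountMatrix, n_pcs: int = 50, seed: int = 0) -> np.ndarray:
    """Top principal components of the log-normalized layer (computed if absent)."""
    X = cm.normalized if cm.normalized is not None else normalize_log1p(cm.counts)
    n_pcs = min(n_pcs, X.shape[1] - 1, X.shape[0] - 1)
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(X - X.mean(axis=0))


def synthetic_doublet_score(cm: CountMatrix, n_sim: int | None = None,
                            k_neighbors: int = 25, seed: int = 0,
                            n_pcs: int = 30) -> pd.Series:
    """Score each cell by its neighborhood overlap with simulated doublets.

    Artificial doublets are sums of random cell pairs; everything is embedded
    by PCA of the log-normalized matrix and each real cell is scored by the
    fraction of simulated doublets among its k nearest neighbors.
    """
    if cm.n_cells < 50:
        raise ValueError("synthetic_doublet_score needs at least 50 cells")
    rng = np.random.default_rng(seed)
    if n_sim is None:
        n_sim = cm.n_cells
    if n_sim == 0:
        return pd.Series(0.0, index=list(cm.cell_ids))
    pairs = rng.integers(0, cm.n_cells, size=(n_sim, 2))
    doublets = cm.counts[pairs[:, 0]] + cm.counts[pairs[:, 1]]
    combined = np.vstack([cm.counts, doublets])
    X = normalize_log1p(combined)
    n_pcs = min(n_pcs, X.shape[1] - 1)
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(X - X.mean(axis=0))
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb[: cm.n_cells])
    idx = idx[:, 1:]  # drop self
    frac = (idx >= cm.n_cells).mean(axis=1)
    return pd.Series(frac, index=list(cm.cell_ids))


def doublet_calls_from_scores(scores: pd.Series, expected_rate: float = 0.06) -> pd.Series:
    """Binary calls by thresholding at the (1 - expected_rate) score quantile."""
    thr = float(np.quantile(scores.to_numpy(), 1.0 - expected_rate))
    if thr <= 0:
        return scores > 0
    return scores >= thr


def doublet_vote(call_tables: list[pd.Series], cell_ids, k: int = 2) -> pd.Series:
    """A cell is a doublet when >= k of the provided call tables agree.

    With a single table the vote degenerates to that table's calls; cells
    missing from a table count as negative (with a warning).
    """
    if not 1 <= len(call_tables) <= 3:
        raise ValueError("doublet_vote expects 1-3 call tables")
    ids = list(cell_ids)
    votes = np.zeros(len(ids), dtype=int)
    for tab in call_tables:
        missing = [c for c in ids if c not in tab.index]
        if missing:
            warnings.warn(f"{len(missing)} cells missing from a doublet table; treated as negative")
        aligned = tab.reindex(ids, fill_value=False).astype(bool)
        votes += aligned.to_numpy()
    k_eff = 1 if len(call_tables) == 1 else k
    return pd.Series(votes >= k_eff, index=ids)


def cluster_graph(embedding: np.ndarray, resolution: float, seed: int = 0,
                  k: int = 15) -> np.ndarray:
    """kNN-graph Leiden clustering; labels are 0..K-1 by decreasing size."""
    n = embedding.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} cells for k={k} neighbors")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # stable relabel: decreasing cluster size, ties by first occurrence
    sizes = pd.Series(labels).value_counts()
    first_seen = {lab: int(np.argmax(labels == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in labels])


def prune_clusters(clusters: np.ndarray, doublet: np.ndarray, low_quality: np.ndarray,
                   bad_fraction: float = 0.25):
    """Remove flagged cells and whole clusters with too many flagged members.

    Returns (keep_mask, doublet_cluster_mask, lowq_cluster_mask). Clusters
    whose doublet fraction or low-quality fraction strictly exceeds
    ``bad_fraction`` are removed in full.
    """
    clusters = np.asarray(clusters)
    doublet = np.asarray(doublet, dtype=bool)
    low_quality = np.asarray(low_quality, dtype=bool)
    doublet_cluster = np.zeros_like(doublet)
    lowq_cluster = np.zeros_like(doublet)
    for lab in np.unique(clusters):
        mask = clusters == lab
        if doublet[mask].mean() > bad_fraction:
            doublet_cluster |= mask
        if low_quality[mask].mean() > bad_fraction:
            lowq_cluster |= mask
    keep = ~(doublet | low_quality | doublet_cluster | lowq_cluster)
    return keep, doublet_cluster, lowq_cluster


def majority_annotate(clusters: np.ndarray, labels: pd.Series | np.ndarray) -> np.ndarray:
    """Every cell receives its cluster's modal label; ties break lexicographically.

    Clusters whose labels are all missing become "unknown".
    """
    clusters = np.asarray(clusters)
    labels = pd.Series(np.asarray(labels, dtype=object))
    out = np.empty(len(clusters), dtype=object)
    for lab in np.unique(clusters):
        mask = clusters == lab
        counts = labels[mask].dropna().value_counts()
        if counts.empty:
            out[mask] = "unknown"
            continue
        top = counts[counts == counts.max()].index
        out[mask] = sorted(top)[0]
    return out


def relabel_granularity(labels_l1, labels_l2, keep_level2: list[str] | None = None) -> np.ndarray:
    """Intermediate granularity: level-2 label if whitelisted, else level-1."""
    keep = set(DEFAULT_KEEP_LEVEL2 if keep_level2 is None else keep_level2)
    l1 = np.asarray(labels_l1, dtype=object)
    l2 = np.asarray(labels_l2, dtype=object)
    return np.where(np.isin(l2, list(keep)), l2, l1)


def proportions_table(meta: pd.DataFrame, group_by=("species", "timepoint"),
                      label_col: str = "label") -> pd.DataFrame:
    """Per-group label proportions and the relative change vs the 0h baseline."""
    group_by = list(group_by)
    counts = meta.groupby(group_by + [label_col], observed=True).size().rename("n").reset_index()
    counts["proportion"] = counts.groupby(group_by, observed=True)["n"].transform(lambda s: s / s.sum())
    if "timepoint" in group_by:
        others = [g for g in group_by if g != "timepoint"]
        base = counts[counts["timepoint"] == "0h"].set_index(others + [label_col])["proportion"]
        keys = counts.set_index(others + [label_col]).index
        p0 = base.reindex(keys).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            counts["rel_change_vs_0h"] = (counts["proportion"].to_numpy() - p0) / p0
    return counts


def infer_sex(cm: CountMatrix, meta: pd.DataFrame, y_markers: list[str] | None = None,
              threshold: float = 0.2) -> pd.DataFrame:
    """Per-replicate sex call from non-PAR Y-chromosome marker detection.

    A replicate is called male when the fraction of its cells with any
    Y-marker count exceeds ``threshold``; "undetermined" when no marker gene
    is present in the matrix.
    """
    y_markers = Y_MARKERS if y_markers is None else y_markers
    present = [g for g in y_markers if g in set(cm.gene_ids)]
    sub = meta.set_index("cell_id").loc[list(cm.cell_ids)]
    rows = []
    if not present:
        warnings.warn("no Y-marker genes present in the gene space")
        for (sp, rep), _ in sub.groupby(["species", "replicate"], observed=True):
            rows.append({"species": sp, "replicate": rep, "y_positive_fraction": float("nan"),
                         "sex": "undetermined"})
        return pd.DataFrame(rows)
    ymat = cm.subset_genes(present).counts
    any_y = (ymat > 0).any(axis=1)
    for (sp, rep), grp in sub.groupby(["species", "replicate"], observed=True):
        pos = sub.index.get_indexer(grp.index)
        frac = float(any_y[pos].mean())
        rows.append({"species": sp, "replicate": rep, "y_positive_fraction": frac,
                     "sex": "male" if frac > threshold else "female"})
    return pd.DataFrame(rows)
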