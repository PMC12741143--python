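"""Latent shift vectors and their downstream uses.

A shift vector is the difference between two group means in VAE latent space:
the species shift (cyno at baseline -> human at baseline) and the temporal
shift (baseline -> a later timepoint within one species). Adding the species
shift to encoded monkey cells and decoding yields in-silico "humanized"
expression without retraining on the target species. This module also covers
the generalization evaluation (replicate and random splits, mean-rank
Spearman correlation), trajectory geometry (cosine/magnitude comparison of
temporal shifts), the perturbation-based gene importance heuristic, and the
sign-concordance binomial test used to compare importance with differential
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vae import VAEResults

__all__ = [
    "ShiftVector",
    "SpeciesGeneStats",
    "SplitSpec",
    "compute_shift",
    "apply_shift",
    "mean_rank_correlation",
    "vector_geometry",
    "split_dataset",
    "feature_importance",
    "sign_concordance_test",
    "importance_vs_dge",
    "sign_aggregate",
]


@dataclass
class ShiftVector:
    vector: np.ndarray
    kind: str = "species"  # species | temporal
    cell_type: str = ""
    from_group: str = ""
    to_group: str = ""

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("shift vector must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


def compute_shift(Z: np.ndarray, from_mask, to_mask, kind: str = "species",
                  cell_type: str = "", from_group: str = "", to_group: str = "") -> ShiftVector:
    """mean(latent | to_group) - mean(latent | from_group)."""
    Z = np.asarray(Z, dtype=float)
    from_mask = np.asarray(from_mask, dtype=bool)
    to_mask = np.asarray(to_mask, dtype=bool)
    if not from_mask.any():
        raise ValueError(f"empty from_group {from_group or '(unnamed)'}")
    if not to_mask.any():
        raise ValueError(f"empty to_group {to_group or '(unnamed)'}")
    vec = Z[to_mask].mean(axis=0) - Z[from_mask].mean(axis=0)
    return ShiftVector(vector=vec, kind=kind, cell_type=cell_type,
                       from_group=from_group, to_group=to_group)


def apply_shift(results: VAEResults, X_source: np.ndarray, shift: ShiftVector) -> np.ndarray:
    """decode(encode(X) + shift); no retraining or fine-tuning on the target."""
    if len(shift.vector) != results.config.latent_dim:
        raise ValueError("latent width mismatch between shift and model")
    Z = results.encode(X_source)
    return results.decode(Z + shift.vector[None, :])


def mean_rank_correlation(exprA: np.ndarray, exprB: np.ndarray,
                          nonzero_filter_on: bool = True) -> float:
    """Spearman rho between per-gene means of two expression matrices.

    With the filter on, genes whose mean is zero in the reference B (the
    human side) are dropped before correlating; ties get average ranks.
    """
    a = np.asarray(exprA, dtype=float).mean(axis=0)
    b = np.asarray(exprB, dtype=float).mean(axis=0)
    if a.shape != b.shape:
        raise ValueError("expression matrices must share the gene space")
    if nonzero_filter_on:
        keep = b > 0
        a, b = a[keep], b[keep]
    if a.size < 10:
        raise ValueError("fewer than 10 genes left for rank correlation")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def vector_geometry(shift_h: ShiftVector, shift_c: ShiftVector) -> dict:
    """Cosine, rescaled similarity, magnitudes and a planar arrow layout.

    The human vector is placed along the x-axis; the cyno vector sits at
    angle arccos(cosine) with its own magnitude. The "tmdt" arrow is a
    human-magnitude vector at the maximal angle (180 deg) — the theoretical
    maximum difference in trajectory.
    """
    u, v = shift_h.vector, shift_c.vector
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        cosine = float("nan")
    else:
        cosine = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    angle = float("nan") if np.isnan(cosine) else float(np.arccos(cosine))
    return {
        "cosine": cosine,
        "rescaled_similarity": float("nan") if np.isnan(cosine) else (1.0 + cosine) / 2.0,
        "magnitude_human": float(nu),
        "magnitude_cyno": float(nv),
        "angle_rad": angle,
        "human_xy": (float(nu), 0.0),
        "cyno_xy": (float("nan"), float("nan")) if np.isnan(angle)
        else (float(nv * np.cos(angle)), float(nv * np.sin(angle))),
        "tmdt_xy": (float(-nu), 0.0),
    }


@dataclass
class SplitSpec:
    mode: str = "by_replicate"  # by_replicate | random
    test_fraction: float = 0.5
    seed: int = 0
    train_replicate: str | None = None  # by_replicate: which replicate trains

    def __post_init__(self) -> None:
        if self.mode not in ("by_replicate", "random"):
            raise ValueError("mode must be 'by_replicate' or 'random'")


def split_dataset(meta: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test cell-id partition.

    ``by_replicate``: one designated replicate per species trains (default the
    lexicographically first), the rest tests — whole replicates stay on one
    side. ``random``: per-cell Bernoulli(test_fraction) draws.
    """
    if spec.mode == "by_replicate":
        train_ids, test_ids = [], []
        for sp, grp in meta.groupby("species", observed=True):
            reps = sorted(grp["replicate"].unique())
            if len(reps) < 2:
                raise ValueError(f"species {sp}: by_replicate split needs >= 2 replicates")
            train_rep = spec.train_replicate or reps[0]
            sel = grp["replicate"] == train_rep
            train_ids += grp.loc[sel, "cell_id"].tolist()
            test_ids += grp.loc[~sel, "cell_id"].tolist()
        return train_ids, test_ids
    rng = np.random.default_rng(spec.seed)
    test = rng.random(len(meta)) < spec.test_fraction
    return meta.loc[~test, "cell_id"].tolist(), meta.loc[test, "cell_id"].tolist()


@dataclass
class SpeciesGeneStats:
    """Per-gene mean and standard deviation of normalized expression, by species."""

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    gene_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_matrix(cls, X: np.ndarray, species_labels, gene_ids=None) -> "SpeciesGeneStats":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(species_labels)
        mean, sd = {}, {}
        for sp in np.unique(labels):
            sub = X[labels == sp]
            mean[sp] = sub.mean(axis=0)
            sd[sp] = sub.std(axis=0, ddof=0)
        return cls(mean=mean, sd=sd, gene_ids=list(gene_ids) if gene_ids is not None else [])


def feature_importance(results: VAEResults, X: np.ndarray, species_labels,
                       stats_: SpeciesGeneStats, alpha: float = 1.0) -> pd.Series:
    """Perturbation-based gene importance in a trained VAE.

    One gene at a time, every cell's input value is moved toward its
    species-specific mean, with the step capped at alpha * species sd:
    x' = x + clip(mu_gs - x, -alpha*sd, +alpha*sd). Importance is the mean
    Euclidean distance between perturbed and unperturbed latent embeddings.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(species_labels)
    Z0 = results.encode(X)
    mu = np.empty_like(X)
    cap = np.empty_like(X)
    for sp in np.unique(labels):
        m = labels == sp
        mu[m] = stats_.mean[sp][None, :]
        cap[m] = alpha * stats_.sd[sp][None, :]
    out = np.empty(X.shape[1])
    for g in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, g] += np.clip(mu[:, g] - X[:, g], -cap[:, g], cap[:, g])
        Zp = results.encode(Xp)
        out[g] = float(np.linalg.norm(Zp - Z0, axis=1).mean())
    return pd.Series(out, index=list(results.gene_ids), name="importance")


def sign_concordance_test(n_positive: int, n_total: int) -> float:
    """Two-sided exact binomial test against p=0.5 by the doubling rule:
    p = min(1, 2*min(P(X<=k), P(X>=k)))."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    lower = stats.binom.cdf(n_positive, n_total, 0.5)
    upper = stats.binom.sf(n_positive - 1, n_total, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def importance_vs_dge(importance: pd.Series, dge_table: pd.DataFrame,
                      ranking: str = "p") -> dict:
    """Spearman correlation between VAE gene importance and a DGE ranking.

    The DGE importance is -log10(p) by default, or |logFC| with
    ``ranking="logfc"``. Returns rho, its p-value and the sign.
    """
    tab = dge_table.set_index("gene") if "gene" in dge_table.columns else dge_table
    common = importance.index.intersection(tab.index)
    if len(common) < 10:
        raise ValueError("fewer than 10 shared genes between importance and DGE")
    if ranking == "p":
        dge_imp = -np.log10(np.clip(tab.loc[common, "p"].astype(float), 1e-300, None))
    elif ranking == "logfc":
        dge_imp = tab.loc[common, "logFC"].astype(float).abs()
    else:
        raise ValueError("ranking must be 'p' or 'logfc'")
    rho, p = stats.spearmanr(importance.loc[common], dge_imp)
    return {"rho": float(rho), "p": float(p), "direction": int(np.sign(rho)), "n_genes": len(common)}


def sign_aggregate(correlations: list[float]) -> dict:
    """Count positive signs across correlations and test concordance vs chance."""
    signs = [c for c in correlations if np.isfinite(c) and c != 0]
    n_pos = sum(1 for c in signs if c > 0)
    n = len(signs)
    return {"n_positive": n_pos, "n_total": n,
            "p": sign_concordance_test(n_pos, n) if n else float("nan")}
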