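"""Two-species synthetic scRNA-seq generator with planted ground truth.

The generator emulates a two-species PBMC-style stimulation time course:
several cell types with marker programs, three timepoints (0h/6h/24h) whose
per-species temporal log-fold-change vectors have a controllable cross-species
cosine similarity, two replicates per species with random intercepts, a
species baseline effect on a gene subset, an incomplete n:m ortholog map,
negative-binomial counts with lognormal library sizes, injected doublets and
low-quality cells, planted ligand-receptor interactions, and Y-chromosome
marker expression for sex inference.

Counts are drawn as NB(mean = libsize_c * p_cg, dispersion) where p_cg is the
per-cell softmax of additive log-scale effects:

    log mu_cg = base_g + marker_{g,type(c)} + species_{g,s(c)}
                + temporal_{g,s,type,time(c)} + replicate_{g,r(c)}

so planted log-effects are, up to compositional renormalization, the natural
ground truth for differential expression and humanization tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCollection, OrthologTable, write_counts

__all__ = [
    "TemporalSpec",
    "LRTruthPair",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "inject_artifacts",
    "truth_summary",
    "write_simulation",
    "make_gene_sets",
]

Y_MARKERS = ["DDX3Y", "KDM5D", "USP9Y", "UTY", "ZFY", "EIF1AY", "NLGN4Y", "RPS4Y1"]
TIMEPOINTS = ["0h", "6h", "24h"]
SPECIES = ["cyno", "human"]
# relative magnitude of the temporal program at each timepoint: the response
# at 6h is present but much weaker than at 24h
TIME_SCALE = {"0h": 0.0, "6h": 0.4, "24h": 1.0}


@dataclass
class TemporalSpec:
    """Per-cell-type temporal response: size, strength, cross-species cosine."""

    n_affected: int = 150
    effect_size: float = 1.2  # per-gene log-scale sd of the 24h response
    cosine: float = 0.8  # target cosine between human and cyno 24h vectors


@dataclass
class LRTruthPair:
    ligand: str
    receptor: str
    source_type: str
    target_type: str
    boost: float = 2.0
    species: str = "both"  # both | cyno | human


def _default_cell_types() -> list[tuple[str, int]]:
    return [("B", 40), ("CD14 Mono", 50), ("CD4 T", 60), ("CD8 T", 50), ("NK", 40)]


def _default_temporal() -> dict[str, TemporalSpec]:
    return {name: TemporalSpec() for name, _ in _default_cell_types()}


def _default_lr_truth() -> list[LRTruthPair]:
    return [
        LRTruthPair("G0100", "G0101", "CD14 Mono", "CD4 T", 2.0, "both"),
        LRTruthPair("G0102", "G0103", "NK", "CD8 T", 2.0, "both"),
        LRTruthPair("G0104", "G0105", "B", "CD14 Mono", 2.0, "cyno"),
        LRTruthPair("G0106", "G0107", "CD8 T", "B", 2.0, "human"),
    ]


def _default_sexes() -> dict[tuple[str, str], str]:
    # mirrors the study design: two male monkeys, one male + one female human
    return {("cyno", "r1"): "male", ("cyno", "r2"): "male",
            ("human", "r1"): "male", ("human", "r2"): "female"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-species time course."""

    n_genes: int = 600
    cell_types: list[tuple[str, int]] = field(default_factory=_default_cell_types)
    n_replicates: int = 2
    ortholog_coverage: float = 0.813
    frac_one_to_many: float = 0.10
    species_effect_sd: float = 0.8
    min_species_effect: float = 0.5  # carrier genes shift by at least this (log-units)
    frac_species_affected: float = 0.30
    temporal: dict[str, TemporalSpec] = field(default_factory=_default_temporal)
    replicate_effect_sd: float = 0.15
    nb_dispersion: float = 2.0
    libsize_lognormal: tuple[float, float] = (math.log(2500.0), 0.35)
    doublet_rate: float = 0.05
    lowq_rate: float = 0.03
    lr_truth: list[LRTruthPair] = field(default_factory=_default_lr_truth)
    sexes: dict[tuple[str, str], str] = field(default_factory=_default_sexes)
    n_markers_per_type: int = 12
    marker_effect: float = 2.2
    n_mito: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        for frac in (self.ortholog_coverage, self.frac_one_to_many,
                     self.frac_species_affected, self.doublet_rate, self.lowq_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.doublet_rate >= 0.5 or self.lowq_rate >= 0.5:
            raise ValueError("artifact rates must be < 0.5")
        for sd in (self.species_effect_sd, self.replicate_effect_sd):
            if sd < 0:
                raise ValueError("effect sds must be >= 0")
        n_reserved = len(Y_MARKERS) + self.n_mito
        n_regular = self.n_genes - n_reserved
        needed = self.n_markers_per_type * len(self.cell_types)
        if needed > n_regular:
            raise ValueError("more marker genes requested than regular genes available")
        for name, spec in self.temporal.items():
            if spec.n_affected > n_regular:
                raise ValueError(f"temporal spec for {name!r}: more affected genes than available")
            if not -1.0 <= spec.cosine <= 1.0:
                raise ValueError("target cosine must lie in [-1, 1]")

    @property
    def replicates(self) -> list[str]:
        return [f"r{i + 1}" for i in range(self.n_replicates)]


@dataclass
class SimTruth:
    """Planted ground truth emitted next to the dataset."""

    gene_names: dict[str, list[str]]  # per species, in matrix order
    human_name_of: dict[str, dict[str, str]]  # per species: own name -> human-space name
    species_effect: pd.Series = None  # indexed by human-space gene name (human minus cyno)
    temporal_lfc: dict = field(default_factory=dict)  # (species, cell_type, tp) -> pd.Series
    target_cosine: dict = field(default_factory=dict)  # cell_type -> planted cosine
    marker_genes: dict = field(default_factory=dict)  # cell_type -> list of human-space names
    de_genes: dict = field(default_factory=dict)  # (species, cell_type, tp) -> set of names
    doublet_ids: list[str] = field(default_factory=list)
    lowq_ids: list[str] = field(default_factory=list)
    lr_pairs: list[LRTruthPair] = field(default_factory=list)
    sexes: dict = field(default_factory=dict)

    def planted_cosine(self, cell_type: str) -> float:
        """Recompute the cross-species cosine of the stored 24h vectors."""
        vh = self.temporal_lfc[("human", cell_type, "24h")]
        vc = self.temporal_lfc[("cyno", cell_type, "24h")]
        common = vh.index.intersection(vc.index)
        a, b = vh.loc[common].to_numpy(), vc.loc[common].to_numpy()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / denom) if denom > 0 else float("nan")


def _build_gene_space(config: SimConfig, rng: np.random.Generator):
    """Lay out gene names, the ortholog table and name maps for both species.

    Returns per-species gene name lists, a human-space name for every gene
    (paralogs keep their own human name; cyno-private genes map to None), and
    the ortholog pair table.
    """
    n_mito = config.n_mito
    mito_names = [f"MT-{i + 1}" for i in range(n_mito)]
    n_regular = config.n_genes - len(Y_MARKERS) - n_mito
    regular_human = [f"G{i:04d}" for i in range(n_regular)]

    # extra paralogs: 1:m (cyno gene -> two human genes) and m:1 (two cyno -> one human)
    n_1m = int(round(config.frac_one_to_many * n_regular / 2))
    n_m1 = n_1m
    idx_perm = rng.permutation(n_regular)
    one_to_many_idx = sorted(idx_perm[:n_1m])
    many_to_one_idx = sorted(idx_perm[n_1m:n_1m + n_m1])

    human_names = Y_MARKERS + mito_names + regular_human \
        + [f"G{i:04d}P" for i in one_to_many_idx]
    cyno_base_names = Y_MARKERS + mito_names + [f"cG{i:04d}" for i in range(n_regular)]
    cyno_extra = [f"cG{i:04d}P" for i in many_to_one_idx]
    cyno_names = cyno_base_names + cyno_extra

    total_cyno = len(cyno_names)
    target_covered = int(round(config.ortholog_coverage * total_cyno))
    always_covered = len(Y_MARKERS) + n_mito + len(cyno_extra)
    n_regular_covered = max(0, min(n_regular, target_covered - always_covered))
    covered_regular = set(rng.choice(n_regular, size=n_regular_covered, replace=False).tolist())
    # planted LR genes must exist in both species' mapped space, so force them
    # into the covered set (swapping out random covered genes to keep coverage)
    lr_idx = set()
    for pair in config.lr_truth:
        for gene in (pair.ligand, pair.receptor):
            if gene.startswith("G") and gene[1:].isdigit():
                lr_idx.add(int(gene[1:]))
    for i in sorted(lr_idx & set(range(n_regular)) - covered_regular):
        swappable = sorted(covered_regular - lr_idx)
        if swappable:
            covered_regular.discard(swappable[rng.integers(len(swappable))])
        covered_regular.add(i)

    pairs: list[tuple[str, str]] = []
    for name in Y_MARKERS + mito_names:
        pairs.append((name, name))
    for i in range(n_regular):
        if i in covered_regular:
            pairs.append((f"cG{i:04d}", f"G{i:04d}"))
            if i in set(one_to_many_idx):
                pairs.append((f"cG{i:04d}", f"G{i:04d}P"))
    for i in many_to_one_idx:
        pairs.append((f"cG{i:04d}P", f"G{i:04d}"))

    # among uncovered regular genes, half share the human symbol across species
    uncovered = sorted(set(range(n_regular)) - covered_regular)
    shared_symbol = set(uncovered[: len(uncovered) // 2])
    cyno_display = list(cyno_names)
    human_name_of_cyno: dict[str, str] = {}
    for j, name in enumerate(cyno_base_names):
        if j < len(Y_MARKERS) + n_mito:
            human_name_of_cyno[name] = name
        else:
            i = j - len(Y_MARKERS) - n_mito
            if i in shared_symbol:
                cyno_display[j] = f"G{i:04d}"
                human_name_of_cyno[f"G{i:04d}"] = f"G{i:04d}"
            else:
                human_name_of_cyno[name] = f"G{i:04d}"
    for i in many_to_one_idx:
        human_name_of_cyno[f"cG{i:04d}P"] = f"G{i:04d}"

    orth = OrthologTable(pairs=pd.DataFrame(pairs, columns=["source_gene", "target_gene"]))
    # rename shared-symbol genes inside the pair table is NOT needed: shared
    # symbols are by construction absent from the table (uncovered).
    human_name_of_human = {g: g for g in human_names}
    return cyno_display, human_names, human_name_of_cyno, human_name_of_human, orth


def _temporal_vectors(config: SimConfig, rng: np.random.Generator, n_regular: int):
    """Per cell type, paired human/cyno 24h log-FC vectors with exact cosine."""
    out = {}
    for ct, spec in config.temporal.items():
        affected = rng.choice(n_regular, size=spec.n_affected, replace=False)
        u = rng.standard_normal(spec.n_affected)
        u /= np.linalg.norm(u)
        w = rng.standard_normal(spec.n_affected)
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        t = spec.cosine
        scale = spec.effect_size * math.sqrt(spec.n_affected)
        v_h = scale * u
        v_c = scale * (t * u + math.sqrt(max(0.0, 1.0 - t * t)) * w)
        out[ct] = (affected, v_h, v_c)
    return out


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, OrthologTable, SimTruth]:
    """Draw the full two-species dataset; identical config => identical output."""
    rng = np.random.default_rng(config.seed)
    n_res = len(Y_MARKERS) + config.n_mito
    n_regular = config.n_genes - n_res

    (cyno_names, human_names, h_of_c, h_of_h, orth) = _build_gene_space(config, rng)

    # base log-expression per ancestral gene (regular block), reserved blocks fixed
    base_regular = rng.normal(0.0, 1.0, size=n_regular)
    base_y = np.full(len(Y_MARKERS), math.log(2.0))
    base_mito = np.full(config.n_mito, math.log(3.0))

    # marker programs: disjoint blocks of regular genes per cell type
    marker_pool = rng.permutation(n_regular)
    marker_idx = {}
    for k, (ct, _) in enumerate(config.cell_types):
        lo = k * config.n_markers_per_type
        marker_idx[ct] = np.sort(marker_pool[lo:lo + config.n_markers_per_type])

    # species effect on a random regular-gene subset (human minus cyno)
    n_sp = int(round(config.frac_species_affected * n_regular))
    sp_idx = np.sort(rng.choice(n_regular, size=n_sp, replace=False))
    sp_vec = np.zeros(n_regular)
    # carriers shift by a guaranteed minimum plus a half-normal magnitude,
    # with random sign: every planted species gene is a real species marker
    draws = rng.normal(0.0, config.species_effect_sd, size=n_sp)
    sp_vec[sp_idx] = np.sign(draws) * (config.min_species_effect + np.abs(draws))

    temporal = _temporal_vectors(config, rng, n_regular)

    # replicate random intercepts, per species x replicate, on regular genes
    rep_vec = {
        (s, r): rng.normal(0.0, config.replicate_effect_sd, size=n_regular)
        for s in SPECIES for r in config.replicates
    }

    truth = SimTruth(
        gene_names={"cyno": list(cyno_names), "human": list(human_names)},
        human_name_of={"cyno": h_of_c, "human": h_of_h},
        lr_pairs=list(config.lr_truth),
        sexes=dict(config.sexes),
    )
    regular_human_names = [f"G{i:04d}" for i in range(n_regular)]
    truth.species_effect = pd.Series(sp_vec, index=regular_human_names)
    truth.marker_genes = {ct: [regular_human_names[i] for i in idx]
                          for ct, idx in marker_idx.items()}
    for ct, (affected, v_h, v_c) in temporal.items():
        names = [regular_human_names[i] for i in affected]
        for tp in TIMEPOINTS[1:]:
            sc = TIME_SCALE[tp]
            truth.temporal_lfc[("human", ct, tp)] = pd.Series(sc * v_h, index=names)
            truth.temporal_lfc[("cyno", ct, tp)] = pd.Series(sc * v_c, index=names)
            thr = 0.2  # genes moved by >0.2 log-units count as planted DE
            truth.de_genes[("human", ct, tp)] = {n for n, v in zip(names, sc * v_h) if abs(v) > thr}
            truth.de_genes[("cyno", ct, tp)] = {n for n, v in zip(names, sc * v_c) if abs(v) > thr}
        truth.target_cosine[ct] = config.temporal[ct].cosine

    # LR boost lookup: (species, cell_type) -> {human gene name: boost}
    name_to_idx = {regular_human_names[i]: i for i in range(n_regular)}
    lr_boost: dict[tuple[str, str], dict[int, float]] = {}
    for pair in config.lr_truth:
        targets = SPECIES if pair.species == "both" else [pair.species]
        for s in targets:
            for gene, ct in ((pair.ligand, pair.source_type), (pair.receptor, pair.target_type)):
                if gene not in name_to_idx:
                    raise ValueError(f"LR truth gene {gene!r} is not a regular simulated gene")
                lr_boost.setdefault((s, ct), {})[name_to_idx[gene]] = pair.boost
    # planted LR genes get a fixed moderate baseline so the planted signal is
    # defined by the boost, not by the baseline lottery
    for pair in config.lr_truth:
        base_regular[name_to_idx[pair.ligand]] = 0.5
        base_regular[name_to_idx[pair.receptor]] = 0.5

    matrices: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in SPECIES:
        rows = []
        own_names = truth.gene_names[s]
        # map regular-index program vectors into this species' gene order
        human_pos = {g: j for j, g in enumerate(own_names)}

        def species_gene_vector(reg_values: np.ndarray, base: bool = False) -> np.ndarray:
            """Scatter a regular-gene vector (len n_regular) into species order,
            duplicating values onto paralog columns."""
            out = np.zeros(len(own_names))
            out[:len(Y_MARKERS)] = 0.0
            for i in range(n_regular):
                val = reg_values[i]
                if s == "human":
                    out[human_pos[f"G{i:04d}"]] = val
                    p = human_pos.get(f"G{i:04d}P")
                    if p is not None:
                        out[p] = val
                else:
                    j = n_res + i
                    out[j] = val
                    p = human_pos.get(f"cG{i:04d}P")
                    if p is not None:
                        out[p] = val
            return out

        base_full = np.concatenate([base_y, base_mito, np.zeros(len(own_names) - n_res)])
        base_full += species_gene_vector(base_regular)
        sp_full = species_gene_vector(sp_vec) if s == "human" else np.zeros(len(own_names))

        for r in config.replicates:
            rep_full = species_gene_vector(rep_vec[(s, r)])
            male = config.sexes.get((s, r), "male") == "male"
            for tp in TIMEPOINTS:
                for ct, n_cells in config.cell_types:
                    logmu = base_full + sp_full + rep_full
                    mk = np.zeros(n_regular)
                    mk[marker_idx[ct]] = config.marker_effect
                    logmu = logmu + species_gene_vector(mk)
                    if ct in temporal:
                        affected, v_h, v_c = temporal[ct]
                        tv = np.zeros(n_regular)
                        tv[affected] = TIME_SCALE[tp] * (v_h if s == "human" else v_c)
                        logmu = logmu + species_gene_vector(tv)
                    boosts = lr_boost.get((s, ct))
                    if boosts:
                        bv = np.zeros(n_regular)
                        for gi, b in boosts.items():
                            bv[gi] = b
                        logmu = logmu + species_gene_vector(bv)
                    if not male:
                        logmu = logmu.copy()
                        logmu[:len(Y_MARKERS)] = -np.inf  # females: no Y expression
                    p = np.exp(logmu - logmu.max())
                    p /= p.sum()
                    libs = rng.lognormal(*config.libsize_lognormal, size=n_cells)
                    mu = libs[:, None] * p[None, :]
                    disp = config.nb_dispersion
                    block = rng.negative_binomial(disp, disp / (disp + mu))
                    rows.append(block)
                    prefix = "c" if s == "cyno" else "h"
                    start = sum(b.shape[0] for b in rows) - n_cells
                    for k in range(n_cells):
                        meta_rows.append({
                            "cell_id": f"{prefix}:{r}:{tp}:{ct}:{start + k}",
                            "species": s, "replicate": r, "timepoint": tp,
                            "label": ct,
                        })
        matrices[s] = np.vstack(rows)

    meta = pd.DataFrame(meta_rows)
    cm = {}
    for s in SPECIES:
        ids = meta.loc[meta["species"] == s, "cell_id"].to_numpy(dtype=object)
        cm[s] = CountMatrix(counts=matrices[s], gene_ids=np.asarray(truth.gene_names[s], dtype=object),
                            cell_ids=ids)

    meta["cluster"] = pd.array([pd.NA] * len(meta), dtype="Int64")
    for flag in ("low_quality", "doublet", "doublet_cluster", "lowq_cluster"):
        meta[flag] = False
    _attach_mito_fraction(cm, meta)
    return cm["cyno"], cm["human"], meta.reset_index(drop=True), orth, truth


def _attach_mito_fraction(cm: dict[str, CountMatrix], meta: pd.DataFrame) -> None:
    frac = pd.Series(0.0, index=meta["cell_id"])
    for s, m in cm.items():
        mito = np.array([g.startswith("MT-") for g in m.gene_ids])
        tot = m.counts.sum(axis=1).astype(float)
        mt = m.counts[:, mito].sum(axis=1)
        f = np.divide(mt, tot, out=np.zeros_like(tot), where=tot > 0)
        frac.loc[m.cell_ids] = f
    meta["mito_fraction"] = frac.to_numpy()


def inject_artifacts(cm_by_species: dict[str, CountMatrix], meta: pd.DataFrame,
                     config: SimConfig, truth: SimTruth,
                     rng: np.random.Generator | None = None):
    """Append doublets (count sums of two same-sample cells) and low-quality
    cells (shrunken non-mito counts, inflated mito fraction) to each species
    matrix; record injected ids in the truth object.

    The number injected is deterministic: round(rate * n_clean) per species;
    which cells seed them is random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    meta = meta.copy()
    out = {}
    new_rows = []
    for s, m in cm_by_species.items():
        sub = meta[meta["species"] == s].reset_index(drop=True)
        n_clean = len(sub)
        n_doub = int(round(config.doublet_rate * n_clean))
        n_lowq = int(round(config.lowq_rate * n_clean))
        blocks = [m.counts]
        ids = list(m.cell_ids)

        # doublets: two random distinct cells from the same sample
        samples = sub.groupby(["replicate", "timepoint"]).indices
        sample_keys = list(samples)
        for k in range(n_doub):
            key = sample_keys[rng.integers(len(sample_keys))]
            pool = samples[key]
            a, b = rng.choice(pool, size=2, replace=False)
            row = m.counts[a] + m.counts[b]
            cid = f"{'c' if s == 'cyno' else 'h'}:DBL:{k}"
            blocks.append(row[None, :])
            ids.append(cid)
            truth.doublet_ids.append(cid)
            new_rows.append({**sub.iloc[a][["species", "replicate", "timepoint"]].to_dict(),
                             "cell_id": cid, "label": sub.iloc[a]["label"]})

        mito = np.array([g.startswith("MT-") for g in m.gene_ids])
        for k in range(n_lowq):
            a = rng.integers(n_clean)
            row = m.counts[a].astype(float).copy()
            u = rng.uniform(0.05, 0.2)
            row[~mito] = np.round(row[~mito] * u)
            f = rng.uniform(0.25, 0.45)  # target mito fraction, above QC cutoffs
            nonmito_total = row[~mito].sum()
            mito_total_target = f / (1.0 - f) * nonmito_total
            cur = row[mito].sum()
            if cur > 0:
                row[mito] = np.round(row[mito] * (mito_total_target / cur))
            else:
                row[mito] = np.round(np.full(mito.sum(), mito_total_target / mito.sum()))
            cid = f"{'c' if s == 'cyno' else 'h'}:LOWQ:{k}"
            blocks.append(row.astype(np.int64)[None, :])
            ids.append(cid)
            truth.lowq_ids.append(cid)
            new_rows.append({**sub.iloc[a][["species", "replicate", "timepoint"]].to_dict(),
                             "cell_id": cid, "label": sub.iloc[a]["label"]})

        out[s] = CountMatrix(counts=np.vstack(blocks).astype(np.int64),
                             gene_ids=m.gene_ids.copy(),
                             cell_ids=np.asarray(ids, dtype=object))

    if new_rows:
        add = pd.DataFrame(new_rows)
        add["cluster"] = pd.array([pd.NA] * len(add), dtype="Int64")
        for flag in ("low_quality", "doublet", "doublet_cluster", "lowq_cluster"):
            add[flag] = False
        add["mito_fraction"] = 0.0
        meta = pd.concat([meta, add[meta.columns]], ignore_index=True)
    _attach_mito_fraction(out, meta)
    return out, meta.reset_index(drop=True), truth


def truth_summary(truth: SimTruth) -> pd.DataFrame:
    """Tabular account of the planted signal: DE counts, cosines, LR pairs."""
    rows = []
    for (s, ct, tp), genes in sorted(truth.de_genes.items()):
        rows.append({"kind": "planted_de", "species": s, "cell_type": ct,
                     "timepoint": tp, "value": len(genes)})
    for ct, cos in sorted(truth.target_cosine.items()):
        rows.append({"kind": "target_cosine", "species": "both", "cell_type": ct,
                     "timepoint": "24h", "value": cos})
        rows.append({"kind": "recomputed_cosine", "species": "both", "cell_type": ct,
                     "timepoint": "24h", "value": truth.planted_cosine(ct)})
    for p in truth.lr_pairs:
        rows.append({"kind": "lr_pair", "species": p.species,
                     "cell_type": f"{p.source_type}->{p.target_type}",
                     "timepoint": "all", "value": f"{p.ligand}:{p.receptor}"})
    rows.append({"kind": "injected_doublets", "species": "both", "cell_type": "all",
                 "timepoint": "all", "value": len(truth.doublet_ids)})
    rows.append({"kind": "injected_lowq", "species": "both", "cell_type": "all",
                 "timepoint": "all", "value": len(truth.lowq_ids)})
    cols = ["kind", "species", "cell_type", "timepoint", "value"]
    return pd.DataFrame(rows, columns=cols)


def lr_database(truth: SimTruth, n_decoys: int = 96, seed: int = 0) -> pd.DataFrame:
    """Ligand-receptor pair table: planted pairs plus unboosted decoy pairs.

    Mirrors real LR databases, where most catalogued pairs are inactive in
    any given dataset; decoys are drawn from regular human-space genes not
    used by any planted pair.
    """
    rng = np.random.default_rng(seed)
    planted = [(p.ligand, p.receptor) for p in truth.lr_pairs]
    used = {g for pair in planted for g in pair}
    used |= {g for genes in truth.marker_genes.values() for g in genes}
    pool = [g for g in truth.gene_names["human"]
            if g.startswith("G") and not g.endswith("P") and g not in used]
    pool = list(rng.permutation(pool))
    rows = list(planted)
    for k in range(min(n_decoys, len(pool) // 2)):
        rows.append((pool[2 * k], pool[2 * k + 1]))
    return pd.DataFrame(rows, columns=["ligand", "receptor"]).drop_duplicates()


def make_gene_sets(truth: SimTruth, n_random: int = 20, set_size: int = 15,
                   seed: int = 0) -> GeneSetCollection:
    """Gene-set collection for enrichment tests: pathways built from planted
    temporal programs and marker blocks, plus random decoys over the human
    gene space."""
    rng = np.random.default_rng(seed)
    universe = [g for g in truth.gene_names["human"] if g.startswith("G")]
    sets: dict[str, set[str]] = {}
    for ct, genes in truth.marker_genes.items():
        sets[f"MARKER_{ct.replace(' ', '_')}"] = set(genes)
    for (s, ct, tp), genes in truth.de_genes.items():
        if s == "human" and tp == "24h" and genes:
            ranked = sorted(genes)
            sets[f"RESPONSE_{ct.replace(' ', '_')}"] = set(ranked[:max(5, len(ranked) // 3)])
    for k in range(n_random):
        sets[f"RANDOM_{k:02d}"] = set(rng.choice(universe, size=set_size, replace=False).tolist())
    return GeneSetCollection(sets=sets, source_db="synthetic")


def write_simulation(out_dir, cm_cyno: CountMatrix, cm_human: CountMatrix,
                     meta: pd.DataFrame, orth: OrthologTable,
                     gene_sets: GeneSetCollection | None = None) -> dict[str, Path]:
    """Write the full fixture as the MTX/TSV/GMT bundle the io module reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths.update({f"cyno_{k}": v for k, v in write_counts(cm_cyno, out_dir, "cyno_").items()})
    paths.update({f"human_{k}": v for k, v in write_counts(cm_human, out_dir, "human_").items()})
    cells_path = out_dir / "cells.tsv"
    meta.to_csv(cells_path, sep="\t", index=False)
    paths["cells"] = cells_path
    orth_path = out_dir / "orthologs.tsv"
    orth.pairs.to_csv(orth_path, sep="\t", index=False)
    paths["orthologs"] = orth_path
    if gene_sets is not None:
        gmt = out_dir / "gene_sets.gmt"
        with open(gmt, "w", encoding="utf-8") as fh:
            for name, members in gene_sets.sets.items():
                fh.write("\t".join([name, gene_sets.source_db] + sorted(members)) + "\n")
        paths["gene_sets"] = gmt
    return paths
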