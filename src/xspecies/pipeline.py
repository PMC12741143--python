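"""End-to-end orchestration on synthetic (or pre-generated) data.

``run_pipeline`` executes: simulate -> artifact injection -> QC (MAD flags,
doublet scoring + vote, high-resolution cluster pruning) -> annotation
(clustering + majority vote, sex inference, proportions) -> ortholog
harmonization -> per-cell-type VAE training with humanization evaluation
under replicate and random splits -> temporal-shift geometry -> feature
importance vs DGE -> per-species DGE with enrichment and cross-species
overlap/co-enrichment -> ligand-receptor communication with conservation
tests -> a machine-readable report. Every stage writes TSV/JSON outputs under
``run_dir/<stage>/``; a single seed drives all randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccc as ccc_mod
from . import dge as dge_mod
from . import orthology, qc, shifts, synth
from .io import CountMatrix, normalize_log1p
from .vae import ExpressionVAE, VAEConfig, select_hvg

log = logging.getLogger("xspecies")

__all__ = ["default_config", "run_pipeline", "write_report"]

ALL_STAGES = ["vae", "importance", "dge", "ccc", "report"]


def default_config() -> dict:
    """Desk-scale demonstration configuration (all stages, generator defaults)."""
    return {
        "seed": 0,
        "stages": list(ALL_STAGES),
        "simulate": {},  # overrides for synth.SimConfig fields
        "qc": {"mito_threshold": {"cyno": 0.15, "human": 0.15}},
        "vae": {
            "min_cells": 300,
            "latent_dim": 10,
            "hidden_sizes": [128, 128],
            "batch_size": 64,
            "max_epochs": 30,
            "patience": 10,
        },
        "importance": {"max_cells": 200, "alpha": 1.0},
        "dge": {"fdr_overlap": 0.20, "top_n": 200, "min_cells": 5},
        "ccc": {"n_perm": 1000, "rank_cut": 0.01, "edge_cut": 0.001},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sim_config(conf: dict, seed: int) -> synth.SimConfig:
    kwargs = dict(conf.get("simulate") or {})
    kwargs.setdefault("seed", seed)
    if "cell_types" in kwargs:
        kwargs["cell_types"] = [tuple(x) for x in kwargs["cell_types"]]
    if "temporal" in kwargs:
        kwargs["temporal"] = {k: synth.TemporalSpec(**v) if isinstance(v, dict) else v
                              for k, v in kwargs["temporal"].items()}
    return synth.SimConfig(**kwargs)


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: dict, run_dir: Path):
        self.config = config
        self.run_dir = run_dir
        self.seed = int(config.get("seed", 0))

    # --- core stages -----------------------------------------------------

    def simulate(self) -> None:
        sim_cfg = _sim_config(self.config, self.seed)
        cm_c, cm_h, meta, orth, truth = synth.simulate_dataset(sim_cfg)
        cms, meta, truth = synth.inject_artifacts({"cyno": cm_c, "human": cm_h},
                                                  meta, sim_cfg, truth)
        self.sim_cfg, self.cms, self.meta = sim_cfg, cms, meta
        self.orth, self.truth = orth, truth
        out = self.run_dir / "simulate"
        out.mkdir(parents=True, exist_ok=True)
        synth.truth_summary(truth).to_csv(out / "truth_summary.tsv", sep="\t", index=False)
        self.gene_sets = synth.make_gene_sets(truth, seed=self.seed)
        log.info("simulate: %d cyno + %d human cells",
                 cms["cyno"].n_cells, cms["human"].n_cells)

    def run_qc(self) -> None:
        qc_conf = self.config.get("qc", {})
        cfg = qc.QCConfig(**{k: v for k, v in qc_conf.items()
                             if k in qc.QCConfig.__dataclass_fields__})
        out = self.run_dir / "qc"
        out.mkdir(parents=True, exist_ok=True)
        kept, report_rows = {}, []
        meta = self.meta
        for sp, cm in self.cms.items():
            cm.normalize()
            meta = qc.qc_flags(cm, meta, cfg)
            scores = qc.synthetic_doublet_score(cm, seed=self.seed)
            calls = qc.doublet_calls_from_scores(scores, cfg.expected_doublet_rate)
            vote = qc.doublet_vote([calls], cm.cell_ids, cfg.doublet_vote_k)
            meta = meta.set_index("cell_id")
            meta.loc[vote.index[vote], "doublet"] = True
            meta = meta.reset_index()
            emb = qc.pca_embedding(cm, cfg.n_pcs, seed=self.seed)
            clusters = qc.cluster_graph(emb, cfg.qc_cluster_resolution, seed=self.seed,
                                        k=min(cfg.knn, cm.n_cells - 1))
            sub = meta.set_index("cell_id").loc[list(cm.cell_ids)]
            keep, dcl, lcl = qc.prune_clusters(clusters, sub["doublet"].to_numpy(),
                                               sub["low_quality"].to_numpy(),
                                               cfg.cluster_bad_fraction)
            meta = meta.set_index("cell_id")
            meta.loc[np.asarray(cm.cell_ids)[dcl], "doublet_cluster"] = True
            meta.loc[np.asarray(cm.cell_ids)[lcl], "lowq_cluster"] = True
            meta = meta.reset_index()
            kept[sp] = cm.subset_cells(keep)
            n_doub = int(sub["doublet"].sum())
            report_rows.append({"species": sp, "n_input": cm.n_cells,
                                "n_removed": int((~keep).sum()),
                                "n_doublets_flagged": n_doub,
                                "n_lowq_flagged": int(sub["low_quality"].sum()),
                                "n_kept": int(keep.sum())})
        self.meta = meta
        self.cms = kept
        pd.DataFrame(report_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
        self.qc_report = pd.DataFrame(report_rows)

    def annotate(self) -> None:
        out = self.run_dir / "annotate"
        out.mkdir(parents=True, exist_ok=True)
        cfg = qc.QCConfig()
        meta = self.meta.set_index("cell_id")
        for sp, cm in self.cms.items():
            emb = qc.pca_embedding(cm, cfg.n_pcs, seed=self.seed)
            clusters = qc.cluster_graph(emb, cfg.annot_cluster_resolution, seed=self.seed,
                                        k=min(cfg.knn, cm.n_cells - 1))
            labels = meta.loc[list(cm.cell_ids), "label"]
            refined = qc.majority_annotate(clusters, labels)
            meta.loc[list(cm.cell_ids), "cluster"] = clusters
            meta.loc[list(cm.cell_ids), "label"] = refined
        self.meta = meta.reset_index()
        kept_ids = set()
        for cm in self.cms.values():
            kept_ids |= set(cm.cell_ids)
        kept_meta = self.meta[self.meta["cell_id"].isin(kept_ids)]
        props = qc.proportions_table(kept_meta)
        props.to_csv(out / "proportions.tsv", sep="\t", index=False)
        sex_tabs = [qc.infer_sex(cm, self.meta) for cm in self.cms.values()]
        pd.concat(sex_tabs, ignore_index=True).to_csv(out / "sex_calls.tsv", sep="\t",
                                                      index=False)
        self.proportions = props

    def harmonize(self) -> None:
        out = self.run_dir / "orthology"
        out.mkdir(parents=True, exist_ok=True)
        hc, hh, unified = orthology.harmonize_duplicating(self.cms["cyno"],
                                                          self.cms["human"], self.orth)
        self.harmonized = {"cyno": hc.normalize(), "human": hh.normalize()}
        self.collapsed = {
            "cyno": orthology.collapse_one_to_one(self.cms["cyno"], self.orth).normalize(),
            "human": self.cms["human"].normalize(),
        }
        self.ccc_input = {
            "cyno": orthology.map_sum_by_human(self.cms["cyno"], self.orth).normalize(),
            "human": self.cms["human"],
        }
        report = orthology.mapping_report(self.cms["cyno"], self.orth)
        report.to_csv(out / "mapping_report.tsv", sep="\t", index=False)
        self.mapping_report = report

    # --- optional stages -------------------------------------------------

    def _vae_config(self, n_genes: int) -> VAEConfig:
        vconf = self.config.get("vae", {})
        fields = {k: v for k, v in vconf.items()
                  if k in VAEConfig.__dataclass_fields__}
        if "hidden_sizes" in fields:
            fields["hidden_sizes"] = tuple(fields["hidden_sizes"])
        fields.setdefault("seed", self.seed)
        cfg = VAEConfig(**fields)
        cfg.latent_dim = min(cfg.latent_dim, max(2, n_genes - 1))
        return cfg

    def run_vae(self) -> None:
        out = self.run_dir / "vae"
        out.mkdir(parents=True, exist_ok=True)
        min_cells = int(self.config.get("vae", {}).get("min_cells", 1000))
        hvg_n = int(self.config.get("vae", {}).get("hvg_per_species",
                                                   min(2000, self.harmonized["cyno"].n_genes)))
        hvg = select_hvg(self.harmonized, n_per_species=hvg_n)
        self.hvg = hvg
        sub = {sp: cm.subset_genes(hvg).normalize() for sp, cm in self.harmonized.items()}
        meta = self.meta.set_index("cell_id")

        eval_rows, geom_rows = [], []
        self.models = {}
        cell_types = sorted(set(meta.loc[list(sub["cyno"].cell_ids), "label"])
                            & set(meta.loc[list(sub["human"].cell_ids), "label"]))
        for ct in cell_types:
            ids = {sp: [c for c in cm.cell_ids if meta.at[c, "label"] == ct]
                   for sp, cm in sub.items()}
            n_total = sum(len(v) for v in ids.values())
            if n_total < min_cells:
                log.info("vae: skipping %s (%d cells < %d)", ct, n_total, min_cells)
                continue
            ct_cm = {sp: cm.subset_cells(ids[sp]) for sp, cm in sub.items()}
            ct_meta = meta.loc[ids["cyno"] + ids["human"]].reset_index()

            # humanization evaluation under both split modes
            for mode in ("by_replicate", "random"):
                spec = shifts.SplitSpec(mode=mode, seed=self.seed)
                row = self._evaluate_humanization(ct, ct_cm, ct_meta, spec)
                if row is not None:
                    eval_rows.append(row)

            # full-data model for temporal geometry + downstream importance
            X = np.vstack([ct_cm["cyno"].normalized, ct_cm["human"].normalized])
            res = ExpressionVAE(X, hvg, self._vae_config(len(hvg))).fit()
            self.models[ct] = (res, ct_cm, ct_meta)
            Z = res.encode(X)
            species = np.array(["cyno"] * ct_cm["cyno"].n_cells
                               + ["human"] * ct_cm["human"].n_cells)
            tp = ct_meta.set_index("cell_id").loc[
                list(ct_cm["cyno"].cell_ids) + list(ct_cm["human"].cell_ids),
                "timepoint"].to_numpy()
            for t in ("6h", "24h"):
                try:
                    sh = {s: shifts.compute_shift(
                        Z, (species == s) & (tp == "0h"), (species == s) & (tp == t),
                        kind="temporal", cell_type=ct, from_group="0h", to_group=t)
                        for s in ("human", "cyno")}
                except ValueError:
                    continue
                geom = shifts.vector_geometry(sh["human"], sh["cyno"])
                geom_rows.append({"cell_type": ct, "timepoint": t,
                                  **{k: v for k, v in geom.items()
                                     if not k.endswith("_xy")}})

        self.humanization = pd.DataFrame(eval_rows)
        self.geometry = pd.DataFrame(geom_rows)
        self.humanization.to_csv(out / "humanization_eval.tsv", sep="\t", index=False)
        self.geometry.to_csv(out / "shift_geometry.tsv", sep="\t", index=False)

    def _evaluate_humanization(self, ct, ct_cm, ct_meta, spec) -> dict | None:
        meta_idx = ct_meta.set_index("cell_id")
        try:
            train_ids, test_ids = shifts.split_dataset(ct_meta, spec)
        except ValueError:
            return None
        train_ids, test_ids = set(train_ids), set(test_ids)

        def part(cm, ids):
            sel = [c for c in cm.cell_ids if c in ids]
            return cm.subset_cells(sel) if sel else None

        tr = {sp: part(cm, train_ids) for sp, cm in ct_cm.items()}
        te = {sp: part(cm, test_ids) for sp, cm in ct_cm.items()}
        if any(v is None for v in (*tr.values(), *te.values())):
            return None
        X_train = np.vstack([tr["cyno"].normalized, tr["human"].normalized])
        res = ExpressionVAE(X_train, list(ct_cm["cyno"].gene_ids),
                            self._vae_config(ct_cm["cyno"].n_genes)).fit()

        def at_0h(cm):
            ids = [c for c in cm.cell_ids
                   if meta_idx.at[c, "timepoint"] == "0h"]
            return cm.subset_cells(ids) if ids else None

        tr0 = {sp: at_0h(cm) for sp, cm in tr.items()}
        te0 = {sp: at_0h(cm) for sp, cm in te.items()}
        if any(v is None for v in (*tr0.values(), *te0.values())):
            return None
        Z = {sp: res.encode(cm.normalized) for sp, cm in tr0.items()}
        delta = shifts.ShiftVector(Z["human"].mean(axis=0) - Z["cyno"].mean(axis=0),
                                   kind="species", cell_type=ct,
                                   from_group="cyno@0h", to_group="human@0h")
        humanized = shifts.apply_shift(res, te0["cyno"].normalized, delta)
        rho_raw = shifts.mean_rank_correlation(te0["cyno"].normalized,
                                               te0["human"].normalized)
        rho_hum = shifts.mean_rank_correlation(humanized, te0["human"].normalized)
        return {"cell_type": ct, "split_mode": spec.mode,
                "n_train": X_train.shape[0],
                "n_test": te0["cyno"].n_cells + te0["human"].n_cells,
                "rho_raw": rho_raw, "rho_humanized": rho_hum,
                "improvement": rho_hum - rho_raw,
                "delta_species_magnitude": delta.magnitude}

    def run_importance(self) -> None:
        out = self.run_dir / "importance"
        out.mkdir(parents=True, exist_ok=True)
        if not hasattr(self, "models"):
            self.run_vae()
        if not hasattr(self, "dge_tables"):
            self.run_dge(write=False)
        iconf = self.config.get("importance", {})
        max_cells = int(iconf.get("max_cells", 200))
        alpha = float(iconf.get("alpha", 1.0))
        rng = np.random.default_rng(self.seed)
        rows, corrs = [], []
        self.importances = {}
        for ct, (res, ct_cm, ct_meta) in self.models.items():
            X = np.vstack([ct_cm["cyno"].normalized, ct_cm["human"].normalized])
            species = np.array(["cyno"] * ct_cm["cyno"].n_cells
                               + ["human"] * ct_cm["human"].n_cells)
            if X.shape[0] > max_cells:
                idx = rng.choice(X.shape[0], size=max_cells, replace=False)
                X, species = X[idx], species[idx]
            st = shifts.SpeciesGeneStats.from_matrix(X, species, res.gene_ids)
            imp = shifts.feature_importance(res, X, species, st, alpha=alpha)
            self.importances[ct] = imp
            for (sp, tct, tp), tab in self.dge_tables.items():
                if tct != ct:
                    continue
                # importance lives in the unified space; match on shared names
                try:
                    cmp = shifts.importance_vs_dge(imp, tab)
                except ValueError:
                    continue
                corrs.append(cmp["rho"])
                rows.append({"cell_type": ct, "species": sp, "timepoint": tp, **cmp})
        agg = shifts.sign_aggregate(corrs)
        self.importance_table = pd.DataFrame(rows)
        self.importance_agg = agg
        self.importance_table.to_csv(out / "importance_vs_dge.tsv", sep="\t", index=False)
        (out / "sign_concordance.json").write_text(json.dumps(agg, indent=2),
                                                   encoding="utf-8")

    def run_dge(self, write: bool = True) -> None:
        out = self.run_dir / "dge"
        if write:
            out.mkdir(parents=True, exist_ok=True)
        dconf = self.config.get("dge", {})
        min_cells = int(dconf.get("min_cells", 5))
        fdr_overlap = float(dconf.get("fdr_overlap", 0.20))
        top_n = int(dconf.get("top_n", 200))

        meta = self.meta.set_index("cell_id")
        self.dge_tables = {}
        frac_rows, overlap_rows = [], []
        enr_tables = {}
        for sp, cm in self.collapsed.items():
            ids = list(cm.cell_ids)
            sub = meta.loc[ids]
            eligible = dge_mod.eligible_cell_types(sub.reset_index(), min_cells=min_cells)
            for ct in eligible:
                in_ct = (sub["label"] == ct).to_numpy()
                tp = sub["timepoint"].to_numpy()
                base = in_ct & (tp == "0h")
                for t in ("6h", "24h"):
                    later = in_ct & (tp == t)
                    if base.sum() < min_cells or later.sum() < min_cells:
                        continue
                    keep_genes = dge_mod.filter_genes(cm.counts[in_ct], cm.gene_ids,
                                                      tp[in_ct],
                                                      min_prop=float(dconf.get("min_prop", 0.7)))
                    gm = cm.subset_genes(keep_genes).normalize()
                    tab = dge_mod.dge_test(gm.counts, gm.gene_ids, base, later,
                                           normalized=gm.normalized,
                                           context={"species": sp, "cell_type": ct,
                                                    "comparison": f"0h_vs_{t}"})
                    self.dge_tables[(sp, ct, t)] = tab
                    frac_rows.append({"species": sp, "cell_type": ct, "timepoint": t,
                                      "fraction_regulated":
                                          dge_mod.fraction_regulated(tab["p"])
                                          if len(tab) >= 100 else float("nan")})
                    fg = dge_mod.select_foreground(tab, fdr_cut=fdr_overlap, top_n=top_n)
                    enr = dge_mod.enrich_fisher(set(fg), set(keep_genes),
                                                self.gene_sets)
                    enr_tables[(sp, ct, t)] = enr

        for ct in sorted({k[1] for k in self.dge_tables}):
            for t in ("6h", "24h"):
                kc, kh = ("cyno", ct, t), ("human", ct, t)
                if kc in self.dge_tables and kh in self.dge_tables:
                    # the 1:1 collapse already put mappable cyno genes in human
                    # name space; private genes drop out of the intersection
                    ov = dge_mod.cross_species_overlap(self.dge_tables[kc],
                                                       self.dge_tables[kh],
                                                       fdr_cut=fdr_overlap)
                    overlap_rows.append({"cell_type": ct, "timepoint": t, **ov})

        jac_rows = []
        for ct in sorted({k[1] for k in enr_tables}):
            for t in ("6h", "24h"):
                kc, kh = ("cyno", ct, t), ("human", ct, t)
                if kc in enr_tables and kh in enr_tables:
                    _, summ = dge_mod.co_enrichment_jaccard(enr_tables[kc], enr_tables[kh])
                    jac_rows.append({"cell_type": ct, "timepoint": t, **summ})

        self.dge_fraction = pd.DataFrame(frac_rows)
        self.dge_overlap = pd.DataFrame(overlap_rows)
        self.enrichment = enr_tables
        self.co_enrichment = pd.DataFrame(jac_rows)
        if write:
            pd.concat(self.dge_tables.values(), ignore_index=True).to_csv(
                out / "dge_tables.tsv", sep="\t", index=False)
            self.dge_fraction.to_csv(out / "fraction_regulated.tsv", sep="\t", index=False)
            self.dge_overlap.to_csv(out / "cross_species_overlap.tsv", sep="\t", index=False)
            self.co_enrichment.to_csv(out / "co_enrichment.tsv", sep="\t", index=False)
            if enr_tables:
                pd.concat([t.assign(species=k[0], cell_type=k[1], timepoint=k[2])
                           .assign(hit_genes=lambda d: d["hit_genes"].map(
                               lambda hs: ",".join(hs)))
                           for k, t in enr_tables.items()],
                          ignore_index=True).to_csv(out / "enrichment.tsv", sep="\t",
                                                    index=False)

    def run_ccc(self) -> None:
        out = self.run_dir / "ccc"
        out.mkdir(parents=True, exist_ok=True)
        cconf = self.config.get("ccc", {})
        n_perm = int(cconf.get("n_perm", 1000))
        rank_cut = float(cconf.get("rank_cut", 0.01))
        edge_cut = float(cconf.get("edge_cut", 0.001))
        lr_pairs = synth.lr_database(self.truth, seed=self.seed)
        meta = self.meta.set_index("cell_id")
        tables = {}
        for sp, cm in self.ccc_input.items():
            cm = cm if cm.normalized is not None else cm.normalize()
            sub = meta.loc[list(cm.cell_ids)]
            for t in ("0h", "6h", "24h"):
                sel = (sub["timepoint"] == t).to_numpy()
                if sel.sum() < 20:
                    continue
                tab = ccc_mod.score_interactions(cm.normalized[sel], cm.gene_ids,
                                                 sub["label"].to_numpy()[sel], lr_pairs,
                                                 n_perm=n_perm, seed=self.seed,
                                                 context={"species": sp, "timepoint": t})
                tables[(sp, t)] = tab
        cons_rows = []
        for t in ("0h", "6h", "24h"):
            kc, kh = ("cyno", t), ("human", t)
            if kc in tables and kh in tables:
                sigc = ccc_mod.filter_significant(tables[kc], rank_cut)
                sigh = ccc_mod.filter_significant(tables[kh], rank_cut)
                bg = pd.concat([tables[kc], tables[kh]])[ccc_mod.KEY_COLS].drop_duplicates()
                cons = ccc_mod.conservation_test(sigc, sigh, bg)
                cons_rows.append({"timepoint": t, **cons})
        self.ccc_tables = tables
        self.ccc_conservation = pd.DataFrame(cons_rows)
        if tables:
            pd.concat(tables.values(), ignore_index=True).to_csv(
                out / "lr_scores.tsv", sep="\t", index=False)
        self.ccc_conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)
        nets = []
        for (sp, t), tab in tables.items():
            net = ccc_mod.network_summaries(tab, edge_cut)
            nets.append(net["edges"].assign(species=sp, timepoint=t))
        if nets:
            pd.concat(nets, ignore_index=True).to_csv(out / "network_edges.tsv",
                                                      sep="\t", index=False)


def run_pipeline(config: dict | str | Path | None = None,
                 run_dir: str | Path = "xspecies_run") -> Path:
    """Execute the requested stages; returns the run directory."""
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text(encoding="utf-8"))
    config = _merge(default_config(), config or {})
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(config, indent=2, default=str),
                                         encoding="utf-8")
    run = PipelineRun(config, run_dir)
    stages = config.get("stages", ALL_STAGES)
    run.simulate()
    run.run_qc()
    run.annotate()
    run.harmonize()
    if "vae" in stages:
        run.run_vae()
    if "dge" in stages:
        run.run_dge()
    if "importance" in stages:
        run.run_importance()
    if "ccc" in stages:
        run.run_ccc()
    if "report" in stages:
        write_report(run_dir)
    return run_dir


def write_report(run_dir: str | Path) -> Path:
    """Assemble a plain-text summary from the stage TSVs present."""
    run_dir = Path(run_dir)
    sections = []

    def add(title: str, rel: str, cols: list[str] | None = None) -> None:
        path = run_dir / rel
        if not path.exists():
            sections.append(f"## {title}\n(absent)\n")
            return
        df = pd.read_csv(path, sep="\t")
        if cols:
            df = df[[c for c in cols if c in df.columns]]
        sections.append(f"## {title}\n{df.to_string(index=False)}\n")

    add("QC removal accounting", "qc/qc_report.tsv")
    add("Ortholog mapping", "orthology/mapping_report.tsv")
    add("Cell type proportions", "annotate/proportions.tsv")
    add("Sex inference", "annotate/sex_calls.tsv")
    add("Humanization evaluation", "vae/humanization_eval.tsv")
    add("Temporal shift geometry", "vae/shift_geometry.tsv")
    add("Regulated transcriptome fraction", "dge/fraction_regulated.tsv")
    add("Cross-species DGE overlap", "dge/cross_species_overlap.tsv")
    add("Co-enrichment", "dge/co_enrichment.tsv")
    add("Importance vs DGE", "importance/importance_vs_dge.tsv")
    add("CCC conservation", "ccc/conservation.tsv")
    report = run_dir / "report.md"
    report.write_text("# Pipeline report\n\n" + "\n".join(sections), encoding="utf-8")
    return report
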