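"""End-to-end orchestration: simulate -> prep -> topics -> ordination/tests ->
taxa lasso -> metabolome prep -> outcome models -> engraftment -> crossmap.

``run_pipeline`` executes the enabled stages in dependency order, writes
versioned TSV/JSON artifacts per stage plus a manifest (parameters, seed,
runtime), and returns a machine-readable report aggregating the headline
statistics. A single pipeline seed fans out to per-stage seeds through a
fixed spawn-key scheme, so disabling one stage never shifts another stage's
random stream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import compositions as comp
from . import engraftment as eng
from . import metabolome as metab
from . import multiomics as mo
from . import outcomes as om
from . import topics as tp
from . import zerosum as zs
from .prep import EARLY_POST, SampleMeta, prepare_counts, select_analysis_sample
from .simulate import SimConfig, simulate_all

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    simulate: dict = field(default_factory=dict)
    stages: dict = field(
        default_factory=lambda: {
            "microbiome": True,
            "topics": True,
            "taxa_lasso": True,
            "metabolome": True,
            "engraftment": True,
            "crossmap": True,
        }
    )
    min_reads: int = 1000
    min_rel: float = 0.001
    prevalence_min: float = 0.01
    k_min: int = 2
    k_max: int = 10
    lda_restarts: int = 5
    n_permutations: int = 999
    taxa_runs: int = 100
    taxa_folds: int = 4
    taxa_n_lambda: int = 30
    pseudocount: float = 0.5
    max_undetected: float = 0.25
    rho_max: float = 0.5
    metab_repeats: int = 100
    metab_folds: int = 10
    metab_n_lambda: int = 30
    splsda_repeats: int = 50
    splsda_folds: int = 4
    crossmap_alpha: float = 0.05
    n_taxa: int = 5
    n_metab: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def _stage_seed(cfg: PipelineConfig, idx: int) -> int:
    return int(
        np.random.SeedSequence(cfg.seed, spawn_key=(idx,)).generate_state(1)[0]
        % (2**31 - 1)
    )


def _write(out_dir, name, obj) -> None:
    if out_dir is None:
        return
    path = Path(out_dir)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path / f"{name}.tsv", sep="\t")
    else:
        (path / f"{name}.json").write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages on a simulated dataset; return the report."""
    t0 = time.time()
    report: dict = {"seed": cfg.seed}
    stage_on = cfg.stages

    sim_cfg = SimConfig(**{**cfg.simulate, "seed": _stage_seed(cfg, 0)})
    ds = simulate_all(sim_cfg)
    if cfg.out_dir:
        from .simulate import write_dataset

        write_dataset(ds, Path(cfg.out_dir) / "simulated")
    report["simulate"] = {
        "n_patients": sim_cfg.n_patients,
        "n_fmt": sim_cfg.n_fmt,
        "n_placebo": sim_cfg.n_placebo,
        "n_stool_samples": int(len(ds.meta.table)),
        "n_serum_samples": int(len(ds.serum_meta)),
        "event_rate": float(ds.outcomes.mean()),
    }

    meta = select_analysis_sample(ds.meta)
    asv_table, genus_table = prepare_counts(
        ds.counts, cfg.min_reads, cfg.min_rel, min_samples=2,
        prevalence_min=cfg.prevalence_min,
    )
    mtbl = meta.table.loc[meta.table.index.intersection(asv_table.counts.index)]
    report["prep"] = {
        "n_samples_retained": int(asv_table.counts.shape[0]),
        "n_asvs_retained": int(asv_table.counts.shape[1]),
        "n_genera_retained": int(genus_table.counts.shape[1]),
    }
    if not stage_on.get("microbiome", True):
        return _round_floats(report)

    early_ids = mtbl.index[
        (mtbl["role"] == "patient") & (mtbl["timepoint"] == EARLY_POST)
    ]
    early_ids = early_ids.intersection(genus_table.counts.index)
    early_meta = mtbl.loc[early_ids]

    model = None
    if stage_on.get("topics", True):
        k_star, ktable, fits = tp.select_k(
            genus_table, cfg.k_min, cfg.k_max, seed=_stage_seed(cfg, 1),
            n_restarts=cfg.lda_restarts,
        )
        model = fits[k_star]
        _write(cfg.out_dir, "k_selection", ktable)
        _write(cfg.out_dir, "topic_term", model.topic_term)
        _write(cfg.out_dir, "sample_topics", model.sample_topics)
        abund = tp.cluster_abundances(model)
        clr_ab = comp.clr_transform(abund.clip(lower=1e-6))
        d = comp.aitchison_distance(clr_ab.loc[early_ids])
        perm_arm = comp.permanova(
            d, early_meta["arm"].to_numpy(), cfg.n_permutations,
            seed=_stage_seed(cfg, 2),
        )
        coords, explained = comp.pcoa(d, k=2)
        _write(cfg.out_dir, "pcoa_coordinates", coords)
        groups_out = pd.to_numeric(early_meta["outcome"], errors="coerce").fillna(0).astype(int).to_numpy()
        perm_gvhd = comp.permanova(
            d, groups_out, cfg.n_permutations, seed=_stage_seed(cfg, 3)
        )
        wilcoxon = {}
        for topic in abund.columns:
            _, p_adj = comp.group_compare(
                abund.loc[early_ids, topic].to_numpy(),
                early_meta["arm"].to_numpy(),
                correction="bonferroni",
                m=len(abund.columns),
            )
            wilcoxon[topic] = p_adj
        # heatmap sample grouping: samples clustered on their (per-cluster
        # scaled) topic abundances, cut into three groups
        ward = comp.ward_groups(abund.to_numpy(), n_groups=3, scale="column")
        report["topics"] = {
            "k_star": int(k_star),
            "top_taxa": tp.top_taxa(model, n=cfg.n_taxa),
            "pcoa_explained": [float(v) for v in explained],
            "permanova_arm_p": perm_arm.p_value,
            "permanova_arm_r2": perm_arm.r2,
            "permanova_gvhd_p": perm_gvhd.p_value,
            "wilcoxon_cluster_p_bonferroni": wilcoxon,
            "ward_cluster_sizes": np.bincount(ward).tolist(),
        }

    if stage_on.get("taxa_lasso", True):
        X = zs.logratio_features(
            genus_table.counts.loc[early_ids], pseudocount=cfg.pseudocount
        )
        y = pd.to_numeric(early_meta["outcome"], errors="coerce").fillna(0).astype(int).to_numpy()
        stab = zs.stability_select(
            X, y, n_runs=cfg.taxa_runs, n_folds=cfg.taxa_folds,
            seed=_stage_seed(cfg, 4), n_lambda=cfg.taxa_n_lambda,
        )
        _write(cfg.out_dir, "taxa_stability", stab)
        top = stab.head(5)
        report["taxa_lasso"] = {
            "top_features": [
                {
                    "feature": f,
                    "probability": float(r["selection_probability"]),
                    "sign": r["sign"],
                }
                for f, r in top.iterrows()
            ],
            "planted_genus_probability": float(
                stab.loc[ds.truth.planted_genus, "selection_probability"]
            )
            if ds.truth.planted_genus in stab.index
            else None,
        }

    prepared = None
    serum_early = None
    if stage_on.get("metabolome", True):
        prepared, dropped = metab.prepare_metabolome(
            ds.metabolome, cfg.max_undetected, cfg.rho_max
        )
        # anchor re-runs are QC duplicates; drop them for modeling
        rerun = [t for _, t in ds.metabolome.anchor_pairs]
        vals = prepared.intensities.drop(index=rerun, errors="ignore")
        logstd = metab.log_standardize(
            metab.MetaboliteMatrix(
                vals, prepared.batch.reindex(vals.index), []
            )
        )
        serum_early = ds.serum_meta[ds.serum_meta["timepoint"] == "post28"]
        ids = logstd.index.intersection(serum_early.index)
        se = serum_early.loc[ids]
        ok = se["outcome"].notna()
        se = se[ok]
        Xm = logstd.loc[se.index]
        ym = se["outcome"].astype(int).to_numpy()
        cov = (se["prophylaxis"] == "PTCy").astype(float).rename("PTCy")
        stab_m = om.logistic_lasso_stability(
            Xm, ym, covariate=cov, n_folds=cfg.metab_folds,
            n_repeats=cfg.metab_repeats, seed=_stage_seed(cfg, 5),
            n_lambda=cfg.metab_n_lambda,
        )
        _write(cfg.out_dir, "metabolite_stability", stab_m)
        feats = stab_m[~stab_m["is_covariate"]]
        splsda_model = om.tune_splsda(
            Xm, ym, n_folds=cfg.splsda_folds, n_repeats=cfg.splsda_repeats,
            seed=_stage_seed(cfg, 6),
        )
        pca_sc, pca_expl = om.pca_scores(logstd, k=2)
        _write(cfg.out_dir, "pca_scores", pca_sc)
        report["metabolome"] = {
            "n_metabolites_retained": int(prepared.intensities.shape[1]),
            "n_dropped_collinear": len(dropped),
            "n_early_post_serum": int(len(se)),
            "top_metabolite": feats.index[0],
            "top_metabolite_probability": float(
                feats["selection_probability"].iloc[0]
            ),
            "top_metabolite_sign": feats["sign"].iloc[0],
            "planted_metabolite_probability": float(
                feats.loc[ds.truth.planted_metabolite, "selection_probability"]
            )
            if ds.truth.planted_metabolite in feats.index
            else None,
            "splsda_best_ber": float(splsda_model.ber_by_config["mean_ber"].min()),
            "splsda_n_components": splsda_model.n_components,
            "pca_explained": [float(v) for v in pca_expl],
        }
        serum_early = se
        prepared_logstd = logstd

    if stage_on.get("engraftment", True):
        rec, summary = eng.engraftment_analysis(
            asv_table, SampleMeta(mtbl), genus=sim_cfg.planted_genus
        )
        _write(cfg.out_dir, "engraftment_records", rec)
        report["engraftment"] = summary

    if stage_on.get("crossmap", True) and model is not None and prepared is not None:
        taxa, mets = mo.select_features(
            model,
            genus_table.counts,
            prepared.intensities.drop(
                index=[t for _, t in ds.metabolome.anchor_pairs], errors="ignore"
            ),
            n_taxa=cfg.n_taxa,
            n_metab=cfg.n_metab,
            pinned_metabolites=(
                [ds.truth.planted_metabolite]
                if ds.truth.planted_metabolite in prepared_logstd.columns
                else []
            ),
        )
        rowfeat = mo.taxa_cluster_features(
            genus_table.counts.loc[early_ids], model, taxa,
            pseudocount=cfg.pseudocount,
        )
        # pair stool and serum by patient at the early-post timepoint
        stool_pat = mtbl.loc[rowfeat.index.intersection(mtbl.index), "patient_id"]
        rows_by_pat = rowfeat.loc[stool_pat.index].set_axis(stool_pat.to_numpy())
        serum_pat = serum_early["patient_id"]
        cols_by_pat = prepared_logstd.loc[serum_early.index, mets].set_axis(
            serum_pat.to_numpy()
        )
        shared = rows_by_pat.index.intersection(cols_by_pat.index)
        log.info("crossmap pairing: %d patients with both compartments", len(shared))
        cmap = mo.cross_correlate(rows_by_pat, cols_by_pat, alpha=cfg.crossmap_alpha)
        _write(cfg.out_dir, "crossmap_rho", cmap.rho)
        _write(cfg.out_dir, "crossmap_p", cmap.p)
        flat = cmap.rho.where(cmap.mask).stack()
        extremes = {}
        if len(flat):
            imax, imin = flat.idxmax(), flat.idxmin()
            extremes = {
                "max_rho": {"pair": list(imax), "rho": float(flat.max())},
                "min_rho": {"pair": list(imin), "rho": float(flat.min())},
            }
        report["crossmap"] = {
            "n_taxa_features": len(taxa),
            "n_metabolite_features": len(mets),
            "n_paired_patients": int(cmap.n_pairs),
            "n_significant": int(cmap.mask.to_numpy().sum()),
            **extremes,
        }

    # runtime goes in the manifest, never the report: the report must be
    # byte-identical across reruns of the same config and seed
    if cfg.out_dir:
        manifest = {"config": asdict(cfg), "runtime_s": round(time.time() - t0, 2)}
        _write(cfg.out_dir, "manifest", manifest)
        _write(cfg.out_dir, "report", _round_floats(report))
    return _round_floats(report)


def _round_floats(obj, digits: int = 10):
    """Round floats for byte-stable report serialization."""
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, float):
        return round(obj, digits)
    return obj
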