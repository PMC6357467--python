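"""Config-driven orchestration of the full methylome analysis.

Stages run in order: matrix assembly (from files or an inline synthetic
cohort) -> pairwise DMR calling -> disease-specific consensus -> region
statistics and covariate screens -> annotation-set enrichment ->
nearest-gene annotation and drug-target enrichment -> phenotype
classifier. Every stage writes plain files (BED/TSV/JSON) into the run
directory and the run ends with a machine-readable ``summary.json``. All
randomness derives from the single config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, consensus, enrichment, annotation, simulate, stats
from .calling import DMRCallingParams, call_dmrs, dmrs_to_bed_frame, region_sample_methylation
from .classify import predict_and_evaluate, train_phenotype_classifier
from .io import build_methylation_matrix, read_bed, read_sample_sheet, write_bed
from .regions import RegionSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict | str | Path) -> list[str]:
    """Return a list of problems (empty means the config is usable)."""
    if not isinstance(config, dict):
        config = load_config(config)
    errors: list[str] = []
    if "seed" not in config:
        errors.append("missing 'seed'")
    has_sim = "simulate" in config
    sheet_path = config.get("matrix", {}).get("sample_sheet")
    if not has_sim and not sheet_path:
        errors.append("need either a 'simulate' block or matrix.sample_sheet")
    if sheet_path and not Path(sheet_path).exists():
        errors.append(f"sample sheet not found: {sheet_path}")
    for key in ("gene_models", "drug_table"):
        p = config.get("annotation", {}).get(key)
        if p and not Path(p).exists():
            errors.append(f"annotation.{key} not found: {p}")
    cdir = config.get("enrichment", {}).get("collection_dir")
    if cdir and not Path(cdir).is_dir():
        errors.append(f"enrichment.collection_dir not found: {cdir}")
    comparisons = config.get("dmr_calling", {}).get("comparisons", [])
    known = {"HC", "DC", "WD", "WDH", "WDN"}
    for pair in comparisons:
        if len(pair) != 2:
            errors.append(f"comparison {pair!r} must name two groups")
        else:
            for g in pair:
                if g not in known:
                    errors.append(f"unknown group label {g!r} in comparisons")
    return errors


def _build_params(cfg: dict, seed: int) -> DMRCallingParams:
    return DMRCallingParams(
        cutoff=cfg.get("cutoff", 0.10),
        min_cpgs=cfg.get("min_cpgs", 5),
        max_gap=cfg.get("max_gap", 1000),
        window_bp=cfg.get("window_bp", 500),
        n_perm=cfg.get("n_perm", 1000),
        seed=seed,
    )


def _simulate_inputs(sim_cfg: dict, seed: int, outdir: Path):
    planted = [simulate.PlantedDMR(**p) for p in sim_cfg.get("planted_dmrs", [])]
    config = simulate.SimulationConfig(
        seed=seed,
        chromosomes=[tuple(c) for c in sim_cfg.get("chromosomes", simulate.DEFAULT_CHROMOSOMES)],
        cpg_island_fraction=sim_cfg.get("cpg_island_fraction", 0.2),
        mean_cpg_spacing=sim_cfg.get("mean_cpg_spacing", 200),
        mean_coverage=sim_cfg.get("mean_coverage", 8.0),
        coverage_dispersion=sim_cfg.get("coverage_dispersion", 3.0),
        beta_precision=sim_cfg.get("beta_precision", 30.0),
        n_per_group=dict(sim_cfg.get("n_per_group", {"WD": 10, "HC": 10})),
        planted_dmrs=planted,
        confounded_fibrosis=sim_cfg.get("confounded_fibrosis", False),
    )
    landscape = simulate.simulate_cpg_landscape(config)
    truth = simulate.plant_dmr_truth(landscape, planted)
    cohort = simulate.simulate_cohort(landscape, truth, config)
    annotations, tss, drugs = simulate.simulate_region_annotations(
        landscape, truth, config,
        enrichment_factor=sim_cfg.get("enrichment_factor", 10.0),
        base_rate=sim_cfg.get("annotation_base_rate", 0.2),
    )
    truth.to_json(outdir / "truth.json")
    return cohort, truth, annotations, tss, drugs


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages; returns the summary dict.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"] if seed is None else seed)
    summary: dict = {"seed": seed, "stages": []}

    annotations = tss = drugs = None
    try:
        if "simulate" in config:
            cohort, truth, annotations, tss, drugs = _simulate_inputs(
                config["simulate"], seed, outdir
            )
            matrix, sheet = cohort.matrix, cohort.sample_sheet
        else:
            sheet = read_sample_sheet(config["matrix"]["sample_sheet"])
            matrix = build_methylation_matrix(
                sheet,
                min_coverage=config.get("matrix", {}).get("min_coverage", 1),
                min_fraction=config.get("matrix", {}).get("min_fraction", 1.0),
            )
        summary["n_cpgs"] = int(matrix.n_cpgs)
        summary["n_samples"] = int(matrix.n_samples)
        summary["stages"].append("matrix")
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError("matrix", exc) from exc

    dmr_cfg = config.get("dmr_calling", {})
    comparisons = [tuple(p) for p in dmr_cfg.get("comparisons", [])]
    results: dict[str, calling.DMRResult] = {}
    try:
        for i, (ga, gb) in enumerate(comparisons):
            params = _build_params(dmr_cfg, seed + 11 + i)
            label_col = "phenotype" if ga in ("WDH", "WDN") else "group"
            res = call_dmrs(matrix, sheet, ga, gb, params, label_column=label_col)
            key = f"{ga}_vs_{gb}"
            results[key] = res
            bed = dmrs_to_bed_frame(res.candidates)
            if len(bed):
                write_bed(RegionSet(bed, name=key), outdir / f"dmrs_{key}.bed")
            counts = res.candidates["direction"].value_counts()
            summary[f"dmrs_{key}"] = {
                "candidates": int(len(res.candidates)),
                "hyper": int(counts.get("hyper", 0)),
                "hypo": int(counts.get("hypo", 0)),
                "fwer_significant": int((res.candidates["fwer"] < 0.05).sum()),
            }
        summary["stages"].append("dmr_calling")
    except Exception as exc:
        raise PipelineError("dmr_calling", exc) from exc

    cons_cfg = config.get("consensus")
    cons_df = None
    if cons_cfg:
        try:
            anchor = results[cons_cfg["anchor"]]
            require = results[cons_cfg["require"]]
            exclude = results[cons_cfg["exclude"]]
            alpha = cons_cfg.get("alpha", 0.05)
            criterion = cons_cfg.get("criterion", "q")
            cons_df = consensus.wd_specific_consensus(
                anchor.significant(alpha, criterion),
                require.significant(alpha, criterion),
                exclude.significant(alpha, criterion),
            )
            background = consensus.consensus_background(anchor.candidates, cons_df)
            counts = cons_df["direction"].value_counts()
            summary["consensus"] = {
                "n": int(len(cons_df)),
                "hyper": int(counts.get("hyper", 0)),
                "hypo": int(counts.get("hypo", 0)),
                "fwer_significant": int((cons_df["fwer"] < 0.05).sum()),
                "background_n": int(len(background)),
            }
            if len(cons_df):
                write_bed(RegionSet(dmrs_to_bed_frame(cons_df)), outdir / "consensus_dmrs.bed")
            summary["stages"].append("consensus")
        except Exception as exc:
            raise PipelineError("consensus", exc) from exc
    else:
        background = None

    stats_cfg = config.get("statistics")
    if stats_cfg is not None and cons_df is not None and len(cons_df) >= 2:
        try:
            table = region_sample_methylation(matrix, RegionSet(cons_df))
            centered = stats.center_by_region(table)
            centered.to_csv(outdir / "consensus_methylation_centered.tsv", sep="\t")
            scores, varexp, _ = stats.principal_components(centered)
            covs = [c for c in stats_cfg.get("covariates", []) if c in sheet.columns]
            assoc = (
                stats.covariate_association(scores[["PC1"]].T, sheet, covs)
                if covs
                else pd.DataFrame()
            )
            if len(assoc):
                assoc.to_csv(outdir / "pc1_covariate_association.tsv", sep="\t", index=False)
            summary["statistics"] = {
                "pc1_variance_explained": float(varexp[0]),
                "pc1_covariates_tested": list(assoc["covariate"]) if len(assoc) else [],
            }
            summary["stages"].append("statistics")
        except Exception as exc:
            raise PipelineError("statistics", exc) from exc

    enr_cfg = config.get("enrichment")
    if (enr_cfg is not None and cons_df is not None and len(cons_df)
            and background is not None and len(background)):
        try:
            if annotations is None:
                cdir = Path(enr_cfg["collection_dir"])
                annotations = {p.stem: read_bed(p) for p in sorted(cdir.glob("*.bed"))}
            panel = enrichment.enrichment_panel(
                RegionSet(cons_df, name="consensus"),
                RegionSet(background, name="background"),
                annotations,
            )
            panel.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            top = panel.iloc[0]
            summary["enrichment"] = {
                "n_annotations": int(len(panel)),
                "top_annotation": str(top["annotation"]),
                "top_odds_ratio": float(top["odds_ratio"]),
                "top_q": float(top["q"]),
            }
            summary["stages"].append("enrichment")
        except Exception as exc:
            raise PipelineError("enrichment", exc) from exc

    ann_cfg = config.get("annotation")
    if ann_cfg is not None and cons_df is not None and len(cons_df):
        try:
            if tss is None:
                tss = annotation.read_gene_models(ann_cfg["gene_models"])
            if drugs is None and ann_cfg.get("drug_table"):
                drugs = pd.read_csv(ann_cfg["drug_table"], sep="\t")
            assignments = annotation.nearest_genes(cons_df, tss, k=ann_cfg.get("k", 2))
            assignments.to_csv(outdir / "dmr_genes.tsv", sep="\t", index=False)
            summary["annotation"] = {"n_assignments": int(len(assignments))}
            if drugs is not None:
                dmr_genes = set(assignments["gene"])
                drug_res = annotation.drug_interaction_enrichment(
                    dmr_genes, drugs, set(tss["gene"])
                )
                drug_res.to_csv(outdir / "drug_enrichment.tsv", sep="\t", index=False)
                if len(drug_res):
                    summary["annotation"]["top_drug"] = str(drug_res.iloc[0]["drug"])
                    summary["annotation"]["top_drug_p"] = float(drug_res.iloc[0]["p"])
            summary["stages"].append("annotation")
        except Exception as exc:
            raise PipelineError("annotation", exc) from exc

    clf_cfg = config.get("classifier")
    if clf_cfg:
        try:
            sim = clf_cfg.get("simulate", {})
            table, labels, test_table, test_labels = simulate.simulate_phenotype_cohorts(
                n_regions=sim.get("n_regions", 2860),
                n_informative=sim.get("n_informative", 44),
                delta=sim.get("delta", 0.2),
                n_train_per_class=sim.get("n_per_class"),
                n_test_per_class=sim.get("n_test_per_class"),
                seed=seed + 101,
            )
            model = train_phenotype_classifier(
                table, labels,
                rounds=clf_cfg.get("rounds", 100),
                learning_rate=clf_cfg.get("learning_rate", 1.0),
                seed=seed + 103,
            )
            model.to_json(outdir / "phenotype_model.json")
            report = predict_and_evaluate(model, test_table, test_labels)
            report.predictions.to_csv(outdir / "phenotype_predictions.tsv", sep="\t", index=False)
            summary["classifier"] = {
                "n_features": len(model.feature_ids),
                "n_selected": len(model.selected_ids),
                "precision_micro": float(report.precision_micro),
                "roc_auc": float(report.roc_auc),
            }
            summary["stages"].append("classifier")
        except Exception as exc:
            raise PipelineError("classifier", exc) from exc

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline finished: %s", summary_path)
    return summary
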