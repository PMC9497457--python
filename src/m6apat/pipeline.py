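"""End-to-end orchestration of the analysis stages with a run manifest.

Stage order: simulate -> preprocess (batch correction) -> diagnose
(screen + LASSO + multivariate model) -> cluster (consensus patterns) ->
enrich (ssGSEA immune profiling) -> lncrna (correlation-selected lncRNAs,
second diagnostic model, lncRNA clusters) -> modules (co-expression) ->
score (m6Ascore, splits, cross-tabulation).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalogs import load_combined_catalog, load_m6a_catalog
from .consensus import select_k_and_label
from .coexpression import detect_modules
from .diagnostics import (
    fit_multivariate_logistic,
    hosmer_lemeshow,
    lasso_logistic_cv,
    univariate_logistic_screen,
)
from .enrichment import group_difference_report, ssgsea_scores, write_gmt
from .io_preprocess import correct_batches, write_annotation, write_expression
from .lncrna import intersect_link_sets, select_related_lncrnas
from .score import compare_scores_across, compute_m6ascore, crosstab_alluvial, split_by_score
from .stats import moderated_t_deg
from .synthetic import SimulationConfig, make_fixture_genesets, simulate_cohort

REQUIRED_BLOCKS = (
    "simulate", "preprocess", "diagnose", "cluster", "enrich", "lncrna",
    "modules", "score",
)


def default_config() -> dict:
    """A demo configuration small enough to run in seconds."""
    return {
        "simulate": {"n_cases": 120, "n_controls": 60, "n_genes": 1200,
                     "n_lncrnas": 60, "n_batches": 3, "immune_set_size": 10,
                     "noise_sd": 1.0},
        "preprocess": {},
        "diagnose": {"n_folds": 10},
        "cluster": {"n_reps": 150, "k_min": 2, "k_max": 5, "p_item": 0.5},
        "enrich": {},
        "lncrna": {},
        "modules": {"top_variance_frac": 0.25, "min_module_size": 20, "power": 6},
        "score": {"split_rule": "median"},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def validate_config(config: dict) -> None:
    for block in REQUIRED_BLOCKS:
        if block not in config:
            raise ValueError(f"config is missing required block {block!r}")


def run_pipeline(config: dict, outdir, seed: int = 0) -> dict:
    """Execute every stage; write all stage outputs and a run manifest."""
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "checksums": {},
    }
    outputs: dict[str, Path] = {}

    def _stage(name):
        manifest["stages"][name] = {"status": "ok"}

    def _write(name: str, path: Path):
        outputs[name] = path

    try:
        # --- simulate -----------------------------------------------------
        sim_cfg = SimulationConfig(**{**config["simulate"], "seed": seed})
        expr, annotation, truth = simulate_cohort(sim_cfg)
        genesets = make_fixture_genesets(sim_cfg, truth)
        write_expression(expr, outdir / "expression_raw.tsv")
        write_annotation(annotation, outdir / "annotation.tsv")
        truth.to_json(outdir / "ground_truth.json")
        write_gmt(genesets, outdir / "immune_sets.gmt")
        for n in ("expression_raw.tsv", "annotation.tsv", "ground_truth.json",
                  "immune_sets.gmt"):
            _write(n, outdir / n)
        _stage("simulate")

        # --- preprocess ---------------------------------------------------
        corrected = correct_batches(expr, annotation)
        write_expression(corrected, outdir / "expression_corrected.tsv")
        _write("expression_corrected.tsv", outdir / "expression_corrected.tsv")
        _stage("preprocess")

        catalog = load_combined_catalog()
        m6a_genes = [g for g in load_m6a_catalog().genes() if g in corrected.index]
        groups = annotation["group"]

        # --- diagnose -----------------------------------------------------
        diag_cfg = config["diagnose"]
        reg_expr = corrected.loc[m6a_genes]
        kept, screen_table = univariate_logistic_screen(reg_expr, groups)
        lasso = lasso_logistic_cv(
            reg_expr.loc[kept] if kept else reg_expr, groups,
            n_folds=diag_cfg.get("n_folds", 10), seed=seed,
        )
        features = lasso.selected or kept[:1]
        model = fit_multivariate_logistic(corrected, groups, features)
        hl = hosmer_lemeshow(model.predict_proba(corrected).to_numpy(),
                             (groups == "case").to_numpy(dtype=float))
        model.lambda_min = lasso.lambda_min
        model.seed = seed
        model.to_json(outdir / "diagnostic_model_m6a.json")
        screen_table.to_csv(outdir / "univariate_screen.tsv", sep="\t")
        manifest["stages"]["diagnose"] = {
            "status": "ok",
            "n_screened": len(kept),
            "n_selected": len(features),
            "auc": model.auc.auc,
            "hosmer_lemeshow_p": hl.p_value,
        }
        for n in ("diagnostic_model_m6a.json", "univariate_screen.tsv"):
            _write(n, outdir / n)

        # --- cluster ------------------------------------------------------
        cl_cfg = config["cluster"]
        cases = annotation.index[groups == "case"]
        cons = select_k_and_label(
            corrected.loc[m6a_genes, cases],
            k_range=range(cl_cfg.get("k_min", 2), cl_cfg.get("k_max", 5) + 1),
            n_reps=cl_cfg.get("n_reps", 1000),
            p_item=cl_cfg.get("p_item", 0.8),
            seed=seed,
        )
        annotation = annotation.copy()
        annotation["pattern_called"] = ""
        annotation.loc[cases, "pattern_called"] = [
            chr(ord("A") + l - 1) for l in cons.labels
        ]
        pd.DataFrame({"k": cons.k_range, "pac": [cons.pac[k] for k in cons.k_range]}).to_csv(
            outdir / "consensus_pac.tsv", sep="\t", index=False
        )
        manifest["stages"]["cluster"] = {
            "status": "ok", "chosen_k": cons.chosen_k,
            "low_confidence": cons.low_confidence,
        }
        _write("consensus_pac.tsv", outdir / "consensus_pac.tsv")

        # --- enrich -------------------------------------------------------
        scores = ssgsea_scores(corrected, genesets)
        scores.to_csv(outdir / "ssgsea_scores.tsv", sep="\t")
        case_scores = scores.loc[:, cases]
        report = group_difference_report(
            case_scores, annotation.loc[cases, "pattern_called"], family="immune-by-pattern"
        )
        report.to_csv(outdir / "immune_pattern_report.tsv", sep="\t")
        _stage("enrich")
        for n in ("ssgsea_scores.tsv", "immune_pattern_report.tsv"):
            _write(n, outdir / n)

        # --- lncrna -------------------------------------------------------
        lnc_ids = [g for g in corrected.index if g.startswith("LNC")]
        m6a_links = select_related_lncrnas(corrected, lnc_ids, catalog, "m6A")
        m5c_links = select_related_lncrnas(corrected, lnc_ids, catalog, "m5C")
        dual = intersect_link_sets(m6a_links, m5c_links)
        m6a_links.to_frame().to_csv(outdir / "lncrna_links_m6a.tsv", sep="\t", index=False)
        m5c_links.to_frame().to_csv(outdir / "lncrna_links_m5c.tsv", sep="\t", index=False)
        (outdir / "lncrna_dual.txt").write_text("\n".join(dual) + "\n")
        manifest["stages"]["lncrna"] = {
            "status": "ok", "n_m6a": len(m6a_links.links),
            "n_m5c": len(m5c_links.links), "n_dual": len(dual),
        }
        lnc_model_path = None
        if len(dual) >= 2:
            lasso2 = lasso_logistic_cv(corrected.loc[dual], groups, seed=seed)
            if lasso2.selected:
                model2 = fit_multivariate_logistic(corrected, groups, lasso2.selected)
                model2.to_json(outdir / "diagnostic_model_lncrna.json")
                lnc_model_path = outdir / "diagnostic_model_lncrna.json"
                _write("diagnostic_model_lncrna.json", lnc_model_path)
        for n in ("lncrna_links_m6a.tsv", "lncrna_links_m5c.tsv", "lncrna_dual.txt"):
            _write(n, outdir / n)

        # --- modules ------------------------------------------------------
        mod_cfg = config["modules"]
        pat = annotation.loc[cases, "pattern_called"]
        deg_union: set[str] = set()
        lvls = sorted(pat.unique())
        for i, a in enumerate(lvls):
            for b in lvls[i + 1:]:
                sub = pat[pat.isin([a, b])]
                if (sub == a).sum() < 2 or (sub == b).sum() < 2:
                    continue
                deg = moderated_t_deg(corrected.loc[:, sub.index], sub)
                deg_union |= set(deg.index[deg["deg"]])
        traits = pd.get_dummies(pat).astype(float)
        modules = detect_modules(
            corrected.loc[:, cases],
            traits=traits,
            top_variance_frac=mod_cfg.get("top_variance_frac", 0.25),
            min_module_size=mod_cfg.get("min_module_size", 30),
            power=mod_cfg.get("power"),
        )
        modules.module_of_gene.to_csv(outdir / "modules.tsv", sep="\t")
        if modules.module_trait is not None:
            modules.module_trait.to_csv(outdir / "module_trait.tsv", sep="\t", index=False)
            _write("module_trait.tsv", outdir / "module_trait.tsv")
        manifest["stages"]["modules"] = {
            "status": "ok", "n_pattern_genes": len(deg_union),
            "n_modules": int(modules.module_of_gene.max()), "power": modules.power,
        }
        _write("modules.tsv", outdir / "modules.tsv")

        # --- score --------------------------------------------------------
        sc_cfg = config["score"]
        signature = sorted(deg_union) if len(deg_union) >= 2 else m6a_genes
        score_table = compute_m6ascore(corrected.loc[:, cases], signature)
        split_by_score(score_table, rule=sc_cfg.get("split_rule", "median"))
        annotation["score_group"] = ""
        annotation.loc[cases, "score_group"] = score_table.table["score_group"]
        comparison = compare_scores_across(pat, score_table)
        score_table.table.to_csv(outdir / "m6ascore.tsv", sep="\t")
        crosstab = crosstab_alluvial(
            annotation.loc[cases], columns=["subtype", "pattern_called", "score_group"]
        )
        crosstab.to_csv(outdir / "alluvial_crosstab.tsv", sep="\t", index=False)
        write_annotation(annotation, outdir / "annotation_final.tsv")
        manifest["stages"]["score"] = {
            "status": "ok",
            "omnibus_p": comparison["omnibus"].p_value,
            "n_signature_genes": len(signature),
        }
        for n in ("m6ascore.tsv", "alluvial_crosstab.tsv", "annotation_final.tsv"):
            _write(n, outdir / n)
    except Exception as exc:
        stage = next(
            (s for s in REQUIRED_BLOCKS if s not in manifest["stages"]), "unknown"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["checksums"] = {name: _sha256(p) for name, p in sorted(outputs.items())}
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return manifest


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
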