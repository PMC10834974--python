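"""End-to-end pipeline: simulate/load -> PCA -> age-adjust -> ratios -> screen
-> classifiers -> consensus panel, with every intermediate written as
delimited text and a machine-readable run report."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age_adjust import apply_correction, fit_age_correction
from .io import read_table, write_ground_truth, write_table
from .models import default_model_specs, run_all
from .panel import panel_class_map
from .screen import (DEFAULT_RATIOS, RatioDefinition, derive_ratios,
                     pca_overview, results_frame, screen)
from .simulate import CohortConfig, build_default_panel, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "input": None,            # path to a table, or None to simulate
    "simulate": {"n_control": 36, "n_case": 76, "seed": 0,
                 "affected_metabolites": None},  # None -> panel default
    "stratum_width": 5.0,
    "reference_age": "auto",
    "min_stratum_size": 2,
    "p_thresh": 0.05,
    "auc_thresh": 0.65,
    "ratios": None,           # None -> Fisher + GSG
    "cv_folds": 5,
    "seed": 0,
    "tune": True,
    "min_models": 3,
    "top_k": 15,
    "outdir": "metabodx_run",
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Merge the default config, an optional YAML file, and keyword overrides."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if k not in cfg:
                raise KeyError(f"unknown configuration key {k!r}")
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in overrides.items():
        if v is not None:
            cfg[k] = v
    return cfg


def _ratio_definitions(cfg: dict) -> tuple[RatioDefinition, ...]:
    if cfg.get("ratios") is None:
        return DEFAULT_RATIOS
    return tuple(
        RatioDefinition(r["name"], tuple(r["numerator"]), tuple(r["denominator"]))
        for r in cfg["ratios"]
    )


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns the run report (also written to report.yaml)."""
    cfg = config
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # --- input ---
    if cfg.get("input"):
        table = read_table(cfg["input"])
        source = str(cfg["input"])
    else:
        sim = cfg["simulate"]
        affected = sim.get("affected_metabolites")
        kwargs = {"n_control": sim["n_control"], "n_case": sim["n_case"],
                  "seed": sim["seed"]}
        if affected is not None:
            kwargs["affected_metabolites"] = frozenset(affected)
        cohort_cfg = CohortConfig(**kwargs)
        table, gt = generate_cohort(cohort_cfg, build_default_panel())
        write_table(table, outdir / "cohort.csv")
        write_ground_truth(gt, outdir / "ground_truth.yaml")
        source = "simulated"

    # --- PCA overview (flags only, never removes) ---
    scores, flags = pca_overview(table)
    scores.to_csv(outdir / "pca_scores.csv", index=False)
    if flags.any():
        warnings_log.append(f"PCA flagged {int(flags.sum())} potential outlier(s)")

    # --- age adjustment ---
    model = fit_age_correction(
        table, stratum_width=cfg["stratum_width"],
        reference_age=cfg["reference_age"],
        min_stratum_size=cfg["min_stratum_size"],
    )
    warnings_log.extend(model.warnings_)
    adjusted = apply_correction(table, model)
    model.to_frame().to_csv(outdir / "age_model.csv", index=False)
    write_table(adjusted, outdir / "adjusted.csv")

    # --- ratios + univariate screen ---
    ratios = _ratio_definitions(cfg)
    adjusted_r = derive_ratios(adjusted, ratios)
    raw_r = derive_ratios(table, ratios)
    results = screen(
        adjusted_r, p_thresh=cfg["p_thresh"], auc_thresh=cfg["auc_thresh"],
        class_map=panel_class_map(), raw_table=raw_r,
    )
    res_df = results_frame(results)
    res_df.to_csv(outdir / "screen_results.csv", index=False)
    bubble = res_df[["metabolite", "class_label", "log2fc", "p_value"]].dropna()
    bubble.to_csv(outdir / "bubble.csv", index=False)

    # --- classifiers + consensus ---
    report_models = run_all(
        adjusted_r, results, specs=default_model_specs(seed=cfg["seed"],
                                                       cv_folds=cfg["cv_folds"]),
        seed=cfg["seed"], top_k=cfg["top_k"], min_models=cfg["min_models"],
        tune=cfg["tune"],
    )
    metrics_df = pd.DataFrame([ev.metrics_row() for ev in
                               report_models["evaluations"].values()])
    metrics_df.to_csv(outdir / "model_metrics.csv", index=False)
    for alg, ev in report_models["evaluations"].items():
        pd.DataFrame(ev.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{alg}.csv", index=False)
    panel_df = pd.DataFrame(report_models["consensus_panel"])
    panel_df.to_csv(outdir / "consensus_panel.csv", index=False)

    report = {
        "version": __version__,
        "config": _yaml_safe(cfg),
        "input": source,
        "n_subjects": int(len(table)),
        "n_metabolites": int(len(model.coefficients)),
        "pca_outliers": int(flags.sum()),
        "reference_age": model.reference_age,
        "metabolites_corrected": int(model.coefficients["slope"].notna().sum()),
        "screen_pass_count": int(res_df["passes_filter"].sum()),
        "model_metrics": metrics_df.to_dict(orient="records"),
        "consensus_panel": [r["feature"] for r in report_models["consensus_panel"]],
        "warnings": warnings_log,
    }
    (outdir / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    return report


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]
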