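"""End-to-end orchestration: characterize -> cluster -> classify subsets ->
fit per-subset region models -> predict -> roll up -> evaluate.

``run_full_pipeline`` drives every stage from a single config dict (load it
from YAML/JSON or build it in code) and returns a machine-readable report.
All randomness flows from the single ``seed`` entry, so a config+seed pair
reproduces the report byte for byte.

Config keys (all optional unless noted)::

    seed: int                      master seed (default 0)
    simulate:                      generate a synthetic cohort
        n_subjects: [67, 86, 42]
        n_regions: 116             or preset: "aal-like" / "bundled"
        n_features: 241
        effect_size: 2.0
        missingness: 0.05
    inputs:                        or load CSVs instead of simulating
        lesion_table: path         wide CSV, subject_id + one column/region
        features: path             wide CSV, empty cells = missing
        atlas: path                registry CSV
    method: "none"                 region-model variant {none, l1, l2}
    region_config:                 overrides for FitConfig (resamples, ...)
    subset_classifier:             n_resamples, grid, alpha, ...
    levels: ["level2", "level1"]   coarse resolutions to evaluate
    per_subset: true               also fit within predicted subsets
    out: path                      if set, write report.json there
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_distance_matrix, default_atlas, load_atlas, rollup_map
from .categorization import cluster_subjects
from .evaluation_stats import (
    cv_correlation,
    evaluate_predictions,
    wilcoxon_rank_sum,
)
from .lesion_metrics import characterize_cohort
from .region_models import FitConfig, fit_all_regions
from .resolution_transfer import direct_fit_at_level, rollup_predictions
from .subset_classifier import fit_subset_pipeline, multiclass_mcc, predict_subset
from .synthetic_data import CohortSpec, generate_atlas, generate_cohort, generate_features

__all__ = ["run_full_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline config."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _round(obj, nd=10):
    """Recursively round floats so report serialization is stable."""
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _perf_summary(perf: pd.DataFrame) -> dict:
    """Median region-wise metrics (undefined ratios excluded, not zeroed)."""
    out = {"n_regions": int(len(perf))}
    for m in ("accuracy", "specificity", "sensitivity"):
        vals = perf[m].dropna()
        out[f"median_{m}"] = float(vals.median()) if len(vals) else None
    if len(perf):
        out["fisher_significant_fraction"] = float((perf["fisher_p"] < 0.05).mean())
    return out


def _build_data(config: dict):
    seed = int(config.get("seed", 0))
    if "inputs" in config:
        inp = config["inputs"]
        atlas = load_atlas(inp["atlas"]) if "atlas" in inp else default_atlas()
        lesion = pd.read_csv(inp["lesion_table"], index_col=0)
        lesion.columns = [int(c) for c in lesion.columns]
        features = pd.read_csv(inp["features"], index_col=0)
        return atlas, lesion, features, None, None
    sim = dict(config.get("simulate", {}))
    preset = sim.pop("preset", None)
    if preset == "bundled":
        atlas = default_atlas()
    else:
        atlas = generate_atlas(
            n_regions=int(sim.pop("n_regions", 116)), seed=seed, preset=preset
        )
    spec_kwargs = {}
    for key in (
        "n_subjects", "region_count_ranges", "clustering_scales",
        "single_lesion_fraction", "n_features", "n_informative_per_region",
        "effect_size", "missingness",
    ):
        if key in sim:
            val = sim[key]
            spec_kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val) if isinstance(val, list) else val
    spec = CohortSpec(seed=seed, **spec_kwargs)
    lesion, truth = generate_cohort(spec, atlas)
    features, feature_truth = generate_features(lesion, spec)
    return atlas, lesion, features, truth, feature_truth


def run_full_pipeline(config: dict) -> dict:
    """Run every stage and return (and optionally write) the report dict."""
    seed = int(config.get("seed", 0))
    method = config.get("method", "none")
    levels = config.get("levels", ["level2", "level1"])
    per_subset = bool(config.get("per_subset", True))

    atlas, lesion, features, sim_truth, _ = _build_data(config)
    dist = build_distance_matrix(atlas)
    truth_binary = (lesion > 0).astype(int)

    # stage 1-2: characterization and k-means subsets
    chars = characterize_cohort(lesion, dist)
    assignment = cluster_subjects(chars, k=int(config.get("k", 3)), seed=seed)
    report: dict = {
        "version": __version__,
        "seed": seed,
        "method": method,
        "n_subjects": int(len(lesion)),
        "n_regions": int(atlas.n_regions),
        "subset_sizes": {
            str(s): int((assignment["subset"] == s).sum())
            for s in sorted(assignment["subset"].unique())
        },
    }
    if sim_truth is not None:
        from sklearn.metrics import adjusted_rand_score

        report["kmeans_ari_vs_planted"] = float(
            adjusted_rand_score(sim_truth["subset"], assignment["subset"])
        )

    # stage 3: subset prediction from non-imaging features
    sc_cfg = dict(config.get("subset_classifier", {}))
    clf = fit_subset_pipeline(
        features, assignment["subset"].to_numpy(), seed=seed,
        n_resamples=int(sc_cfg.get("n_resamples", 100)),
        grid=sc_cfg.get("grid"),
        alpha=float(sc_cfg.get("alpha", 0.05)),
        variance_target=float(sc_cfg.get("variance_target", 0.95)),
        max_missing_fraction=float(sc_cfg.get("max_missing_fraction", 0.2)),
    )
    pred_subsets = pd.Series(predict_subset(clf, features), index=features.index)
    from sklearn.metrics import confusion_matrix as _sk_confusion

    cm = _sk_confusion(assignment["subset"], pred_subsets)
    report["subset_classifier"] = {
        "accuracy": float((pred_subsets.to_numpy() == assignment["subset"].to_numpy()).mean()),
        "mcc": multiclass_mcc(cm),
        "n_components": int(clf.reduction.n_components),
        "n_screened_features": len(clf.screened_features),
        "best_params": {k: (v if v is None or isinstance(v, (int, float)) else str(v))
                        for k, v in clf.best_params.items()},
        "predicted_subset_sizes": {
            str(s): int((pred_subsets == s).sum()) for s in sorted(pred_subsets.unique())
        },
    }
    rho, p = cv_correlation(lesion, assignment["subset"], pred_subsets)
    report["cv_true_vs_predicted"] = {"spearman_rho": rho, "p": p}

    # stage 4-6: region models per group, predictions, roll-ups, evaluation
    fit_cfg = FitConfig(method=method, seed=seed, **config.get("region_config", {}))
    groups: dict[str, pd.Index] = {"complete": lesion.index}
    if per_subset:
        for s in sorted(pred_subsets.unique()):
            groups[f"subset_{s}"] = pred_subsets.index[pred_subsets == s]

    report["groups"] = {}
    for gname, ids in groups.items():
        g_lesion = lesion.loc[ids]
        g_feat = features.loc[ids].fillna(features.loc[ids].median())
        result = fit_all_regions(g_lesion, g_feat, fit_cfg)
        pred = result.predictions(g_feat)
        perf = evaluate_predictions(truth_binary.loc[ids], pred)
        entry: dict = {
            "n_subjects": int(len(ids)),
            "n_modelled_regions": len(result.models),
            "unmodellable": {str(k): v for k, v in sorted(result.unmodellable.items())},
            "aal": _perf_summary(perf),
        }
        for level in levels:
            mapping = rollup_map(atlas, level)
            coarse_truth = rollup_predictions(truth_binary.loc[ids], mapping)
            modified = rollup_predictions(pred, {k: v for k, v in mapping.items() if k in pred.columns})
            mod_perf = evaluate_predictions(coarse_truth[modified.columns], modified)
            direct_result, _ = direct_fit_at_level(g_lesion, g_feat, mapping, fit_cfg)
            direct_pred = direct_result.predictions(g_feat)
            dir_perf = evaluate_predictions(coarse_truth[direct_pred.columns], direct_pred)
            level_entry = {
                "modified": _perf_summary(mod_perf),
                "direct": _perf_summary(dir_perf),
            }
            mod_sens = mod_perf["sensitivity"].dropna()
            dir_sens = dir_perf["sensitivity"].dropna()
            if len(mod_sens) and len(dir_sens):
                z, pz = wilcoxon_rank_sum(mod_sens, dir_sens)
                level_entry["modified_vs_direct_ranksum"] = {"z": z, "p": pz}
            entry[level] = level_entry
        report["groups"][gname] = entry

    report = _round(report)
    if "out" in config:
        out_dir = Path(config["out"])
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
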