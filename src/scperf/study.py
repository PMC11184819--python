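"""End-to-end synthetic study: simulate a dataset collection, run the
pipeline grid, score and correct the metrics, featurize datasets, train the
meta-models and evaluate them on held-out datasets.

The default configuration is a desk-scale study (6 datasets x a 36-pipeline
subgrid) that exercises every stage end to end; all sizes are configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import meta, metrics
from .engine import enumerate_grid, run_grid
from .synth import SynthDatasetConfig, generate_dataset_collection, generate_gene_sets

__all__ = ["StudyConfig", "run_full_study"]

def _nanmedian(x) -> float:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    return float(np.median(x)) if x.size else float("nan")


REDUCED_GRID_LEVELS = {
    "filtering": ["default", "stringent", "lenient"],
    "normalization": ["lognorm", "pooling", "pearson"],
    "n_dims": [10],
    "resolution": [0.1, 0.5, 1.0, 2.0],
}


@dataclass
class StudyConfig:
    n_datasets: int = 6
    n_labeled: int = 2
    n_genes: int = 1000
    dataset_ranges: dict = field(
        default_factory=lambda: {
            "n_cells": (220, 320),
            "n_clusters": (2, 5),
            "libsize_mu_log": (7.8, 8.8),
            "de_prob": (0.1, 0.3),
            "logfc_sd": (1.0, 2.0),
        }
    )
    grid_levels: dict = field(default_factory=lambda: dict(REDUCED_GRID_LEVELS))
    n_random_sets: int = 15
    gsea_n_perm: int = 200
    test_frac: float = 0.34
    cv_k: int = 2
    ppca_q: int = 2
    metrics: tuple = metrics.METRIC_NAMES
    correct_gsea: bool = False
    rf_ntree_grid: tuple = (100,)
    rf_mtry_grid: tuple | None = None
    en_alpha_grid: tuple = meta.ALPHA_GRID
    en_lambda_grid: tuple = meta.LAMBDA_GRID

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        from .io import read_yaml

        raw = read_yaml(path) or {}
        cfg = cls(**raw)
        return cfg


def _score_all(collection, results, sets, n_perm, seed) -> pd.DataFrame:
    by_id = {d.dataset_id: d.counts for d in collection}
    rows = []
    for i, res in enumerate(results):
        if isinstance(res, dict):
            rows.append(
                {
                    "dataset_id": res["dataset_id"],
                    "pipeline_id": res["pipeline_id"],
                    "k": np.nan,
                    **{m: np.nan for m in metrics.METRIC_NAMES},
                }
            )
            continue
        s = int(np.random.SeedSequence([seed, 7, i]).generate_state(1)[0] & 0x7FFFFFFF)
        rows.append(metrics.score_clustering(by_id[res.dataset_id], res, sets, n_perm=n_perm, seed=s))
    return pd.DataFrame(rows)


def _process_table(table: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    for m in cfg.metrics:
        table = metrics.scale_within_dataset(table, m)
        if m in metrics.PURITY_METRICS or (m == "gsea" and cfg.correct_gsea):
            table = metrics.correct_for_k(table, m)
        table = metrics.impute_missing(table, m)
    return table


def run_full_study(config: StudyConfig | None = None, seed: int = 0, outdir=None) -> dict:
    """Run every stage of the synthetic study; returns a report bundle and
    optionally writes deterministic CSV/JSON outputs to ``outdir``."""
    cfg = config or StudyConfig()
    base = SynthDatasetConfig(n_genes=cfg.n_genes, seed=0)
    collection = generate_dataset_collection(
        cfg.n_datasets, ranges=cfg.dataset_ranges, seed=seed, base_config=base
    )
    sets = generate_gene_sets(collection, n_random=cfg.n_random_sets, seed=seed + 1)
    grid = enumerate_grid(cfg.grid_levels)
    results = run_grid([d.counts for d in collection], grid, seed=seed)
    table = _score_all(collection, results, sets, cfg.gsea_n_perm, seed)
    table = _process_table(table, cfg)

    ids = [d.dataset_id for d in collection]
    labeled = ids[: cfg.n_labeled]
    split = meta.dataset_aware_split(ids, labeled, test_frac=cfg.test_frac, seed=seed)
    from .features import compute_dataset_features

    features, ppca, scaler = compute_dataset_features(collection, split.train_ids, q=cfg.ppca_q)
    folds = meta.dataset_aware_cv_folds(split.train_ids, k=cfg.cv_k, seed=seed)
    ari = ev.pipeline_ari(results, {d.dataset_id: d.true_labels for d in collection if d.dataset_id in labeled})

    train_tab = table[table["dataset_id"].isin(split.train_ids)].reset_index(drop=True)
    test_tab = table[table["dataset_id"].isin(split.test_ids)].reset_index(drop=True)

    eval_rows, pred_rows, determinants = [], [], []
    for metric in cfg.metrics:
        for kind in ("random_forest", "elastic_net"):
            for mode in ("pipeline_only", "interactions"):
                tr = meta.assemble_features(features, grid, train_tab, mode, metric, model_kind=kind)
                if kind == "random_forest":
                    p = tr.X.shape[1]
                    mtry = cfg.rf_mtry_grid or (max(1, int(np.ceil(p / 3))),)
                    model = meta.tune_random_forest(tr, folds, ntree_grid=cfg.rf_ntree_grid, mtry_grid=mtry, seed=seed)
                else:
                    model = meta.tune_elastic_net(
                        tr, folds, alpha_grid=cfg.en_alpha_grid, lambda_grid=cfg.en_lambda_grid, seed=seed
                    )
                te = meta.assemble_features(features, grid, test_tab, mode, metric, model_kind=kind)
                preds = meta.predict(model, te)
                target_col = (
                    f"{metric}_corrected" if f"{metric}_corrected" in test_tab else f"{metric}_scaled"
                )
                per_ds = ev.per_dataset_correlation(preds, test_tab, target_col)
                p_metric = ev.wilcoxon_vs_zero(per_ds["r"])
                block = {
                    "metric": metric,
                    "model": kind,
                    "mode": mode,
                    "median_r_metric": _nanmedian(per_ds["r"]),
                    "p_metric": p_metric,
                }
                if len(ari):
                    per_ari = ev.ari_agreement(preds, test_tab, ari)
                    block["median_r_ari"] = _nanmedian(per_ari["r"])
                    block["p_ari"] = ev.wilcoxon_vs_zero(per_ari["r"])
                eval_rows.append(block)
                pred_rows.append(
                    test_tab[["dataset_id", "pipeline_id"]].assign(
                        metric=metric, model=kind, mode=mode, prediction=preds
                    )
                )
                if len(per_ds) >= 5:
                    det = ev.determinant_analysis(per_ds, features)
                    det.insert(0, "mode", mode)
                    det.insert(0, "model", kind)
                    det.insert(0, "metric", metric)
                    determinants.append(det)

    evaluation = pd.DataFrame(eval_rows)
    evaluation["p_metric_adj"] = ev.bh_adjust(evaluation["p_metric"])
    if "p_ari" in evaluation:
        evaluation["p_ari_adj"] = ev.bh_adjust(evaluation["p_ari"])
    predictions = pd.concat(pred_rows, ignore_index=True)
    det_df = (
        pd.concat(determinants, ignore_index=True)
        if determinants
        else pd.DataFrame(columns=["metric", "model", "mode", "feature", "r", "p", "significant"])
    )
    if len(det_df):
        sig_any = det_df.groupby("feature")["significant"].transform("any")
        det_df["significant_in_any_model"] = sig_any

    bundle = {
        "config": cfg,
        "collection": collection,
        "grid": grid,
        "results": results,
        "table": table,
        "features": features,
        "split": split,
        "ari": ari,
        "evaluation": evaluation,
        "predictions": predictions,
        "determinants": det_df,
    }
    if outdir is not None:
        _write_outputs(bundle, Path(outdir), seed)
    return bundle


def _write_outputs(bundle: dict, outdir: Path, seed: int) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    bundle["table"].to_csv(outdir / "performance_table.csv", index=False, float_format=fmt)
    bundle["features"].to_csv(outdir / "dataset_features.csv", float_format=fmt)
    bundle["ari"].to_csv(outdir / "ari.csv", index=False, float_format=fmt)
    bundle["evaluation"].to_csv(outdir / "evaluation.csv", index=False, float_format=fmt)
    bundle["predictions"].to_csv(outdir / "predictions.csv", index=False, float_format=fmt)
    bundle["determinants"].to_csv(outdir / "determinants.csv", index=False, float_format=fmt)
    summary = {
        "seed": seed,
        "n_datasets": len(bundle["collection"]),
        "n_pipelines": len(bundle["grid"]),
        "n_rows": int(len(bundle["table"])),
        "train_ids": bundle["split"].train_ids,
        "test_ids": bundle["split"].test_ids,
        "n_evaluation_blocks": int(len(bundle["evaluation"])),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(bundle["config"]).items()
            if not isinstance(v, dict)
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
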