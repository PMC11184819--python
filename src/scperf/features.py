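"""Per-dataset feature vectors for the meta-models.

Each dataset is summarized by 21 quality-control statistics (medians and
dispersion of per-cell QC metrics plus dataset-level composition measures)
and by its scores on a 20-component probabilistic PCA of the dataset-by-gene
mean-expression matrix.  The PPCA model and the feature scalers are fitted
on training datasets only and applied unchanged to held-out datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import MAD_SCALE, CountMatrix, compute_cell_qc

__all__ = [
    "QC_FEATURE_NAMES",
    "PPCAModel",
    "summarize_dataset_qc",
    "mean_expression_matrix",
    "fit_ppca",
    "transform_ppca",
    "scale_features",
    "compute_dataset_features",
]

QC_FEATURE_NAMES = (
    "median_log10_total_counts",
    "median_log10_detected_features",
    "median_pct_top20",
    "median_pct_top50",
    "median_pct_top100",
    "median_pct_top200",
    "median_pct_mito",
    "median_featcount_dist",
    "median_pct_coding",
    "log10_n_cells",
    "log10_genes_detected",
    "median_prop_genes_detected",
    "mad_log10_total_counts",
    "mad_log10_detected_features",
    "frac_cells_high_mito",
    "sparsity",
    "cv_library_size",
    "iqr_pct_top50",
    "skew_log10_library_size",
    "frac_genes_coding",
    "frac_genes_mito",
)


def _mad(x: np.ndarray) -> float:
    med = np.nanmedian(x)
    return float(MAD_SCALE * np.nanmedian(np.abs(x - med)))


def summarize_dataset_qc(qc: pd.DataFrame, counts: CountMatrix) -> pd.Series:
    """The 21 per-dataset QC statistics (schema in ``QC_FEATURE_NAMES``)."""
    if len(qc) < 2:
        raise ValueError("need at least 2 cells")
    v = counts.values.astype(float)
    totals = qc["total_counts"].to_numpy(float)
    lt = qc["log10_total_counts"].to_numpy(float)
    lf = qc["log10_total_features"].to_numpy(float)
    mt = qc["pct_counts_Mt"].to_numpy(float)
    coding_mask = counts.gene_flags["coding"].to_numpy(bool)
    mito_mask = counts.gene_flags["mito"].to_numpy(bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_coding = np.where(totals > 0, v[coding_mask].sum(axis=0) / totals, np.nan)
    genes_detected = int(((v > 0).sum(axis=1) > 0).sum())
    ok_tot = totals[totals > 0]
    out = {
        "median_log10_total_counts": np.nanmedian(lt),
        "median_log10_detected_features": np.nanmedian(lf),
        "median_pct_top20": np.nanmedian(qc["pct_counts_in_top_20_features"]),
        "median_pct_top50": np.nanmedian(qc["pct_counts_in_top_50_features"]),
        "median_pct_top100": np.nanmedian(qc["pct_counts_in_top_100_features"]),
        "median_pct_top200": np.nanmedian(qc["pct_counts_in_top_200_features"]),
        "median_pct_mito": np.nanmedian(mt),
        "median_featcount_dist": np.nanmedian(qc["featcount_dist"]),
        "median_pct_coding": np.nanmedian(pct_coding),
        "log10_n_cells": np.log10(counts.n_cells),
        "log10_genes_detected": np.log10(max(genes_detected, 1)),
        "median_prop_genes_detected": np.nanmedian(
            qc["detected_features"].to_numpy(float) / counts.n_genes
        ),
        "mad_log10_total_counts": _mad(lt),
        "mad_log10_detected_features": _mad(lf),
        "frac_cells_high_mito": float(np.nanmean(mt > 0.08)),
        "sparsity": float((v == 0).mean()),
        "cv_library_size": float(ok_tot.std(ddof=1) / ok_tot.mean()) if ok_tot.size > 1 else 0.0,
        "iqr_pct_top50": float(
            np.nanpercentile(qc["pct_counts_in_top_50_features"], 75)
            - np.nanpercentile(qc["pct_counts_in_top_50_features"], 25)
        ),
        "skew_log10_library_size": float(stats.skew(lt[np.isfinite(lt)])),
        "frac_genes_coding": float(coding_mask.mean()),
        "frac_genes_mito": float(mito_mask.mean()),
    }
    s = pd.Series(out, name=counts.dataset_id).astype(float)
    assert len(s) == 21
    return s


def mean_expression_matrix(collection: list[CountMatrix]) -> pd.DataFrame:
    """Dataset-by-gene matrix of mean raw counts per gene.

    Gene universes are intersected (with a warning) when they differ.
    """
    universes = [pd.Index(c.gene_ids) for c in collection]
    shared = universes[0]
    for u in universes[1:]:
        shared = shared.intersection(u)
    if any(len(u) != len(shared) for u in universes):
        warnings.warn("gene universes differ; using the intersection", stacklevel=2)
    rows = []
    for c in collection:
        pos = pd.Index(c.gene_ids).get_indexer(shared)
        rows.append(c.values[pos, :].mean(axis=1))
    return pd.DataFrame(rows, index=[c.dataset_id for c in collection], columns=shared)


@dataclass
class PPCAModel:
    """Closed-form maximum-likelihood probabilistic PCA (genes >> datasets
    handled through the thin SVD of the centered data)."""

    mu: np.ndarray
    W: np.ndarray  # genes x q, columns ordered by decreasing variance
    sigma2: float
    q: int


def fit_ppca(matrix: pd.DataFrame | np.ndarray, q: int = 20) -> PPCAModel:
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    if n < q + 1:
        raise ValueError("need more training rows than components")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = S**2 / n  # eigenvalues of the ML covariance (1/N convention)
    total = float(lam.sum())
    top = lam[:q]
    if d > q:
        sigma2 = max((total - float(top.sum())) / (d - q), 0.0)
    else:
        sigma2 = 0.0
    if np.any(top <= sigma2):
        warnings.warn("component variance at or below noise floor; clipping", stacklevel=2)
    W = Vt[:q].T * np.sqrt(np.clip(top - sigma2, 0.0, None))
    return PPCAModel(mu=mu, W=W, sigma2=float(sigma2), q=q)


def transform_ppca(model: PPCAModel, matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Posterior-mean latent scores (W^T W + sigma^2 I)^-1 W^T (x - mu)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != model.mu.size:
        raise ValueError("gene universe does not match the fitted model")
    M = model.W.T @ model.W + model.sigma2 * np.eye(model.q)
    return np.linalg.solve(M, model.W.T @ (X - model.mu).T).T


def scale_features(table: pd.DataFrame, train_ids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize every numeric column by train-set mean/sd; the test block
    is transformed with the stored train statistics only."""
    train_ids = list(train_ids)
    missing = set(train_ids) - set(table.index)
    if missing:
        raise KeyError(f"unknown train ids: {sorted(missing)[:3]}")
    tr = table.loc[train_ids]
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=1)
    zero = ~(sd > 0)
    if zero.any():
        warnings.warn("zero train sd in feature columns; setting them to 0", stacklevel=2)
    sd_safe = sd.where(~zero, 1.0)
    scaled = (table - mu) / sd_safe
    scaled.loc[:, zero[zero].index] = 0.0
    stats_df = pd.DataFrame({"mean": mu, "sd": sd})
    return scaled, stats_df


def compute_dataset_features(
    collection: list,
    train_ids,
    q: int = 20,
    qc_tables: dict | None = None,
) -> tuple[pd.DataFrame, PPCAModel, pd.DataFrame]:
    """Full 41-column feature table (21 QC + ``q`` PPCA scores), train-scaled.

    ``collection`` holds CountMatrix objects (or objects with a ``.counts``
    attribute).  PPCA is fitted on the training rows of the dataset-by-gene
    mean matrix only, then applied to all rows.
    """
    counts_list = [getattr(c, "counts", c) for c in collection]
    qc_rows = []
    for cm in counts_list:
        qc = qc_tables.get(cm.dataset_id) if qc_tables else None
        if qc is None:
            qc = compute_cell_qc(cm)
        qc_rows.append(summarize_dataset_qc(qc, cm))
    qc_df = pd.DataFrame(qc_rows)

    mexpr = mean_expression_matrix(counts_list)
    model = fit_ppca(mexpr.loc[list(train_ids)], q=q)
    scores = transform_ppca(model, mexpr)
    pc_df = pd.DataFrame(
        scores, index=mexpr.index, columns=[f"PC{i + 1}" for i in range(q)]
    )
    feats = pd.concat([qc_df, pc_df], axis=1)
    scaled, stats_df = scale_features(feats, train_ids)
    return scaled, model, stats_df
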