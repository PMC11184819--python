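"""Cluster-quality metrics, per-dataset scaling, cluster-number correction,
imputation and agreement with reference labels.

Four metrics score every clustering output: Calinski-Harabasz (CH),
negated Davies-Bouldin (DB), mean silhouette (SIL) and a gene-set
enrichment score (mean |NES| over clusters).  DB is stored negated so that
higher is better for all four.  Because the purity metrics trend strongly
with the number of clusters k, each is z-scored within its dataset and the
k-trend is removed by a local regression, leaving residuals as the
*corrected* metric.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .engine import ClusteringResult, CountMatrix, select_hvgs
from .gsea import gsea_metric
from .smooth import loess_fit

__all__ = [
    "purity_input",
    "calinski_harabasz",
    "davies_bouldin_neg",
    "silhouette_mean",
    "find_markers",
    "score_clustering",
    "scale_within_dataset",
    "correct_for_k",
    "impute_missing",
    "adjusted_rand_index",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ch", "db", "sil", "gsea")
PURITY_METRICS = ("ch", "db", "sil")


def purity_input(counts: CountMatrix, clustering: ClusteringResult, n_hvgs: int = 500):
    """log1p raw counts on the clustering's kept cells, restricted to the
    ``n_hvgs`` most variable genes of that submatrix; cells x genes."""
    sub = counts.subset_cells(clustering.kept_cell_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hvgs = select_hvgs(sub.values.astype(float), sub.gene_ids, n=n_hvgs)
    pos = pd.Index(sub.gene_ids).get_indexer(hvgs)
    return np.log1p(sub.values[pos, :].astype(float)).T


def _group(X: np.ndarray, labels: np.ndarray):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    return X, labels, uniq


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Between/within dispersion ratio [B/(k-1)] / [W/(n-k)]; NaN at k=1."""
    X, labels, uniq = _group(X, labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        return float("nan")
    if k >= n:
        raise ValueError("needs n > k")
    mu = X.mean(axis=0)
    B = W = 0.0
    for c in uniq:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        B += Xc.shape[0] * float(((mc - mu) ** 2).sum())
        W += float(((Xc - mc) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def davies_bouldin_neg(X: np.ndarray, labels: np.ndarray) -> float:
    """Negated Davies-Bouldin index, so higher means better-separated
    clusters; NaN at k=1 or on coincident centroids."""
    X, labels, uniq = _group(X, labels)
    k = uniq.size
    if k < 2:
        return float("nan")
    cents = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    s = np.array(
        [np.linalg.norm(X[labels == c] - cents[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    d = cdist(cents, cents)
    if np.any(d[~np.eye(k, dtype=bool)] == 0):
        return float("nan")
    with np.errstate(divide="ignore"):
        R = (s[:, None] + s[None, :]) / d
    np.fill_diagonal(R, -np.inf)
    return float(-np.mean(R.max(axis=1)))


def silhouette_mean(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient; singleton-cluster points score 0."""
    X, labels, uniq = _group(X, labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        return float("nan")
    D = squareform(pdist(X))
    sizes = {c: int((labels == c).sum()) for c in uniq}
    scores = np.zeros(n)
    # mean distance from each point to each cluster
    md = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    counts = np.array([sizes[c] for c in uniq], dtype=float)
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        if sizes[labels[i]] == 1:
            scores[i] = 0.0
            continue
        a = md[i, ci] / (counts[ci] - 1)  # exclude self
        b = np.min(np.delete(md[i] / counts, ci))
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def find_markers(normalized: np.ndarray, gene_ids: np.ndarray, labels: np.ndarray) -> dict:
    """One-vs-rest log2 fold change of mean expression per cluster.

    Returns cluster id -> Series of log2FC indexed by gene, sorted by
    decreasing value with ties broken by gene id.  Clusters of a single
    cell are computed all the same (flagged by the caller if needed).
    """
    normalized = np.asarray(normalized, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    gene_ids = np.asarray(gene_ids, dtype=object)
    out = {}
    for c in uniq:
        mask = labels == c
        m_in = normalized[:, mask].mean(axis=1)
        m_out = normalized[:, ~mask].mean(axis=1)
        lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
        s = pd.Series(lfc, index=gene_ids)
        s = s.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
        out[c] = s
    return out


def score_clustering(
    counts: CountMatrix,
    clustering: ClusteringResult,
    sets: dict | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """All four raw metrics for one clustering output.

    k = 1 outputs yield NaN for every metric (imputed downstream).
    """
    res = {
        "dataset_id": clustering.dataset_id,
        "pipeline_id": clustering.pipeline_id,
        "k": clustering.k,
    }
    if clustering.k < 2:
        res.update({m: float("nan") for m in METRIC_NAMES})
        return res
    X = purity_input(counts, clustering)
    res["ch"] = calinski_harabasz(X, clustering.labels)
    res["db"] = davies_bouldin_neg(X, clustering.labels)
    res["sil"] = silhouette_mean(X, clustering.labels)
    if sets is None:
        res["gsea"] = float("nan")
    else:
        logc = np.log1p(counts.subset_cells(clustering.kept_cell_ids).values.astype(float))
        markers = find_markers(logc, counts.gene_ids, clustering.labels)
        res["gsea"] = gsea_metric(markers, sets, n_perm=n_perm, seed=seed)
    return res


# ---------------------------------------------------------------------------
# performance-table transforms (long DataFrame keyed on dataset_id, pipeline_id)


def scale_within_dataset(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Z-score ``metric`` within each dataset over non-missing rows (sample
    sd); adds ``{metric}_scaled``.  Missing stays missing."""
    table = table.copy()
    out = np.full(len(table), np.nan)
    for _, idx in table.groupby("dataset_id").indices.items():
        x = table[metric].to_numpy(float)[idx]
        ok = np.isfinite(x)
        if ok.sum() < 2:
            continue
        mu, sd = x[ok].mean(), x[ok].std(ddof=1)
        if sd == 0:
            warnings.warn(f"zero variance for {metric} in a dataset block", stacklevel=2)
            z = np.where(ok, 0.0, np.nan)
        else:
            z = (x - mu) / sd
        out[idx] = z
    table[f"{metric}_scaled"] = out
    return table


def correct_for_k(table: pd.DataFrame, metric: str, span: float = 0.75) -> pd.DataFrame:
    """Remove the cluster-number trend: per dataset, local regression of the
    scaled metric on k; ``{metric}_corrected`` holds the residuals."""
    col = f"{metric}_scaled"
    if col not in table:
        raise KeyError(f"scale_within_dataset must run before correct_for_k ({col})")
    table = table.copy()
    out = np.full(len(table), np.nan)
    kk = table["k"].to_numpy(float)
    vv = table[col].to_numpy(float)
    for _, idx in table.groupby("dataset_id").indices.items():
        x, y = kk[idx], vv[idx]
        ok = np.isfinite(y) & np.isfinite(x)
        if ok.sum() < 2:
            continue
        if np.unique(x[ok]).size < 2:
            warnings.warn("k constant within dataset; residuals are centered values", stacklevel=2)
            res = y[ok] - y[ok].mean()
        else:
            res = y[ok] - loess_fit(x[ok], y[ok], span=span, degree=2)
        block = np.full(idx.size, np.nan)
        block[ok] = res
        out[idx] = block
    table[f"{metric}_corrected"] = out
    return table


def impute_missing(table: pd.DataFrame, metric: str, column: str | None = None) -> pd.DataFrame:
    """Replace missing entries by the per-dataset median of the (corrected)
    scaled metric; adds ``{metric}_imputed`` flags."""
    col = column or (
        f"{metric}_corrected" if f"{metric}_corrected" in table else f"{metric}_scaled"
    )
    table = table.copy()
    vals = table[col].to_numpy(float).copy()
    flags = ~np.isfinite(vals)
    for _, idx in table.groupby("dataset_id").indices.items():
        block = vals[idx]
        ok = np.isfinite(block)
        if not ok.any():
            raise ValueError("dataset block with all metric values missing")
        block[~ok] = np.median(block[ok])
        vals[idx] = block
    table[col] = vals
    table[f"{metric}_imputed"] = flags
    return table


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted Rand index between two labelings of the same cells."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("labelings must cover the same cells")
    if a.size < 2:
        raise ValueError("need at least 2 cells")
    return float(adjusted_rand_score(a, b))
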