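"""Held-out evaluation of meta-models and determinants of per-dataset
predictive performance.

Predictive power on a test dataset is the Pearson correlation between
predicted and observed metric values across its pipelines.  A one-sample
signed-rank test (alternative: greater than zero) over test datasets,
Benjamini-Hochberg corrected across model/metric blocks, assesses whether
prediction beats chance.  For labeled datasets the observed metric is
replaced by the adjusted Rand index against the reference labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import adjusted_rand_index

__all__ = [
    "per_dataset_correlation",
    "wilcoxon_vs_zero",
    "bh_adjust",
    "pipeline_ari",
    "ari_agreement",
    "determinant_analysis",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def per_dataset_correlation(
    predictions: np.ndarray, table: pd.DataFrame, column: str
) -> pd.DataFrame:
    """One Pearson r per dataset between predictions and ``column``,
    computed over that dataset's pipeline rows."""
    table = table.assign(_pred=np.asarray(predictions, float))
    rows = []
    for did, block in table.groupby("dataset_id"):
        if len(block) < 3:
            raise ValueError(f"dataset {did} has fewer than 3 pipelines")
        rows.append(
            {
                "dataset_id": did,
                "r": _pearson(block["_pred"].to_numpy(), block[column].to_numpy(float)),
                "n_pipelines": len(block),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_vs_zero(correlations) -> float:
    """One-sample signed-rank p-value, alternative 'greater than 0'.

    Exact null when the sample is small and free of ties/zeros, otherwise
    the normal approximation with continuity correction.
    """
    x = np.asarray(correlations, float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        return float("nan")
    if np.all(x == 0):
        return 1.0
    return float(stats.wilcoxon(x, alternative="greater", method="auto").pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def pipeline_ari(clusterings: list, reference_labels: dict) -> pd.DataFrame:
    """ARI of each clustering output against its dataset's reference labels.

    ``reference_labels`` maps dataset_id -> Series indexed by cell id.
    Outputs for datasets without references are skipped.
    """
    rows = []
    for res in clusterings:
        if isinstance(res, dict):  # error record
            continue
        ref = reference_labels.get(res.dataset_id)
        if ref is None:
            continue
        truth = ref.loc[res.kept_cell_ids].to_numpy()
        rows.append(
            {
                "dataset_id": res.dataset_id,
                "pipeline_id": res.pipeline_id,
                "ari": adjusted_rand_index(res.labels, truth),
            }
        )
    return pd.DataFrame(rows)


def ari_agreement(
    predictions: np.ndarray, table: pd.DataFrame, ari_table: pd.DataFrame
) -> pd.DataFrame:
    """Per labeled dataset, r between predicted metric and pipeline-wise ARI."""
    merged = table.assign(_pred=np.asarray(predictions, float)).merge(
        ari_table, on=["dataset_id", "pipeline_id"], how="inner"
    )
    rows = []
    for did, block in merged.groupby("dataset_id"):
        rows.append(
            {
                "dataset_id": did,
                "r": _pearson(block["_pred"].to_numpy(), block["ari"].to_numpy(float)),
                "n_pipelines": len(block),
            }
        )
    return pd.DataFrame(rows)


def determinant_analysis(
    per_dataset: pd.DataFrame, features: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Correlate each dataset feature with per-dataset predictive power.

    Returns one row per feature with the Pearson r, the two-sided t-based
    p-value and a significance flag at ``alpha``; constant features are
    skipped.
    """
    perf = per_dataset.set_index("dataset_id")["r"].dropna()
    if len(perf) < 5:
        raise ValueError("need at least 5 test datasets")
    F = features.loc[perf.index]
    rows = []
    for col in F.columns:
        x = F[col].to_numpy(float)
        if np.std(x) == 0:
            continue
        r, p = stats.pearsonr(x, perf.to_numpy())
        rows.append({"feature": col, "r": float(r), "p": float(p), "significant": p < alpha})
    return pd.DataFrame(rows)
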