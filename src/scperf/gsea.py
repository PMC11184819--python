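"""Gene set enrichment scoring of clustering outputs.

Classic weighted Kolmogorov-Smirnov enrichment: genes are ranked by a
per-cluster statistic (one-vs-rest log2 fold change), the running sum gains
|stat|^p / sum_hits |stat|^p on set members and loses 1/(N - N_hits)
otherwise, and the enrichment score (ES) is the signed maximum deviation.
The normalized score (NES) divides the ES by the mean absolute ES of
same-sign gene-label permutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gsea_es", "gsea_nes", "gsea_metric", "filter_gene_sets"]


def _es_from_positions(stats_sorted: np.ndarray, hit_pos: np.ndarray, p: float) -> float:
    """ES for hit positions (sorted ascending) in a ranked list."""
    N = stats_sorted.size
    m = hit_pos.size
    if m == 0 or m == N:
        raise ValueError("gene set must overlap the ranking but not cover it")
    w = np.abs(stats_sorted[hit_pos]) ** p
    tot = w.sum()
    if tot == 0:  # all hit stats zero: uniform weights
        w = np.ones(m)
        tot = float(m)
    cum = np.cumsum(w) / tot
    miss = (hit_pos - np.arange(m)) / (N - m)
    after = cum - miss  # running sum just after each hit
    before = np.concatenate([[0.0], cum[:-1]]) - miss  # just before each hit
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def _prepare(ranked: pd.Series, gene_set) -> tuple[np.ndarray, np.ndarray]:
    stats = ranked.to_numpy(float)
    idx = pd.Index(ranked.index)
    pos = idx.get_indexer(pd.unique(pd.Series(list(gene_set))))
    pos = np.sort(pos[pos >= 0])
    return stats, pos


def gsea_es(ranked: pd.Series, gene_set, p: float = 1.0) -> float:
    """Enrichment score of ``gene_set`` in a ranked gene list.

    ``ranked`` is a Series of ranking statistics indexed by gene id, sorted
    in decreasing order.
    """
    stats, pos = _prepare(ranked, gene_set)
    if pos.size == 0:
        return float("nan")
    return _es_from_positions(stats, pos, p)


def _perm_es(stats: np.ndarray, m: int, p: float, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    N = stats.size
    # random hit positions == shuffling gene labels
    r = rng.random((n_perm, N))
    pos = np.sort(np.argpartition(r, m - 1, axis=1)[:, :m], axis=1)
    w = np.abs(stats[pos]) ** p
    tot = w.sum(axis=1, keepdims=True)
    bad = tot[:, 0] == 0
    if bad.any():
        w[bad] = 1.0
        tot[bad] = m
    cum = np.cumsum(w, axis=1) / tot
    miss = (pos - np.arange(m)[None, :]) / (N - m)
    after = cum - miss
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def gsea_nes(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    p: float = 1.0,
) -> float:
    """Normalized enrichment score under gene-label permutations.

    NES = ES / mean(|ES_perm|) over permutations whose ES shares the sign
    of the observed ES; NaN when no same-sign permutation exists.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    stats, pos = _prepare(ranked, gene_set)
    if pos.size == 0:
        return float("nan")
    es = _es_from_positions(stats, pos, p)
    perm = _perm_es(stats, pos.size, p, n_perm, np.random.default_rng(seed))
    if es == 0.0:
        return 0.0
    same = perm > 0 if es > 0 else perm < 0
    if not same.any():
        return float("nan")
    return float(es / np.abs(perm[same]).mean())


def filter_gene_sets(sets: dict, universe, min_size: int = 10, max_size: int = 500) -> dict:
    """Keep sets whose overlap with ``universe`` has more than ``min_size``
    and fewer than ``max_size`` genes (both bounds exclusive)."""
    uni = set(universe)
    out = {}
    for name, genes in sets.items():
        n = len(uni.intersection(genes))
        if min_size < n < max_size:
            out[name] = list(genes)
    return out


def gsea_metric(
    markers: dict,
    sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    agg: str = "mean",
    min_size: int = 10,
    max_size: int = 500,
) -> float:
    """Mean over clusters of the aggregated |NES| over size-filtered sets.

    ``markers`` maps cluster id -> decreasing-sorted ranked Series (as from
    :func:`scperf.metrics.find_markers`).
    """
    if len(markers) < 2:
        return float("nan")
    any_ranking = next(iter(markers.values()))
    kept = filter_gene_sets(sets, any_ranking.index, min_size, max_size)
    if not kept:
        raise ValueError("no gene sets within the size bounds")
    per_cluster = []
    ss = np.random.SeedSequence(seed)
    for (cluster, ranked), child in zip(sorted(markers.items()), ss.spawn(len(markers))):
        seeds = child.generate_state(len(kept)) & 0x7FFFFFFF
        vals = [
            abs(gsea_nes(ranked, genes, n_perm=n_perm, seed=int(s)))
            for (name, genes), s in zip(sorted(kept.items()), seeds)
        ]
        vals = [v for v in vals if np.isfinite(v)]
        if not vals:
            continue
        per_cluster.append(max(vals) if agg == "max" else float(np.mean(vals)))
    return float(np.mean(per_cluster)) if per_cluster else float("nan")
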