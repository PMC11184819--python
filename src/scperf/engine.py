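"""Clustering-pipeline grid: filtering, normalization, dimensionality
reduction and graph clustering applied to raw count matrices.

A *pipeline* is one point in the Cartesian grid of
filtering strategy x normalization method x number of principal
components x clustering resolution.  The default grid (3 x 3 x 4 x 8)
contains 288 pipelines.
"""

from __future__ import annotations

import itertools
import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import lsqr
from sklearn.neighbors import NearestNeighbors

from .smooth import loess_fit

__all__ = [
    "CountMatrix",
    "PipelineConfig",
    "PipelineGrid",
    "ClusteringResult",
    "PipelineError",
    "DEFAULT_GRID_LEVELS",
    "enumerate_grid",
    "encode_pipeline_grid",
    "compute_cell_qc",
    "filter_cells",
    "normalize",
    "pooling_size_factors",
    "select_hvgs",
    "reduce_dims",
    "cluster_graph",
    "run_pipeline",
    "run_grid",
]

MAD_SCALE = 1.4826  # normal-consistency constant, matching R's mad()

FILTER_STRATEGIES = ("default", "stringent", "lenient")
NORM_METHODS = ("lognorm", "pooling", "pearson")

DEFAULT_GRID_LEVELS = {
    "filtering": list(FILTER_STRATEGIES),
    "normalization": list(NORM_METHODS),
    "n_dims": [10, 15, 20, 30],
    "resolution": [0.1, 0.2, 0.3, 0.5, 0.8, 1.0, 1.2, 2.0],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed on a specific dataset (e.g. all cells filtered)."""


@dataclass
class CountMatrix:
    """Raw gene-by-cell count matrix with per-gene annotation flags."""

    values: np.ndarray  # genes x cells, non-negative integers
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    gene_flags: pd.DataFrame  # index gene_ids, boolean columns 'mito', 'coding'
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError("values shape does not match gene/cell ids")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != self.gene_ids.size:
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != self.cell_ids.size:
            raise ValueError("cell ids must be unique")
        if not {"mito", "coding"}.issubset(self.gene_flags.columns):
            raise ValueError("gene_flags needs 'mito' and 'coding' columns")

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def subset_cells(self, cell_ids: np.ndarray) -> "CountMatrix":
        pos = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (pos < 0).any():
            raise KeyError("unknown cell ids")
        return CountMatrix(
            self.values[:, pos],
            self.gene_ids,
            np.asarray(cell_ids, dtype=object),
            self.gene_flags,
            self.dataset_id,
        )


@dataclass(frozen=True)
class PipelineConfig:
    filtering: str
    normalization: str
    n_dims: int
    resolution: float

    def __post_init__(self) -> None:
        if self.filtering not in FILTER_STRATEGIES:
            raise ValueError(f"unknown filtering strategy {self.filtering!r}")
        if self.normalization not in NORM_METHODS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.n_dims <= 0 or self.resolution <= 0:
            raise ValueError("n_dims and resolution must be positive")

    @property
    def pipeline_id(self) -> str:
        return (
            f"{self.filtering}|{self.normalization}"
            f"|dims{self.n_dims}|res{self.resolution:g}"
        )


@dataclass
class PipelineGrid:
    levels: dict
    configs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.configs)

    @property
    def pipeline_ids(self) -> list:
        return [c.pipeline_id for c in self.configs]


@dataclass
class ClusteringResult:
    kept_cell_ids: np.ndarray
    labels: np.ndarray  # integer cluster label per kept cell
    k: int
    pipeline_id: str
    dataset_id: str

    @property
    def singular(self) -> bool:
        return self.k == 1


def enumerate_grid(levels: dict | None = None) -> PipelineGrid:
    """Cartesian product of pipeline-step levels, filtering slowest and
    resolution fastest, with stable pipeline ids."""
    if levels is None:
        levels = DEFAULT_GRID_LEVELS
    for step in ("filtering", "normalization", "n_dims", "resolution"):
        if step not in levels or len(levels[step]) == 0:
            raise ValueError(f"grid step {step!r} needs at least one level")
    configs = [
        PipelineConfig(f, m, int(d), float(r))
        for f, m, d, r in itertools.product(
            levels["filtering"], levels["normalization"], levels["n_dims"], levels["resolution"]
        )
    ]
    return PipelineGrid(levels=dict(levels), configs=configs)


def combination_count(levels: dict) -> int:
    """Size of an arbitrary pipeline space: the product of the number of
    method/parameter choices per analysis step."""
    if not levels:
        raise ValueError("need at least one step")
    n = 1
    for step, choices in levels.items():
        if len(choices) == 0:
            raise ValueError(f"step {step!r} has no choices")
        n *= len(choices)
    return n


def encode_pipeline_grid(grid: PipelineGrid, style: str = "linear") -> pd.DataFrame:
    """Numeric encoding of the pipeline grid, one row per pipeline.

    ``linear``: one-hot categorical steps plus standardized numeric steps
    (used by penalized linear models and the planted performance model).
    ``tree``: integer level codes plus raw numeric steps (random forest).
    """
    rows = pd.DataFrame(
        {
            "filtering": [c.filtering for c in grid.configs],
            "normalization": [c.normalization for c in grid.configs],
            "n_dims": [c.n_dims for c in grid.configs],
            "resolution": [c.resolution for c in grid.configs],
        },
        index=grid.pipeline_ids,
    )
    if style == "tree":
        out = pd.DataFrame(index=rows.index)
        for col in ("filtering", "normalization"):
            lv = list(grid.levels[col])
            out[col] = [lv.index(v) for v in rows[col]]
        out["n_dims"] = rows["n_dims"].astype(float)
        out["resolution"] = rows["resolution"].astype(float)
        return out
    if style != "linear":
        raise ValueError("style must be 'linear' or 'tree'")
    parts = []
    for col in ("filtering", "normalization"):
        for lv in grid.levels[col]:
            parts.append(pd.Series((rows[col] == lv).astype(float), name=f"{col}={lv}"))
    for col in ("n_dims", "resolution"):
        v = rows[col].astype(float)
        sd = v.std(ddof=1)
        parts.append((v - v.mean()) / (sd if sd > 0 else 1.0))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# per-cell QC


def _pct_top(values: np.ndarray, totals: np.ndarray, n: int) -> np.ndarray:
    n = min(n, values.shape[0])
    part = np.partition(values, values.shape[0] - n, axis=0)[-n:, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * part.sum(axis=0) / totals


def compute_cell_qc(counts: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: totals, detected features, top-N count
    concentrations, mitochondrial proportion and the residual of detected
    features regressed on total counts (``featcount_dist``).

    Cells with zero total counts get NaN metrics and ``zero_total=True``.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValueError("empty count matrix")
    v = counts.values.astype(float)
    totals = v.sum(axis=0)
    detected = (v > 0).sum(axis=0).astype(float)
    zero = totals == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_tot = np.where(zero, np.nan, np.log10(np.where(zero, 1, totals)))
        log_feat = np.where(detected == 0, np.nan, np.log10(np.where(detected == 0, 1, detected)))
    mito_mask = counts.gene_flags["mito"].to_numpy(dtype=bool)
    mito_counts = v[mito_mask, :].sum(axis=0) if mito_mask.any() else np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mt = np.where(zero, np.nan, mito_counts / np.where(zero, 1, totals))

    qc = pd.DataFrame(index=pd.Index(counts.cell_ids, name="cell_id"))
    qc["total_counts"] = totals
    qc["detected_features"] = detected
    qc["log10_total_counts"] = log_tot
    qc["log10_total_features"] = log_feat
    for n in (20, 50, 100, 200):
        qc[f"pct_counts_in_top_{n}_features"] = np.where(zero, np.nan, _pct_top(v, totals, n))
    qc["pct_counts_Mt"] = pct_mt

    ok = ~zero & (detected > 0)
    dist = np.full(counts.n_cells, np.nan)
    if ok.sum() >= 2:
        fit = loess_fit(log_tot[ok], log_feat[ok], span=0.75, degree=2)
        dist[ok] = log_feat[ok] - fit
    elif ok.sum() == 1:
        dist[ok] = 0.0
    qc["featcount_dist"] = dist
    qc["zero_total"] = zero
    return qc


def _mad_flags(x: np.ndarray, lower: float | None, upper: float | None) -> np.ndarray:
    """Deviation flags under the MAD rule; NaN never flags."""
    med = np.nanmedian(x)
    mad = MAD_SCALE * np.nanmedian(np.abs(x - med))
    flag = np.zeros(x.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        if lower is not None:
            flag |= x < med - lower * mad
        if upper is not None:
            flag |= x > med + upper * mad
    return flag


def filter_cells(qc: pd.DataFrame, strategy: str = "default") -> np.ndarray:
    """Outlier-cell exclusion by MAD rules on five QC metrics.

    ``default`` flags: log10 totals / features below median-5*MAD or above
    median+2.5*MAD; top-20 concentration and featcount_dist beyond +/-5*MAD;
    mito proportion above median+2.5*MAD *and* above 0.08.  A cell is removed
    with >=2 flags.  ``stringent`` removes at >=1 flag under the same rules.
    ``lenient`` uses +/-5*MAD two-sided flags and a mito flag of above
    median+3*MAD *or* above 0.08, removing at >=2 flags.  Zero-count cells
    are always removed.
    """
    if strategy not in FILTER_STRATEGIES:
        raise ValueError(f"unknown filtering strategy {strategy!r}")
    lt = qc["log10_total_counts"].to_numpy(float)
    lf = qc["log10_total_features"].to_numpy(float)
    t20 = qc["pct_counts_in_top_20_features"].to_numpy(float)
    fc = qc["featcount_dist"].to_numpy(float)
    mt = qc["pct_counts_Mt"].to_numpy(float)

    if strategy in ("default", "stringent"):
        flags = (
            _mad_flags(lt, 5.0, 2.5).astype(int)
            + _mad_flags(lf, 5.0, 2.5)
            + _mad_flags(t20, 5.0, 5.0)
            + _mad_flags(fc, 5.0, 5.0)
            + (_mad_flags(mt, None, 2.5) & (mt > 0.08))
        )
        need = 2 if strategy == "default" else 1
    else:  # lenient
        with np.errstate(invalid="ignore"):
            mito_flag = _mad_flags(mt, None, 3.0) | (mt > 0.08)
        flags = (
            _mad_flags(lt, 5.0, 5.0).astype(int)
            + _mad_flags(lf, 5.0, 5.0)
            + _mad_flags(t20, 5.0, 5.0)
            + _mad_flags(fc, 5.0, 5.0)
            + mito_flag
        )
        need = 2
    keep = (flags < need) & ~qc["zero_total"].to_numpy(bool)
    return qc.index.to_numpy(object)[keep]


# ---------------------------------------------------------------------------
# normalization


def pooling_size_factors(counts: CountMatrix, pool_size: int = 20) -> np.ndarray:
    """Per-cell size factors by pooling-and-deconvolution.

    Cells are ordered by library size on a ring; each window of
    ``pool_size`` consecutive cells yields a pooled factor estimate (median
    ratio of pooled counts to the average cell), and the per-cell factors
    are recovered by least squares.  Returned factors average to 1.
    """
    v = counts.values.astype(float)
    libsize = v.sum(axis=0)
    if np.any(libsize == 0):
        raise PipelineError("zero-library cell present; filter cells first")
    n = counts.n_cells
    pool = min(pool_size, n)
    order = np.argsort(libsize, kind="stable")
    ref = v.mean(axis=1)
    nz = ref > 0
    theta = np.empty(n)
    ring = np.concatenate([order, order[: pool - 1]])
    for i in range(n):
        members = ring[i : i + pool]
        pooled = v[:, members].sum(axis=1)
        theta[i] = np.median(pooled[nz] / ref[nz])
    rows = np.repeat(np.arange(n), pool)
    cols = np.concatenate([ring[i : i + pool] for i in range(n)])
    A = sparse.csr_matrix((np.ones(n * pool), (rows, cols)), shape=(n, n))
    # low-weight anchor equations keep the system full rank and scaled
    w = 0.1
    anchor = sparse.identity(n, format="csr") * w
    B = sparse.vstack([A, anchor]).tocsr()
    rhs = np.concatenate([theta, w * libsize / libsize.mean()])
    sol = lsqr(B, rhs, atol=1e-12, btol=1e-12, iter_lim=10 * n)[0]
    sol = np.clip(sol, 1e-8, None)
    return sol / sol.mean()


def normalize(counts: CountMatrix, method: str) -> np.ndarray:
    """Normalize a (pre-filtered) count matrix; returns genes x cells floats.

    lognorm: log1p of counts scaled to 1e4 per cell.
    pooling: log1p of counts divided by deconvolved size factors.
    pearson: analytic Pearson residuals under NB(mu, theta=100), clipped
    at +/- sqrt(n_cells).
    """
    if method not in NORM_METHODS:
        raise ValueError(f"unknown normalization {method!r}")
    v = counts.values.astype(float)
    libsize = v.sum(axis=0)
    if np.any(libsize == 0):
        raise PipelineError("zero-library cell present; filter cells first")
    if method == "lognorm":
        return np.log1p(1e4 * v / libsize)
    if method == "pooling":
        sf = pooling_size_factors(counts)
        return np.log1p(v / sf)
    # pearson residuals
    theta = 100.0
    total = libsize.sum()
    p_g = v.sum(axis=1) / total
    mu = np.outer(p_g, libsize)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v - mu) / np.sqrt(mu + mu**2 / theta)
    r[~np.isfinite(r)] = 0.0
    clip = np.sqrt(counts.n_cells)
    return np.clip(r, -clip, clip)


# ---------------------------------------------------------------------------
# feature selection / dimensionality reduction


def select_hvgs(matrix: np.ndarray, gene_ids: np.ndarray, n: int = 2000) -> np.ndarray:
    """Rank genes by variance-stabilised standardized variance and return
    the top ``n`` gene ids.

    A local regression of log10 variance on log10 mean gives each gene an
    expected sd; values standardized by that sd (upper-clipped at
    sqrt(n_cells)) are re-scored by their variance.  Ties keep input order.
    """
    matrix = np.asarray(matrix, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_cells = matrix.shape[1]
    mean = matrix.mean(axis=1)
    var = matrix.var(axis=1, ddof=1) if n_cells > 1 else np.zeros(matrix.shape[0])
    usable = (var > 0) & (mean > 0)
    score = np.zeros(matrix.shape[0])
    if usable.sum() >= 2:
        fit = loess_fit(np.log10(mean[usable]), np.log10(var[usable]), span=0.3, degree=2)
        sd_pred = np.sqrt(np.clip(10.0**fit, 1e-12, None))
        z = (matrix[usable] - mean[usable, None]) / sd_pred[:, None]
        z = np.minimum(z, np.sqrt(n_cells))
        score[usable] = z.var(axis=1, ddof=1)
    elif usable.sum() == 1:
        score[usable] = 1.0
    n_usable = int(usable.sum())
    if n_usable < n:
        warnings.warn(
            f"only {n_usable} genes with usable variance; returning all of them",
            stacklevel=2,
        )
        n = max(n_usable, 1)
    order = np.argsort(-score, kind="stable")
    return gene_ids[order[:n]]


def reduce_dims(matrix: np.ndarray, n_dims: int, seed: int = 0) -> np.ndarray:
    """PCA scores (cells x n_dims) of the gene-standardized matrix.

    Genes are centered and unit-scaled; each component is sign-fixed so its
    largest-magnitude gene loading is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_cells = matrix.shape
    if n_dims >= min(n_cells, n_genes):
        raise ValueError("n_dims must be smaller than both matrix dimensions")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True) if n_cells > 1 else np.ones((n_genes, 1))
    sd = np.where(sd > 0, sd, 1.0)
    X = ((matrix - mean) / sd).T  # cells x genes
    # deterministic thin SVD; scales fine at desk size
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_dims], S[:n_dims], Vt[:n_dims]
    # sign convention on loadings
    flip = np.sign(Vt[np.arange(n_dims), np.argmax(np.abs(Vt), axis=1)])
    flip = np.where(flip == 0, 1.0, flip)
    return U * S * flip


def _snn_graph(emb: np.ndarray, k: int, prune: float) -> ig.Graph:
    n = emb.shape[0]
    k = min(k, n)
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)
    B = sparse.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())), shape=(n, n)
    )
    shared = (B @ B.T).tocoo()
    r, c, s = shared.row, shared.col, shared.data
    keep = r < c
    r, c, s = r[keep], c[keep], s[keep]
    jac = s / (2 * k - s)
    keep = jac >= prune
    g = ig.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_graph(
    embeddings: np.ndarray,
    resolution: float,
    seed: int = 42,
    k: int = 20,
    prune: float = 1.0 / 15.0,
) -> np.ndarray:
    """Shared-nearest-neighbor graph (Jaccard weights) plus Louvain
    modularity clustering at the given resolution."""
    emb = np.asarray(embeddings, dtype=float)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n < k:
        warnings.warn(f"only {n} cells; reducing neighbor count", stacklevel=2)
        k = n
    g = _snn_graph(emb, k, prune)
    ig.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(weights="weight", resolution=float(resolution))
    ig.set_random_number_generator(random)
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# composition


def run_pipeline(counts: CountMatrix, config: PipelineConfig, seed: int = 42) -> ClusteringResult:
    """QC -> filter -> normalize -> HVG(2000) -> PCA -> SNN/Louvain."""
    qc = compute_cell_qc(counts)
    kept = filter_cells(qc, config.filtering)
    if kept.size == 0:
        raise PipelineError("all cells removed by filtering")
    sub = counts.subset_cells(kept)
    norm = normalize(sub, config.normalization)
    # variance-stabilised gene ranking operates on the raw counts of the
    # retained cells; the normalized values are then subset to those genes
    hvgs = select_hvgs(sub.values.astype(float), sub.gene_ids, n=2000)
    pos = pd.Index(sub.gene_ids).get_indexer(hvgs)
    hv = norm[pos, :]
    n_dims = min(config.n_dims, min(hv.shape) - 1)
    if n_dims < 1:
        raise PipelineError("matrix too small for dimensionality reduction")
    emb = reduce_dims(hv, n_dims)
    labels = cluster_graph(emb, config.resolution, seed=seed)
    return ClusteringResult(
        kept_cell_ids=kept,
        labels=labels,
        k=int(np.unique(labels).size),
        pipeline_id=config.pipeline_id,
        dataset_id=counts.dataset_id,
    )


def _run_seed(seed: int, d_idx: int, p_idx: int) -> int:
    ss = np.random.SeedSequence([int(seed), d_idx, p_idx])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_grid(
    datasets: list,
    grid: PipelineGrid,
    seed: int = 42,
    cache: dict | None = None,
) -> list:
    """Execute every pipeline on every dataset.

    Returns one entry per dataset x pipeline: a ``ClusteringResult`` or, on
    failure, a dict error record with the reason.  ``cache`` (keyed on
    (dataset_id, pipeline_id)) makes the sweep resumable.
    """
    if not datasets or len(grid) == 0:
        raise ValueError("datasets and grid must be non-empty")
    out = []
    for d_idx, counts in enumerate(datasets):
        # upstream stages shared by many configs are computed once
        stage: dict = {"qc": None, "filter": {}, "norm": {}, "emb": {}}
        for p_idx, config in enumerate(grid.configs):
            key = (counts.dataset_id, config.pipeline_id)
            if cache is not None and key in cache:
                out.append(cache[key])
                continue
            try:
                res = _staged_run(counts, config, _run_seed(seed, d_idx, p_idx), stage)
            except PipelineError as exc:
                res = {
                    "dataset_id": counts.dataset_id,
                    "pipeline_id": config.pipeline_id,
                    "error": str(exc),
                }
            if cache is not None:
                cache[key] = res
            out.append(res)
    return out


def _staged_run(counts: CountMatrix, config: PipelineConfig, seed: int, stage: dict) -> ClusteringResult:
    """Same composition as :func:`run_pipeline`, memoising the stages shared
    between grid configs (QC, filtering, normalization+HVG, embedding)."""
    if stage["qc"] is None:
        stage["qc"] = compute_cell_qc(counts)
    if config.filtering not in stage["filter"]:
        stage["filter"][config.filtering] = filter_cells(stage["qc"], config.filtering)
    kept = stage["filter"][config.filtering]
    if kept.size == 0:
        raise PipelineError("all cells removed by filtering")
    nkey = (config.filtering, config.normalization)
    if nkey not in stage["norm"]:
        sub = counts.subset_cells(kept)
        hkey = ("hvg", config.filtering)
        if hkey not in stage["filter"]:
            stage["filter"][hkey] = select_hvgs(sub.values.astype(float), sub.gene_ids, n=2000)
        norm = normalize(sub, config.normalization)
        pos = pd.Index(sub.gene_ids).get_indexer(stage["filter"][hkey])
        stage["norm"][nkey] = norm[pos, :]
    hv = stage["norm"][nkey]
    n_dims = min(config.n_dims, min(hv.shape) - 1)
    if n_dims < 1:
        raise PipelineError("matrix too small for dimensionality reduction")
    ekey = (*nkey, n_dims)
    if ekey not in stage["emb"]:
        stage["emb"][ekey] = reduce_dims(hv, n_dims)
    labels = cluster_graph(stage["emb"][ekey], config.resolution, seed=seed)
    return ClusteringResult(
        kept_cell_ids=kept,
        labels=labels,
        k=int(np.unique(labels).size),
        pipeline_id=config.pipeline_id,
        dataset_id=counts.dataset_id,
    )
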