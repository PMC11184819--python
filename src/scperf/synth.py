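"""Synthetic scRNA-seq datasets and planted-signal performance tables.

Counts are drawn from a gamma-Poisson (negative binomial) mixture over
planted cell clusters: each cluster has its own expression profile obtained
by perturbing a shared base profile with log2 fold changes on a random
subset of genes.  Library sizes are log-normal, a fraction of genes is
flagged mitochondrial / protein-coding, and a fraction of cells is given an
inflated mitochondrial load so that QC filtering rules have targets.

Performance tables with a known dataset x pipeline interaction structure
are generated separately, so the meta-learning stage can be validated
against a planted ground truth without running any clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CountMatrix, PipelineGrid, encode_pipeline_grid

__all__ = [
    "SynthDatasetConfig",
    "SyntheticDataset",
    "PlantedPerformanceModel",
    "generate_dataset",
    "generate_dataset_collection",
    "generate_gene_sets",
    "generate_performance_table",
]

# share of expression carried by mitochondrial genes in a typical cell and
# in a damaged/outlier cell
MITO_EXPR_SHARE = 0.05
OUTLIER_MITO_SHARE = 0.30


@dataclass
class SynthDatasetConfig:
    n_cells: int = 500
    n_genes: int = 1500
    n_clusters: int = 4
    cluster_props: np.ndarray | None = None
    de_prob: float = 0.1
    logfc_sd: float = 1.0
    libsize_mu_log: float = np.log(5000.0)
    libsize_sd_log: float = 0.35
    nb_dispersion: float = 2.0
    mito_frac: float = 0.02
    coding_frac: float = 0.8
    outlier_cell_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise ValueError("counts must be positive")
        if self.n_clusters > self.n_cells:
            raise ValueError("more clusters than cells")
        if self.cluster_props is None:
            self.cluster_props = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_props = np.asarray(self.cluster_props, dtype=float)
        if self.cluster_props.size != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(self.cluster_props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1")
        for name in ("de_prob", "mito_frac", "coding_frac", "outlier_cell_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    true_labels: pd.Series  # index cell_id -> cluster id
    gene_flags: pd.DataFrame
    cluster_profiles: np.ndarray = field(default=None, repr=False)  # genes x K
    config: SynthDatasetConfig | None = None

    @property
    def dataset_id(self) -> str:
        return self.counts.dataset_id


@dataclass
class PlantedPerformanceModel:
    beta_dataset: np.ndarray
    beta_pipeline: np.ndarray
    beta_interaction: np.ndarray  # (n_dataset_features, n_pipeline_features)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_dataset = np.asarray(self.beta_dataset, float)
        self.beta_pipeline = np.asarray(self.beta_pipeline, float)
        self.beta_interaction = np.asarray(self.beta_interaction, float)
        if self.beta_interaction.shape != (self.beta_dataset.size, self.beta_pipeline.size):
            raise ValueError("interaction matrix shape must match main-effect vectors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gene_universe(n_genes: int, mito_frac: float, coding_frac: float, rng: np.random.Generator):
    n_mito = int(round(mito_frac * n_genes))
    mito = np.zeros(n_genes, dtype=bool)
    mito[rng.choice(n_genes, size=n_mito, replace=False)] = True
    coding = rng.random(n_genes) < coding_frac
    gene_ids = np.array(
        [
            (f"MT-G{i:05d}" if mito[i] else f"G{i:05d}")
            for i in range(n_genes)
        ],
        dtype=object,
    )
    flags = pd.DataFrame({"mito": mito, "coding": coding}, index=gene_ids)
    return gene_ids, flags


def _base_profile(n_genes: int, mito: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    p /= p.sum()
    return _set_mito_share(p, mito, MITO_EXPR_SHARE)


def _set_mito_share(p: np.ndarray, mito: np.ndarray, share: float) -> np.ndarray:
    p = p.copy()
    if mito.any() and mito.sum() < mito.size:
        p[mito] *= share / max(p[mito].sum(), 1e-300)
        p[~mito] *= (1.0 - share) / max(p[~mito].sum(), 1e-300)
    return p / p.sum()


def generate_dataset(
    config: SynthDatasetConfig,
    dataset_id: str = "synth",
    gene_universe: tuple | None = None,
) -> SyntheticDataset:
    """Draw one negative-binomial cluster-mixture dataset.

    ``gene_universe`` (gene ids + flags) may be passed in so that every
    dataset of a collection shares the same genes.
    """
    rng = np.random.default_rng(config.seed)
    if gene_universe is None:
        gene_ids, flags = _gene_universe(config.n_genes, config.mito_frac, config.coding_frac, rng)
    else:
        gene_ids, flags = gene_universe
        if gene_ids.size != config.n_genes:
            raise ValueError("gene universe size must equal n_genes")
    mito = flags["mito"].to_numpy(bool)

    base = _base_profile(config.n_genes, mito, rng)
    K = config.n_clusters
    profiles = np.tile(base[:, None], (1, K))
    for c in range(K):
        de = rng.random(config.n_genes) < config.de_prob
        lfc = rng.normal(0.0, config.logfc_sd, size=config.n_genes)
        profiles[de, c] *= 2.0 ** lfc[de]
        profiles[:, c] = _set_mito_share(profiles[:, c] / profiles[:, c].sum(), mito, MITO_EXPR_SHARE)

    labels = rng.choice(K, size=config.n_cells, p=config.cluster_props)
    libsize = rng.lognormal(config.libsize_mu_log, config.libsize_sd_log, size=config.n_cells)
    outlier = rng.random(config.n_cells) < config.outlier_cell_frac

    cell_profiles = profiles[:, labels]
    if outlier.any() and mito.any():
        boosted = np.stack(
            [_set_mito_share(cell_profiles[:, i], mito, OUTLIER_MITO_SHARE) for i in np.where(outlier)[0]],
            axis=1,
        )
        cell_profiles = cell_profiles.copy()
        cell_profiles[:, outlier] = boosted

    mean = cell_profiles * libsize[None, :]
    theta = config.nb_dispersion
    if np.isfinite(theta):
        lam = rng.gamma(shape=theta, scale=mean / theta)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = np.array([f"{dataset_id}:cell{i:05d}" for i in range(config.n_cells)], dtype=object)
    cm = CountMatrix(counts, gene_ids, cell_ids, flags, dataset_id=dataset_id)
    return SyntheticDataset(
        counts=cm,
        true_labels=pd.Series(labels, index=cell_ids, name="label"),
        gene_flags=flags,
        cluster_profiles=profiles,
        config=config,
    )


def generate_dataset_collection(
    n_datasets: int,
    ranges: dict | None = None,
    seed: int = 0,
    base_config: SynthDatasetConfig | None = None,
) -> list[SyntheticDataset]:
    """Draw a heterogeneous collection of datasets on a shared gene universe.

    ``ranges`` maps config field names to (min, max); each dataset's value
    is drawn uniformly (integers for count-valued fields).  Unlisted fields
    come from ``base_config``.
    """
    if n_datasets < 2:
        raise ValueError("a collection needs at least 2 datasets")
    ranges = dict(ranges or {})
    for name, rg in ranges.items():
        if len(rg) != 2 or rg[1] < rg[0]:
            raise ValueError(f"invalid range for {name!r}: {rg}")
    if "n_genes" in ranges:
        raise ValueError("the gene universe is shared; n_genes cannot vary")
    base = base_config or SynthDatasetConfig()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_datasets + 1)
    urng = np.random.default_rng(child[0])
    gene_ids, flags = _gene_universe(
        base.n_genes, base.mito_frac, base.coding_frac, np.random.default_rng(child[0])
    )
    int_fields = {"n_cells", "n_clusters"}
    out = []
    for i in range(n_datasets):
        kwargs = {
            f: getattr(base, f)
            for f in (
                "n_cells n_genes n_clusters de_prob logfc_sd libsize_mu_log "
                "libsize_sd_log nb_dispersion mito_frac coding_frac outlier_cell_frac"
            ).split()
        }
        for name, (lo, hi) in ranges.items():
            v = urng.uniform(lo, hi)
            kwargs[name] = int(round(v)) if name in int_fields else float(v)
        kwargs["seed"] = int(child[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        cfg = SynthDatasetConfig(cluster_props=None, **kwargs)
        out.append(generate_dataset(cfg, dataset_id=f"synth-{i:03d}", gene_universe=(gene_ids, flags)))
    return out


def generate_gene_sets(
    collection: list[SyntheticDataset],
    n_random: int = 20,
    size_range: tuple[int, int] = (20, 100),
    markers_per_cluster: int = 40,
    seed: int = 0,
) -> dict[str, list]:
    """Gene-set collection over the shared gene universe: random sets plus
    one set of top planted up-regulated genes per (dataset, cluster)."""
    rng = np.random.default_rng(seed)
    gene_ids = collection[0].counts.gene_ids
    sets: dict[str, list] = {}
    for i in range(n_random):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"RANDOM_{i:03d}"] = list(rng.choice(gene_ids, size=size, replace=False))
    for ds in collection:
        prof = ds.cluster_profiles
        rest = prof.mean(axis=1, keepdims=True)
        for c in range(prof.shape[1]):
            lfc = np.log2((prof[:, c] + 1e-12) / (rest[:, 0] + 1e-12))
            top = np.argsort(-lfc, kind="stable")[:markers_per_cluster]
            sets[f"MARKERS_{ds.dataset_id}_c{c}"] = list(gene_ids[top])
    return sets


def generate_performance_table(
    model: PlantedPerformanceModel,
    dataset_features: pd.DataFrame,
    pipeline_grid: PipelineGrid,
    metric_name: str = "metric",
) -> pd.DataFrame:
    """Planted performance values per dataset x pipeline row.

    value = f_d . beta_dataset + g_p . beta_pipeline + f_d^T B g_p + noise,
    with ``g_p`` the linear (one-hot + standardized numeric) encoding of the
    pipeline grid.
    """
    F = dataset_features.to_numpy(float)
    G = encode_pipeline_grid(pipeline_grid, style="linear").to_numpy(float)
    if F.shape[1] != model.beta_dataset.size:
        raise ValueError("dataset feature count does not match beta_dataset")
    if G.shape[1] != model.beta_pipeline.size:
        raise ValueError("pipeline encoding width does not match beta_pipeline")
    V = (
        F @ model.beta_dataset[:, None]
        + (G @ model.beta_pipeline)[None, :]
        + F @ model.beta_interaction @ G.T
    )
    rng = np.random.default_rng(model.seed)
    if model.noise_sd > 0:
        V = V + rng.normal(0.0, model.noise_sd, size=V.shape)
    d_ids = np.repeat(dataset_features.index.to_numpy(object), len(pipeline_grid))
    p_ids = np.tile(np.asarray(pipeline_grid.pipeline_ids, dtype=object), len(dataset_features))
    return pd.DataFrame(
        {"dataset_id": d_ids, "pipeline_id": p_ids, metric_name: V.ravel()}
    )
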