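"""Disk formats: Matrix Market count triplets, GMT gene sets, label TSVs,
YAML configs and clustering-result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .engine import ClusteringResult, CountMatrix

__all__ = [
    "write_dataset",
    "read_counts",
    "read_labels",
    "read_gmt",
    "write_gmt",
    "write_clusterings",
    "read_clusterings",
    "read_yaml",
    "write_yaml",
]


def write_dataset(dataset, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx + genes.tsv + barcodes.tsv (CellRanger-style
    triplet); synthetic datasets also get labels.tsv and config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = getattr(dataset, "counts", dataset)
    spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts.values))
    genes = counts.gene_flags.reset_index()
    genes.columns = ["gene_id", "mito", "coding"]
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(counts.cell_ids, name="cell_id").to_csv(outdir / "barcodes.tsv", sep="\t", index=False)
    labels = getattr(dataset, "true_labels", None)
    if labels is not None:
        labels.rename_axis("cell_id").reset_index().to_csv(outdir / "labels.tsv", sep="\t", index=False)
    cfg = getattr(dataset, "config", None)
    if cfg is not None:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v.item() if isinstance(v, np.generic) else v)
            for k, v in vars(cfg).items()
        }
        write_yaml(d, outdir / "config.yaml")
    return outdir


def read_counts(indir: str | Path, dataset_id: str | None = None) -> CountMatrix:
    indir = Path(indir)
    m = spio.mmread(indir / "matrix.mtx")
    values = np.asarray(m.todense() if sparse.issparse(m) else m).astype(np.int64)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    flags = pd.DataFrame(
        {"mito": genes["mito"].astype(bool), "coding": genes["coding"].astype(bool)},
        index=genes["gene_id"].astype(str),
    )
    return CountMatrix(
        values,
        genes["gene_id"].astype(str).to_numpy(object),
        barcodes.iloc[:, 0].astype(str).to_numpy(object),
        flags,
        dataset_id=dataset_id or indir.name,
    )


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="label")


def read_gmt(path: str | Path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError("GMT lines need name, description and >=1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *map(str, sets[name])]) + "\n")


def write_clusterings(results: list, path: str | Path) -> None:
    """Long TSV (dataset_id, pipeline_id, cell_id, label); error records get
    a single row with label 'ERROR:<reason>'."""
    rows = []
    for res in results:
        if isinstance(res, dict):
            rows.append((res["dataset_id"], res["pipeline_id"], "", f"ERROR:{res['error']}"))
            continue
        for cid, lab in zip(res.kept_cell_ids, res.labels):
            rows.append((res.dataset_id, res.pipeline_id, cid, int(lab)))
    pd.DataFrame(rows, columns=["dataset_id", "pipeline_id", "cell_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_clusterings(path: str | Path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "label": str})
    out = []
    for (did, pid), block in df.groupby(["dataset_id", "pipeline_id"], sort=False):
        lab = block["label"].astype(str)
        if lab.str.startswith("ERROR:").any():
            out.append({"dataset_id": did, "pipeline_id": pid, "error": lab.iloc[0][6:]})
            continue
        labels = lab.astype(int).to_numpy()
        out.append(
            ClusteringResult(
                kept_cell_ids=block["cell_id"].to_numpy(object),
                labels=labels,
                k=int(np.unique(labels).size),
                pipeline_id=pid,
                dataset_id=did,
            )
        )
    return out


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
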