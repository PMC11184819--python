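import numpy as np
import pandas as pd
import pytest

import scperf as sp


@pytest.fixture(scope="session")
def small_dataset() -> sp.SyntheticDataset:
    """300 cells x 800 genes, 3 well-separated planted clusters."""
    cfg = sp.SynthDatasetConfig(
        n_cells=300, n_genes=800, n_clusters=3, logfc_sd=1.5, seed=11
    )
    return sp.generate_dataset(cfg, dataset_id="small")


@pytest.fixture(scope="session")
def small_qc(small_dataset) -> pd.DataFrame:
    return sp.compute_cell_qc(small_dataset.counts)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def toy_counts(values, mito_idx=(), dataset_id="toy") -> sp.CountMatrix:
    """Dense toy CountMatrix with simple gene/cell ids."""
    values = np.asarray(values)
    g, c = values.shape
    gene_ids = np.array([f"g{i}" for i in range(g)], dtype=object)
    mito = np.zeros(g, dtype=bool)
    mito[list(mito_idx)] = True
    flags = pd.DataFrame({"mito": mito, "coding": ~mito}, index=gene_ids)
    return sp.CountMatrix(
        values,
        gene_ids,
        np.array([f"c{j}" for j in range(c)], dtype=object),
        flags,
        dataset_id=dataset_id,
    )
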