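import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichescore.dataset import ExpressionDataset
from nichescore.preprocess import lognormalize


def make_dataset(
    counts,
    gene_ids=None,
    cell_ids=None,
    sample="s1",
    condition="sham",
    clusters=None,
    samples=None,
    conditions=None,
    lognormed=False,
):
    """Build a small ExpressionDataset from a dense genes x cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i:02d}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i:03d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample": samples if samples is not None else [sample] * n_cells,
            "condition": conditions if conditions is not None else [condition] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if clusters is not None:
        meta["cluster"] = list(clusters)
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        gene_ids=pd.Index(gene_ids),
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
    )
    if lognormed:
        ds = lognormalize(ds)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def smoke_data():
    """One smoke-preset dataset shared across tests that only read it."""
    import nichescore as ns

    ds, truth = ns.generate_dataset(ns.preset("smoke", seed=11))
    return lognormalize(ds), truth
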