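"""Readers and writers for the standard text formats the pipeline consumes.

Counts travel as a 10x-style triplet: a Matrix Market file (genes x cells)
plus ``features.tsv`` / ``barcodes.tsv`` without headers, and a cell-metadata
TSV with a header (cell_id, sample, lineage, condition[, cluster]).  Gene
sets use GMT; regulons and ligand-receptor source tables are delimited text.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import (
    DEFAULT_MITO_PREFIX,
    DEFAULT_REPORTER,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    NichescoreError,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "read_lr_table",
    "read_ortholog_table",
    "FormatError",
]


class FormatError(NichescoreError):
    """An input file did not match the expected structure."""


def _read_single_column(path: str) -> list[str]:
    table = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return table.iloc[:, 0].tolist()


def read_counts(
    matrix_path: str,
    features_path: str,
    barcodes_path: str,
    meta_path: str,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    reporter: str = DEFAULT_REPORTER,
    exclusion_genes: Sequence[str] = (),
) -> ExpressionDataset:
    """Load a Matrix Market triplet plus cell metadata into a dataset.

    Gene flags are initialised here: ``is_mito`` from the (case-sensitive)
    symbol prefix, ``is_reporter`` from equality with ``reporter`` and
    ``is_excluded_contaminant`` from membership in ``exclusion_genes``.
    """
    counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
    genes = _read_single_column(features_path)
    barcodes = _read_single_column(barcodes_path)
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path} has {counts.shape[0]} rows but "
            f"{features_path} lists {len(genes)} features"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path} has {counts.shape[1]} columns but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    gene_index = pd.Index(genes)
    if gene_index.has_duplicates:
        dups = gene_index[gene_index.duplicated()].unique().tolist()
        raise FormatError(f"{features_path} contains duplicate symbols: {dups}")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FormatError(f"{meta_path} lacks a cell_id column")
    meta = meta.set_index("cell_id")
    missing = [b for b in barcodes if b not in meta.index]
    if missing:
        raise FormatError(
            f"{meta_path} is missing {len(missing)} barcodes, "
            f"first 10: {missing[:10]}"
        )

    gene_meta = pd.DataFrame(index=gene_index)
    gene_meta["is_mito"] = gene_index.str.startswith(mito_prefix)
    gene_meta["is_reporter"] = gene_index == reporter
    gene_meta["is_excluded_contaminant"] = gene_index.isin(list(exclusion_genes))

    return ExpressionDataset(
        counts=counts,
        gene_ids=gene_index,
        cell_ids=pd.Index(barcodes),
        cell_meta=meta,
        gene_meta=gene_meta,
    )


def write_counts(ds: ExpressionDataset, out_dir: str, prefix: str = "") -> dict:
    """Write the triplet + metadata TSV; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, prefix + "matrix.mtx"),
        "features": os.path.join(out_dir, prefix + "features.tsv"),
        "barcodes": os.path.join(out_dir, prefix + "barcodes.tsv"),
        "meta": os.path.join(out_dir, prefix + "meta.tsv"),
    }
    coo = ds.counts.tocoo()
    scipy.io.mmwrite(
        paths["matrix"],
        sp.coo_matrix(
            (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
        ),
    )
    pd.Series(ds.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(ds.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    meta = ds.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(paths["meta"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT file; the description field carries the category tag."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, category, *genes = parts
            genes = [g for g in genes if g]
            collection.add(GeneSet(name=name, genes=tuple(genes), category=category))
    return collection


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.category, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Regulons and ligand-receptor tables
# ---------------------------------------------------------------------------

def read_regulons(path: str):
    """Read regulons from TSV with columns tf, target, mode, weight."""
    from .metacells import Regulon

    table = pd.read_csv(path, sep="\t")
    required = {"tf", "target", "mode", "weight"}
    if not required.issubset(table.columns):
        raise FormatError(
            f"{path} lacks columns {sorted(required - set(table.columns))}"
        )
    regulons = []
    for tf, grp in table.groupby("tf", sort=True):
        targets = [
            (row.target, int(row.mode), float(row.weight))
            for row in grp.itertuples()
        ]
        regulons.append(Regulon(tf=tf, targets=tuple(targets)))
    return regulons


def write_regulons(regulons, path: str) -> None:
    rows = [
        {"tf": reg.tf, "target": t, "mode": m, "weight": w}
        for reg in regulons
        for (t, m, w) in reg.targets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lr_table(path: str) -> pd.DataFrame:
    """Read a ligand-receptor pair table (CSV with ligand,receptor columns)."""
    table = pd.read_csv(path)
    if not {"ligand", "receptor"}.issubset(table.columns):
        raise FormatError(f"{path} needs 'ligand' and 'receptor' columns")
    return table[["ligand", "receptor"]].astype(str)


def read_ortholog_table(path: str) -> pd.DataFrame:
    """Read a two-column symbol mapping (CSV with from,to columns)."""
    table = pd.read_csv(path)
    if not {"from", "to"}.issubset(table.columns):
        raise FormatError(f"{path} needs 'from' and 'to' columns")
    return table[["from", "to"]].astype(str)
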