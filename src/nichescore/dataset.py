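"""Core in-memory containers for lineage-traced single-cell data.

The central object is :class:`ExpressionDataset`: a sparse genes x cells
count matrix with a lazily computed log-normalized layer and two metadata
tables (per cell: sample, lineage, condition, optional cluster; per gene:
mitochondrial / contaminant / reporter flags).  Every pipeline stage
consumes and returns this object, so all validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "GeneSetCollection",
    "NichescoreError",
    "ValidationError",
]


class NichescoreError(Exception):
    """Base class for structured errors raised by this package."""


class ValidationError(NichescoreError):
    """A container or argument violated an invariant."""


REQUIRED_CELL_COLUMNS = ("sample", "condition")
GENE_FLAG_COLUMNS = ("is_mito", "is_excluded_contaminant", "is_reporter")

#: default exclusion genes marking immune / erythrocyte contamination
DEFAULT_EXCLUSION_GENES = ("Ptprc", "Hba-a1", "Hba-a2", "Hbb-bs")
DEFAULT_MITO_PREFIX = "mt-"
DEFAULT_REPORTER = "tdTomato"


def _as_csr(matrix) -> sp.csr_matrix:
    if not sp.issparse(matrix):
        matrix = sp.csr_matrix(np.asarray(matrix))
    return matrix.tocsr()


@dataclass
class ExpressionDataset:
    """Sparse count matrix (genes x cells) plus metadata.

    Parameters
    ----------
    counts:
        Non-negative integral counts, genes in rows, cells in columns.
    gene_ids:
        Unique gene symbols (case-sensitive), one per row of ``counts``.
    cell_ids:
        Unique cell barcodes, one per column of ``counts``.
    cell_meta:
        Table indexed by cell id with at least ``sample`` and ``condition``
        columns; ``lineage`` and ``cluster`` are optional.
    gene_meta:
        Table indexed by gene id with boolean flags ``is_mito``,
        ``is_excluded_contaminant`` and ``is_reporter``.  Missing flags are
        initialised to ``False``.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame = None  # type: ignore[assignment]
    lognorm: sp.csr_matrix | None = field(default=None, repr=False)
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        self.counts = _as_csr(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, name="gene_id")
        self.cell_ids = pd.Index(self.cell_ids, name="cell_id")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.gene_ids)
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"counts has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"counts has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:10]}")
        if self.cell_ids.has_duplicates:
            dups = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell barcodes: {dups[:10]}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts contain non-integral entries")
        missing_cells = self.cell_ids.difference(self.cell_meta.index)
        if len(missing_cells):
            raise ValidationError(
                "cell_meta is missing barcodes: "
                f"{missing_cells[:10].tolist()}"
            )
        for col in REQUIRED_CELL_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell_meta lacks required column {col!r}")
        # align metadata to matrix order; add default flags
        self.cell_meta = self.cell_meta.loc[self.cell_ids].copy()
        self.gene_meta = self.gene_meta.reindex(self.gene_ids).copy()
        for col in GENE_FLAG_COLUMNS:
            if col not in self.gene_meta.columns:
                self.gene_meta[col] = False
            self.gene_meta[col] = self.gene_meta[col].fillna(False).astype(bool)
        if self.lognorm is not None:
            self.lognorm = _as_csr(self.lognorm)
            if self.lognorm.shape != self.counts.shape:
                raise ValidationError("lognorm shape differs from counts shape")

    # -- basic properties --------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def clusters(self) -> pd.Series | None:
        if "cluster" in self.cell_meta.columns:
            return self.cell_meta["cluster"]
        return None

    def gene_index(self, symbol: str) -> int:
        """Row index of an exact, case-sensitive gene symbol."""
        idx = self.gene_ids.get_indexer([symbol])
        if idx[0] < 0:
            raise KeyError(f"gene {symbol!r} not in dataset")
        return int(idx[0])

    def has_gene(self, symbol: str) -> bool:
        return symbol in self.gene_ids

    def require_lognorm(self) -> sp.csr_matrix:
        if self.lognorm is None:
            raise ValidationError(
                "log-normalized layer missing; run lognormalize() first"
            )
        return self.lognorm

    # -- subsetting --------------------------------------------------------
    def subset_cells(self, keep: np.ndarray) -> "ExpressionDataset":
        """Dataset restricted to cells where ``keep`` is True (or an index array)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionDataset(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep],
            gene_meta=self.gene_meta,
            lognorm=None if self.lognorm is None else self.lognorm[:, keep],
            scale_factor=self.scale_factor,
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionDataset(
            counts=self.counts[keep, :],
            gene_ids=self.gene_ids[keep],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[keep],
            lognorm=None if self.lognorm is None else self.lognorm[keep, :],
            scale_factor=self.scale_factor,
        )

    def with_clusters(self, labels: Sequence) -> "ExpressionDataset":
        """Copy of the dataset with a cluster column assigned."""
        labels = pd.Series(np.asarray(labels, dtype=object), index=self.cell_ids)
        out = self.copy()
        out.cell_meta = out.cell_meta.copy()
        out.cell_meta["cluster"] = labels
        return out

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            lognorm=None if self.lognorm is None else self.lognorm.copy(),
            scale_factor=self.scale_factor,
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=self.gene_meta.copy(),
        )
        if self.lognorm is not None:
            adata.layers["lognorm"] = self.lognorm.T.tocsr()
        return adata


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with a category tag (e.g. "collagens", "s_phase")."""

    name: str
    genes: tuple
    category: str = ""

    def __post_init__(self):
        genes = tuple(self.genes)
        if not genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            seen, dups = set(), []
            for g in genes:
                if g in seen:
                    dups.append(g)
                seen.add(g)
            raise ValidationError(
                f"gene set {self.name!r} has duplicate symbols: {dups}"
            )
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet | None":
        """Restrict to symbols present in ``universe``; None if empty."""
        uni = set(universe)
        kept = tuple(g for g in self.genes if g in uni)
        if not kept:
            return None
        return GeneSet(self.name, kept, self.category)


class GeneSetCollection:
    """Ordered collection of :class:`GeneSet` keyed by name."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValidationError(f"duplicate gene set name {gs.name!r}")
        self._sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def by_category(self, *categories: str) -> list[GeneSet]:
        return [gs for gs in self if gs.category in categories]

    def union_genes(self, *categories: str) -> tuple:
        """Deduplicated union (insertion order) of the sets in ``categories``."""
        seen: dict[str, None] = {}
        for gs in self.by_category(*categories):
            for g in gs.genes:
                seen.setdefault(g)
        return tuple(seen)
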