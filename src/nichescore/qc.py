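"""Cell-level quality control and the reporter-transcript lineage-purity filter.

Two stages act here.  First, conventional QC removes cells with too few or
too many detected genes, a mitochondrial read fraction above the cutoff
(strict ``>``), or any read in an exclusion gene (Ptprc, hemoglobins —
immune / erythrocyte contamination).  Second, the purity filter keeps only
genetically traced cells: per (cluster, sample) group it computes the
conditional probability of detecting the reporter transcript
(``condGeneProb``); groups below the threshold are dropped wholesale, then
any remaining cell without a single reporter read is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_EXCLUSION_GENES,
    DEFAULT_REPORTER,
    ExpressionDataset,
    NichescoreError,
    ValidationError,
)

__all__ = [
    "QcThresholds",
    "QcReport",
    "PurityReport",
    "filter_cells_qc",
    "cond_gene_prob",
    "filter_lineage_purity",
]


@dataclass(frozen=True)
class QcThresholds:
    """Cell QC cutoffs.

    ``min_features`` may be a single integer or a per-sample mapping (the
    lower cutoff was tuned per sample in practice); the feature-count window
    is inclusive on both ends, the mitochondrial rule is strict ``>``.
    """

    min_features: int | Mapping[str, int] = 500
    max_features: int = 5000
    max_mito_fraction: float = 0.06
    exclusion_genes: tuple = DEFAULT_EXCLUSION_GENES

    def __post_init__(self):
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must lie in [0, 1]")
        mins = (
            self.min_features.values()
            if isinstance(self.min_features, Mapping)
            else [self.min_features]
        )
        for m in mins:
            if m >= self.max_features:
                raise ValidationError("min_features must be < max_features")

    def min_for_sample(self, sample: str) -> int:
        if isinstance(self.min_features, Mapping):
            return int(self.min_features.get(sample, 500))
        return int(self.min_features)


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    removed_low_features: int
    removed_high_features: int
    removed_mito: int
    removed_exclusion: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "low_features",
                    "high_features",
                    "mito_fraction",
                    "exclusion_gene",
                ],
                "cells_removed": [
                    self.removed_low_features,
                    self.removed_high_features,
                    self.removed_mito,
                    self.removed_exclusion,
                ],
            }
        )


def filter_cells_qc(
    ds: ExpressionDataset, thresholds: QcThresholds | None = None
) -> tuple[ExpressionDataset, QcReport]:
    """Apply all QC criteria jointly on the raw counts of the input.

    Criteria are evaluated on the unfiltered matrix (not sequentially
    re-computed), so per-criterion removal counts may overlap.
    """
    thresholds = thresholds or QcThresholds()
    counts = ds.counts.tocsc()
    n_detected = np.diff(counts.indptr)  # nonzero entries per cell
    total = np.asarray(counts.sum(axis=0)).ravel()

    mito_rows = ds.gene_meta["is_mito"].to_numpy()
    mito_total = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    excl_rows = ds.gene_ids.get_indexer(
        [g for g in thresholds.exclusion_genes if g in ds.gene_ids]
    )
    if len(excl_rows):
        excl_hits = np.asarray((counts[excl_rows, :] > 0).sum(axis=0)).ravel() > 0
    else:
        excl_hits = np.zeros(ds.n_cells, dtype=bool)

    min_per_cell = np.array(
        [thresholds.min_for_sample(s) for s in ds.cell_meta["sample"]]
    )
    low = n_detected < min_per_cell
    high = n_detected > thresholds.max_features
    mito_bad = mito_frac > thresholds.max_mito_fraction

    keep = ~(low | high | mito_bad | excl_hits)
    report = QcReport(
        n_input=ds.n_cells,
        n_retained=int(keep.sum()),
        removed_low_features=int(low.sum()),
        removed_high_features=int(high.sum()),
        removed_mito=int(mito_bad.sum()),
        removed_exclusion=int(excl_hits.sum()),
    )
    if report.n_retained == 0:
        raise NichescoreError(
            "QC removed every cell; per-criterion counts: "
            f"low_features={report.removed_low_features}, "
            f"high_features={report.removed_high_features}, "
            f"mito={report.removed_mito}, exclusion={report.removed_exclusion}"
        )
    return ds.subset_cells(keep), report


def cond_gene_prob(
    ds: ExpressionDataset,
    gene: str = DEFAULT_REPORTER,
    cluster_labels: Sequence | None = None,
    sample_labels: Sequence | None = None,
) -> pd.DataFrame:
    """Per-(cluster, sample) fraction of cells detecting ``gene``.

    Returns a table with columns cluster, sample, cond_gene_prob, n_cells.
    Only groups that actually contain cells appear.
    """
    if not ds.has_gene(gene):
        raise KeyError(f"gene {gene!r} not in dataset")
    clusters = (
        pd.Series(cluster_labels, index=ds.cell_ids)
        if cluster_labels is not None
        else ds.clusters
    )
    if clusters is None or clusters.isna().any():
        raise ValidationError("every cell needs a cluster label")
    samples = (
        pd.Series(sample_labels, index=ds.cell_ids)
        if sample_labels is not None
        else ds.cell_meta["sample"]
    )
    detected = np.asarray(
        (ds.counts[ds.gene_index(gene), :] > 0).todense()
    ).ravel()
    table = pd.DataFrame(
        {
            "cluster": clusters.to_numpy(),
            "sample": samples.to_numpy(),
            "detected": detected,
        }
    )
    grouped = (
        table.groupby(["cluster", "sample"], sort=True, observed=True)
        .agg(cond_gene_prob=("detected", "mean"), n_cells=("detected", "size"))
        .reset_index()
    )
    return grouped


@dataclass
class PurityReport:
    threshold: float
    groups_removed: pd.DataFrame
    n_removed_group_rule: int
    n_removed_zero_read: int
    n_retained: int


def filter_lineage_purity(
    ds: ExpressionDataset,
    reporter: str = DEFAULT_REPORTER,
    threshold: float = 0.8,
) -> tuple[ExpressionDataset, PurityReport]:
    """Keep genetically traced cells only.

    Rule 1: every (cluster, sample) group whose reporter detection
    probability is below ``threshold`` is removed entirely.  Rule 2: from
    the remainder, any cell with zero reporter reads is removed.  The order
    is fixed — rule 1 before rule 2.
    """
    purity = cond_gene_prob(ds, reporter)
    bad = purity[purity["cond_gene_prob"] < threshold]
    bad_keys = set(zip(bad["cluster"], bad["sample"]))

    clusters = ds.clusters.to_numpy()
    samples = ds.cell_meta["sample"].to_numpy()
    in_bad_group = np.array(
        [(c, s) in bad_keys for c, s in zip(clusters, samples)]
    )

    reporter_counts = np.asarray(
        ds.counts[ds.gene_index(reporter), :].todense()
    ).ravel()
    zero_read = (reporter_counts == 0) & ~in_bad_group

    keep = ~(in_bad_group | zero_read)
    report = PurityReport(
        threshold=threshold,
        groups_removed=bad.reset_index(drop=True),
        n_removed_group_rule=int(in_bad_group.sum()),
        n_removed_zero_read=int(zero_read.sum()),
        n_retained=int(keep.sum()),
    )
    return ds.subset_cells(keep), report
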