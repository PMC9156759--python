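"""Threshold-gated marker / differential-expression detection and
cross-dataset cluster similarity.

Candidate genes must clear two pre-test gates — a minimum fraction of
expressing cells in either group (min.pct) and a minimum absolute log fold
change — before any p-value is computed.  The test is a Wilcoxon rank-sum
on log-normalized expression: exact (full enumeration over group
assignments, midranks for ties) when the pooled group is small, the
tie-corrected normal approximation otherwise.  The gates and the
Benjamini-Hochberg correction, not the test statistic itself, carry the
scientific content of the procedure.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .composition import bh_fdr
from .dataset import ExpressionDataset, NichescoreError, ValidationError
from .preprocess import lognormalize, select_variable_genes

__all__ = [
    "rank_sum_pvalue",
    "marker_genes",
    "deg_between_conditions",
    "cluster_similarity",
]

EXACT_MAX_POOLED = 16  # full enumeration up to choose(16, 8) = 12870 splits


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Pooled size <= EXACT_MAX_POOLED: exact permutation distribution of the
    rank-sum with midranks, so ties are handled correctly.  Larger groups:
    scipy's tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValidationError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([x, y])
    if n + m <= EXACT_MAX_POOLED:
        ranks = rankdata(pooled)
        observed = ranks[:n].sum()
        mean_w = n * (n + m + 1) / 2.0
        obs_dev = abs(observed - mean_w)
        total = comb(n + m, n)
        extreme = 0
        for subset in combinations(range(n + m), n):
            w = ranks[list(subset)].sum()
            if abs(w - mean_w) >= obs_dev - 1e-12:
                extreme += 1
        return extreme / total
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _log_fc(lognorm_in: np.ndarray, lognorm_out: np.ndarray) -> np.ndarray:
    """ln(mean(expm1(in)) + 1) - ln(mean(expm1(out)) + 1), per gene."""
    mean_in = np.expm1(lognorm_in).mean(axis=1)
    mean_out = np.expm1(lognorm_out).mean(axis=1)
    return np.log1p(mean_in) - np.log1p(mean_out)


def _deg_table(
    lognorm_a: np.ndarray,
    lognorm_b: np.ndarray,
    gene_ids,
    min_pct: float,
    logfc_threshold: float,
) -> pd.DataFrame:
    """Gate then test group A against group B; genes as rows of inputs."""
    pct_in = (lognorm_a > 0).mean(axis=1)
    pct_out = (lognorm_b > 0).mean(axis=1)
    log_fc = _log_fc(lognorm_a, lognorm_b)
    gate = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
        np.abs(log_fc) >= logfc_threshold
    )
    idx = np.flatnonzero(gate)
    p = np.array(
        [rank_sum_pvalue(lognorm_a[g], lognorm_b[g]) for g in idx]
    )
    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids)[idx],
            "log_fc": log_fc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p": p,
        }
    )
    if len(table):
        table["p_adj"] = bh_fdr(np.clip(table["p"].to_numpy(), 1e-300, 1.0))
        table = table.sort_values(
            ["p_adj", "log_fc"], ascending=[True, False], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["p_adj"] = np.array([], dtype=np.float64)
    return table


def marker_genes(
    ds: ExpressionDataset,
    cluster_labels=None,
    min_pct: float = 0.3,
    logfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker detection per cluster with min.pct / logFC gates."""
    lognorm = ds.require_lognorm()
    clusters = (
        pd.Series(np.asarray(cluster_labels), index=ds.cell_ids)
        if cluster_labels is not None
        else ds.clusters
    )
    if clusters is None:
        raise ValidationError("cluster labels required")
    labels = clusters.to_numpy()
    names = np.unique(labels)
    if len(names) < 2:
        raise NichescoreError("need >= 2 clusters for marker detection")
    dense = np.asarray(lognorm.todense())
    tables = []
    for name in names:
        in_mask = labels == name
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {name!r} has < 3 cells; skipped")
            continue
        table = _deg_table(
            dense[:, in_mask],
            dense[:, ~in_mask],
            ds.gene_ids,
            min_pct,
            logfc_threshold,
        )
        table.insert(1, "cluster", name)
        tables.append(table)
    if not tables:
        raise NichescoreError("no cluster had enough cells")
    return pd.concat(tables, ignore_index=True)


def deg_between_conditions(
    ds: ExpressionDataset,
    cluster,
    cond_a,
    cond_b,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.3,
    alpha_adj: float = 0.01,
) -> pd.DataFrame:
    """Condition B vs condition A within one cluster; keeps p_adj < alpha_adj.

    ``log_fc`` is positive for genes higher in ``cond_b``.
    """
    lognorm = ds.require_lognorm()
    clusters = ds.clusters
    if clusters is None:
        raise ValidationError("cluster labels required")
    in_cluster = clusters.to_numpy() == cluster
    cond = ds.cell_meta["condition"].to_numpy()
    mask_a = in_cluster & (cond == cond_a)
    mask_b = in_cluster & (cond == cond_b)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise NichescoreError(
            f"cluster {cluster!r} lacks cells in one of the conditions "
            f"({cond_a!r}: {int(mask_a.sum())}, {cond_b!r}: {int(mask_b.sum())})"
        )
    dense = np.asarray(lognorm.todense())
    table = _deg_table(
        dense[:, mask_b], dense[:, mask_a], ds.gene_ids, min_pct, logfc_threshold
    )
    table.insert(1, "cluster", cluster)
    return table[table["p_adj"] < alpha_adj].reset_index(drop=True)


def cluster_similarity(
    datasets,
    n_var_genes: int = 500,
    scale_factor: float = 1e4,
) -> pd.DataFrame:
    """Pearson similarity of cluster-averaged profiles across datasets.

    ``datasets`` is a list of (label, ExpressionDataset with clusters).
    Datasets are merged on their shared gene universe, the most variable
    genes of the merged data selected, and cluster-average log-normalized
    profiles correlated.  Row/column names are "label:cluster".
    """
    from .dataset import ExpressionDataset as _EDS
    import scipy.sparse as sp

    if not datasets:
        raise ValidationError("no datasets given")
    shared = None
    for _, ds in datasets:
        genes = set(ds.gene_ids)
        shared = genes if shared is None else shared & genes
    shared = sorted(shared)
    if len(shared) < 2:
        raise NichescoreError("shared gene universe is too small")
    if len(shared) < n_var_genes:
        warnings.warn(
            f"gene intersection ({len(shared)}) < n_var_genes ({n_var_genes}); "
            "using the full intersection"
        )
        n_var_genes = len(shared)

    mats, metas, cell_ids = [], [], []
    for label, ds in datasets:
        rows = ds.gene_ids.get_indexer(shared)
        mats.append(ds.counts[rows, :])
        meta = ds.cell_meta.copy()
        if "cluster" not in meta.columns or meta["cluster"].isna().any():
            raise ValidationError(f"dataset {label!r} lacks cluster labels")
        meta = meta.assign(
            cluster=[f"{label}:{c}" for c in meta["cluster"]],
        )
        meta.index = [f"{label}:{c}" for c in meta.index]
        metas.append(meta)
        cell_ids.extend(meta.index)
    merged = _EDS(
        counts=sp.hstack(mats).tocsr(),
        gene_ids=pd.Index(shared),
        cell_ids=pd.Index(cell_ids),
        cell_meta=pd.concat(metas),
    )
    merged = lognormalize(merged, scale_factor=scale_factor)
    var_genes = select_variable_genes(merged, n=n_var_genes)
    rows = merged.gene_ids.get_indexer(var_genes)
    dense = np.asarray(merged.lognorm[rows, :].todense())

    labels = merged.cell_meta["cluster"].to_numpy()
    names = np.unique(labels)
    if len(names) < 2:
        raise NichescoreError("need >= 2 clusters in total")
    profiles = np.column_stack(
        [dense[:, labels == name].mean(axis=1) for name in names]
    )
    corr = np.corrcoef(profiles.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)
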