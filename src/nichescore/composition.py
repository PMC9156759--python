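"""Cluster-composition analysis between two conditions.

Per cluster the statistic is the log2 fold difference of normalized
proportions (log2FD), with a small pseudo-proportion keeping it finite when
a cluster is absent from one condition.  Significance comes from a
label-permutation null (add-one p estimator, two-sided on |log2FD|) with
Benjamini-Hochberg correction across clusters, and the dual decision rule
FDR < 0.05 and |log2FD| > 0.58 (~1.5-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dataset import NichescoreError, ValidationError

__all__ = [
    "cluster_proportions",
    "proportion_shift_test",
    "flag_significant",
    "bh_fdr",
    "CompositionResult",
]

DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_ABS_LOG2FD = 0.58


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_proportions(cluster_labels, condition_labels) -> pd.DataFrame:
    """Normalized per-condition cluster proportions.

    Rows are clusters, columns conditions; each column sums to 1.  Clusters
    absent from a condition get proportion 0.
    """
    clusters = np.asarray(cluster_labels)
    conditions = np.asarray(condition_labels)
    if clusters.shape != conditions.shape:
        raise ValidationError("cluster and condition labels differ in length")
    table = pd.crosstab(pd.Series(clusters, name="cluster"),
                        pd.Series(conditions, name="condition"))
    if (table.sum(axis=0) == 0).any():
        raise NichescoreError("a condition has no cells")
    return table / table.sum(axis=0)


@dataclass
class CompositionResult:
    """Per-cluster shift statistics between condition A (reference) and B."""

    table: pd.DataFrame  # cluster, prop_a, prop_b, log2fd, p_perm, fdr, significant
    condition_a: str
    condition_b: str
    n_permutations: int
    fdr_max: float = DEFAULT_FDR_MAX
    min_abs_log2fd: float = DEFAULT_MIN_ABS_LOG2FD


def _log2fd(count_a, count_b, n_a: int, n_b: int) -> np.ndarray:
    """log2((prop_b + 0.5/n_b) / (prop_a + 0.5/n_a)) — pseudo keeps it finite.

    Computed as a difference of logs so that swapping the two conditions
    negates the statistic bit-exactly (tie comparisons in the permutation
    null then behave symmetrically).
    """
    prop_a = np.asarray(count_a, dtype=np.float64) / n_a
    prop_b = np.asarray(count_b, dtype=np.float64) / n_b
    return np.log2(prop_b + 0.5 / n_b) - np.log2(prop_a + 0.5 / n_a)


def proportion_shift_test(
    cluster_labels,
    condition_labels,
    n_permutations: int = 1000,
    seed: int = 0,
    condition_a: str | None = None,
    condition_b: str | None = None,
    stratify_by=None,
) -> CompositionResult:
    """Permutation test for composition shifts between two conditions.

    The null redistributes condition labels across cells (optionally within
    strata) ``n_permutations`` times; the two-sided p-value per cluster is
    the add-one estimator on |log2FD|.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    clusters = np.asarray(cluster_labels)
    conditions = np.asarray(condition_labels)
    uniq_cond = sorted(pd.unique(conditions).tolist())
    if len(uniq_cond) != 2 and (condition_a is None or condition_b is None):
        raise NichescoreError(
            f"{len(uniq_cond)} conditions found; run pairwise comparisons "
            "with condition_a/condition_b set"
        )
    if condition_a is None:
        condition_a, condition_b = uniq_cond
    mask = np.isin(conditions, [condition_a, condition_b])
    clusters, conditions = clusters[mask], conditions[mask]

    cluster_names, cluster_codes = np.unique(clusters, return_inverse=True)
    k = len(cluster_names)
    is_b = conditions == condition_b
    n_a = int((~is_b).sum())
    n_b = int(is_b.sum())
    if n_a == 0 or n_b == 0:
        raise NichescoreError("a condition has no cells")

    count_a = np.bincount(cluster_codes[~is_b], minlength=k)
    count_b = np.bincount(cluster_codes[is_b], minlength=k)
    obs = _log2fd(count_a, count_b, n_a, n_b)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=np.int64)
    abs_obs = np.abs(obs)
    strata = (
        [np.arange(len(cluster_codes))]
        if stratify_by is None
        else [
            np.flatnonzero(np.asarray(stratify_by)[mask] == s)
            for s in pd.unique(np.asarray(stratify_by)[mask])
        ]
    )
    perm_is_b = is_b.copy()
    for _ in range(n_permutations):
        for idx in strata:
            perm_is_b[idx] = is_b[idx][rng.permutation(len(idx))]
        pa = np.bincount(cluster_codes[~perm_is_b], minlength=k)
        pb = np.bincount(cluster_codes[perm_is_b], minlength=k)
        null = _log2fd(pa, pb, n_a, n_b)
        exceed += np.abs(null) >= abs_obs

    p_perm = (1.0 + exceed) / (1.0 + n_permutations)
    fdr = bh_fdr(p_perm)
    table = pd.DataFrame(
        {
            "cluster": cluster_names,
            "prop_a": count_a / n_a,
            "prop_b": count_b / n_b,
            "log2fd": obs,
            "p_perm": p_perm,
            "fdr": fdr,
        }
    )
    result = CompositionResult(
        table=table,
        condition_a=str(condition_a),
        condition_b=str(condition_b),
        n_permutations=n_permutations,
    )
    return flag_significant(result)


def flag_significant(
    result: CompositionResult,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_log2fd: float = DEFAULT_MIN_ABS_LOG2FD,
) -> CompositionResult:
    """(Re-)apply the dual rule: FDR strictly below ``fdr_max`` and
    |log2FD| strictly above ``min_abs_log2fd``.  Idempotent."""
    table = result.table.copy()
    table["significant"] = (table["fdr"] < fdr_max) & (
        table["log2fd"].abs() > min_abs_log2fd
    )
    return CompositionResult(
        table=table,
        condition_a=result.condition_a,
        condition_b=result.condition_b,
        n_permutations=result.n_permutations,
        fdr_max=fdr_max,
        min_abs_log2fd=min_abs_log2fd,
    )
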