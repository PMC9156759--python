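"""Binned-control module scoring and cell-cycle phase assignment.

The module score of a gene set is, per cell, the mean log-normalized
expression of the set's genes minus the mean over a pool of control genes.
Controls are expression-matched: all genes are ranked by their dataset-wide
average expression and cut into equal-frequency bins; each target gene
contributes ``n_ctrl`` control genes sampled from its own bin.  This cancels
depth and coverage effects, so the score reflects coordinated up- or
down-regulation of the set rather than overall expression level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .dataset import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    NichescoreError,
    ValidationError,
)

__all__ = [
    "ScoreVector",
    "PhaseCall",
    "module_score",
    "score_battery",
    "cell_cycle_phase",
    "ECM_AGGREGATE_CATEGORIES",
    "ECM_SCORE_NAME",
]

#: matrisome divisions pooled into the aggregate ECM score
ECM_AGGREGATE_CATEGORIES = ("collagens", "glycoproteins", "proteoglycans")
ECM_SCORE_NAME = "ECM"


@dataclass
class ScoreVector:
    """Per-cell module score with the parameters that produced it."""

    values: np.ndarray
    score_name: str
    gene_set_name: str
    n_bins: int
    n_ctrl: int
    seed: int
    cell_ids: pd.Index = None  # type: ignore[assignment]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.cell_ids, name=self.score_name)


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene; ties go to the lower bin."""
    ranks = rankdata(avg, method="min")  # ties share the lower rank
    return ((ranks - 1) * n_bins // len(avg)).astype(np.int64)


def module_score(
    ds: ExpressionDataset,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Binned-control score of ``gs`` per cell on the log-normalized layer.

    Deterministic given ``seed``.  Gene-set symbols absent from the dataset
    are dropped with a warning; an entirely absent set is an error.
    Control genes are drawn without replacement from the target's expression
    bin; a bin smaller than ``n_ctrl`` falls back to sampling with
    replacement (and warns), which matters only for small gene universes.
    """
    lognorm = ds.require_lognorm()
    present = [g for g in gs.genes if ds.has_gene(g)]
    missing = [g for g in gs.genes if not ds.has_gene(g)]
    if missing:
        warnings.warn(
            f"gene set {gs.name!r}: {len(missing)} symbols absent from the "
            f"dataset were dropped (first 5: {missing[:5]})"
        )
    if not present:
        raise NichescoreError(
            f"no gene of set {gs.name!r} is present in the dataset"
        )
    n_bins = min(n_bins, ds.n_genes)
    avg = np.asarray(lognorm.mean(axis=1)).ravel()
    bins = _expression_bins(avg, n_bins)

    rng = np.random.default_rng(seed)
    target_idx = np.array([ds.gene_index(g) for g in present])
    control_idx: list[np.ndarray] = []
    warned_small = False
    for gi in target_idx:
        pool = np.flatnonzero(bins == bins[gi])
        if len(pool) >= n_ctrl:
            chosen = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            if not warned_small:
                warnings.warn(
                    f"expression bin of size {len(pool)} < n_ctrl={n_ctrl}; "
                    "sampling controls with replacement"
                )
                warned_small = True
            chosen = rng.choice(pool, size=n_ctrl, replace=True)
        control_idx.append(chosen)
    controls = np.concatenate(control_idx)

    target_mean = np.asarray(lognorm[target_idx, :].mean(axis=0)).ravel()
    # pooled control mean counts repeated picks with multiplicity
    ctrl_sum = np.zeros(ds.n_cells)
    uniq, mult = np.unique(controls, return_counts=True)
    ctrl_matrix = lognorm[uniq, :]
    ctrl_sum = np.asarray(
        sp.diags(mult.astype(np.float64)).dot(ctrl_matrix).sum(axis=0)
    ).ravel()
    ctrl_mean = ctrl_sum / len(controls)

    return ScoreVector(
        values=target_mean - ctrl_mean,
        score_name=gs.name,
        gene_set_name=gs.name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        cell_ids=ds.cell_ids,
    )


def score_battery(
    ds: ExpressionDataset,
    collection: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every set in ``collection`` plus the aggregate ECM score.

    The aggregate pools the union of the collagen, glycoprotein and
    proteoglycan sets (the core matrisome).  A set with no overlap with the
    gene universe is skipped with a warning; it does not abort the battery.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene set collection")
    columns: dict[str, np.ndarray] = {}
    for gs in collection:
        try:
            sv = module_score(ds, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
        except NichescoreError as err:
            warnings.warn(f"skipping score {gs.name!r}: {err}")
            continue
        columns[gs.name] = sv.values
    ecm_genes = collection.union_genes(*ECM_AGGREGATE_CATEGORIES)
    if ecm_genes:
        ecm_set = GeneSet(ECM_SCORE_NAME, ecm_genes, category="ecm_aggregate")
        try:
            sv = module_score(ds, ecm_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
            columns[ECM_SCORE_NAME] = sv.values
        except NichescoreError as err:
            warnings.warn(f"skipping aggregate ECM score: {err}")
    if not columns:
        raise NichescoreError("every gene set failed to score")
    return pd.DataFrame(columns, index=ds.cell_ids)


@dataclass
class PhaseCall:
    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # "G1", "S" or "G2M"
    cell_ids: pd.Index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_score": self.s_score,
                "g2m_score": self.g2m_score,
                "phase": self.phase,
            },
            index=self.cell_ids,
        )


def cell_cycle_phase(
    ds: ExpressionDataset,
    s_genes: GeneSet,
    g2m_genes: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> PhaseCall:
    """S/G2M module scores and the argmax phase call.

    A cell is G1 when both scores are non-positive; otherwise the phase with
    the larger score wins.
    """
    s = module_score(ds, s_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m = module_score(ds, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    phase = np.where(
        (s.values <= 0) & (g2m.values <= 0),
        "G1",
        np.where(s.values > g2m.values, "S", "G2M"),
    )
    return PhaseCall(
        s_score=s.values,
        g2m_score=g2m.values,
        phase=phase,
        cell_ids=ds.cell_ids,
    )
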