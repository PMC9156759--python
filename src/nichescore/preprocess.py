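"""Log-normalization and variance-stabilized highly-variable gene selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataset import ExpressionDataset, ValidationError

__all__ = ["lognormalize", "select_variable_genes"]

DEFAULT_SCALE_FACTOR = 1e4


def lognormalize(
    ds: ExpressionDataset, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionDataset:
    """Populate the log-normalized layer: x' = ln(1 + scale_factor * x / colsum).

    The transformation is column-local (per cell); raw counts are untouched.
    Cells with zero total counts are rejected — QC must run first.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    colsums = np.asarray(ds.counts.sum(axis=0)).ravel()
    if (colsums == 0).any():
        n_zero = int((colsums == 0).sum())
        raise ValidationError(
            f"{n_zero} cells have zero total counts; run QC filtering before "
            "normalization"
        )
    csc = ds.counts.tocsc().astype(np.float64)
    # scale each column by scale_factor / colsum, then log1p on nonzeros
    scale = scale_factor / colsums
    csc.data *= np.repeat(scale, np.diff(csc.indptr))
    np.log1p(csc.data, out=csc.data)
    out = ds.copy()
    out.lognorm = csc.tocsr()
    out.scale_factor = float(scale_factor)
    return out


def _gene_mean_var(counts: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = counts.shape[1]
    mean = np.asarray(counts.mean(axis=1)).ravel()
    sq = counts.copy()
    sq.data = sq.data.astype(np.float64) ** 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_variable_genes(ds: ExpressionDataset, n: int = 2000) -> list[str]:
    """Top ``n`` genes by standardized variance (vst-style selection).

    A mean-variance trend is fit on raw counts by lowess of log10(variance)
    against log10(mean) (span 0.3); counts are standardized against the
    fitted trend, clipped at sqrt(n_cells), and genes are ranked by the
    variance of the clipped values.  Ties break lexicographically, so the
    result is deterministic and invariant to gene order.
    """
    if n > ds.n_genes:
        raise ValidationError(
            f"requested {n} variable genes but dataset has {ds.n_genes}"
        )
    counts = ds.counts.astype(np.float64)
    n_cells = ds.n_cells
    mean, var = _gene_mean_var(counts)
    std_var = np.zeros(ds.n_genes)

    positive = (var > 0) & (mean > 0)
    if positive.sum() >= 2:
        x = np.log10(mean[positive])
        y = np.log10(var[positive])
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = lowess(y, x, frac=0.3, return_sorted=False)
        # degenerate neighborhoods (few distinct means) fall back to the
        # gene's own variance, i.e. a standardized variance near 1
        bad = ~np.isfinite(fitted)
        fitted[bad] = y[bad]
        exp_sd = np.sqrt(10.0**fitted)
        clip_max = np.sqrt(n_cells)

        idx_pos = np.flatnonzero(positive)
        sd_full = np.zeros(ds.n_genes)
        sd_full[idx_pos] = exp_sd
        csr = counts.tocsr()
        for j, g in enumerate(idx_pos):
            sd = sd_full[g]
            if sd <= 0:
                continue
            row = csr.getrow(g)
            vals = row.data
            mu = mean[g]
            z_nonzero = np.clip((vals - mu) / sd, -clip_max, clip_max)
            z_zero = np.clip(-mu / sd, -clip_max, clip_max)
            n_zero = n_cells - vals.size
            total = z_nonzero.sum() + n_zero * z_zero
            total_sq = (z_nonzero**2).sum() + n_zero * z_zero**2
            mean_z = total / n_cells
            std_var[g] = (total_sq - n_cells * mean_z**2) / max(n_cells - 1, 1)

    order = pd.DataFrame({"sv": std_var, "gene": ds.gene_ids}).sort_values(
        ["sv", "gene"], ascending=[False, True], kind="mergesort"
    )
    return order["gene"].head(n).tolist()
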