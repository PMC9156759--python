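"""Meta-cell construction and correlation analyses on meta-cell averages.

Meta-cells are very small, transcriptionally homogeneous groups of cells
obtained by Louvain community detection at a deliberately high resolution
on a shared-nearest-neighbor graph built in PCA space.  Averaging
expression and functional scores within meta-cells suppresses the count
sparsity of individual cells, so Pearson correlations of a score against
genes or against transcription-factor activities become informative.

TF activity here is a signed, weighted mean of z-scored target profiles —
a transparent stand-in with the same interface as enrichment-based activity
inference, so a heavier implementation can be swapped in.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .dataset import ExpressionDataset, NichescoreError, ValidationError
from .preprocess import select_variable_genes

__all__ = [
    "MetaCellTable",
    "Regulon",
    "build_metacells",
    "score_gene_correlation",
    "regulon_activity",
    "score_score_correlation",
    "safe_pearson",
]


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with signed, weighted targets.

    Each target is a (gene symbol, mode, weight) triple with mode +1/-1 and
    weight in (0, 1].
    """

    tf: str
    targets: tuple

    def __post_init__(self):
        if not self.targets:
            raise ValidationError(f"regulon {self.tf!r} has no targets")
        for _, mode, weight in self.targets:
            if mode not in (-1, 1):
                raise ValidationError(f"regulon {self.tf!r}: mode must be +1/-1")
            if not 0 < weight <= 1:
                raise ValidationError(
                    f"regulon {self.tf!r}: weights must lie in (0, 1]"
                )


@dataclass
class MetaCellTable:
    """Cell-to-meta-cell assignment with per-meta-cell averages."""

    assignment: pd.Series  # cell_id -> meta-cell id (retained cells only)
    profiles: pd.DataFrame  # meta-cell x gene averaged lognorm
    score_means: pd.DataFrame  # meta-cell x score
    sizes: pd.Series  # cells per meta-cell

    @property
    def n_metacells(self) -> int:
        return len(self.profiles)


def safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with the convention that constant vectors give r = 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _snn_graph(pcs: np.ndarray, k_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k = min(k_neighbors + 1, n)  # +1: each point is its own neighbor
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    knn = nn.kneighbors(pcs, return_distance=False)
    neighbor_sets = [set(row) for row in knn]
    edges, weights = [], []
    for i in range(n):
        for j in knn[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = shared / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = weights
    return graph


def build_metacells(
    ds: ExpressionDataset,
    scores: pd.DataFrame | None = None,
    n_pcs: int = 20,
    k_neighbors: int = 20,
    resolution: float = 10.0,
    min_size: int = 5,
    n_var_genes: int = 2000,
    seed: int = 0,
) -> MetaCellTable:
    """PCA -> SNN graph -> Louvain at high resolution -> averaged profiles.

    Meta-cells smaller than ``min_size`` are dropped together with their
    cells.  ``scores`` is an optional cells x scores table (e.g. the output
    of :func:`nichescore.scoring.score_battery`) averaged alongside.
    """
    if ds.n_cells < 2 * min_size:
        raise ValidationError("need at least 2*min_size cells")
    lognorm = ds.require_lognorm()
    var_genes = select_variable_genes(ds, n=min(n_var_genes, ds.n_genes))
    rows = ds.gene_ids.get_indexer(var_genes)
    x = np.asarray(lognorm[rows, :].todense()).T  # cells x genes
    # z-scale per gene, clipped to damp outlier cells
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -10, 10)

    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    graph = _snn_graph(pcs, k_neighbors)

    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        communities = graph.community_multilevel(
            weights="weight", resolution=resolution
        )
    finally:
        _pyrandom.setstate(state)
    membership = np.asarray(communities.membership)

    sizes_all = np.bincount(membership)
    kept_ids = np.flatnonzero(sizes_all >= min_size)
    if len(kept_ids) < 2:
        raise NichescoreError(
            f"only {len(kept_ids)} meta-cells of size >= {min_size} found; "
            "lower the resolution or min_size"
        )
    keep_cell = np.isin(membership, kept_ids)
    relabel = {old: new for new, old in enumerate(kept_ids)}
    mc_ids = np.array([relabel[m] for m in membership[keep_cell]])

    assignment = pd.Series(mc_ids, index=ds.cell_ids[keep_cell], name="metacell")
    n_mc = len(kept_ids)
    # averaging matrix: metacell x cell indicator / size
    sizes = np.bincount(mc_ids, minlength=n_mc)
    lognorm_kept = lognorm[:, np.flatnonzero(keep_cell)]
    profile_sum = np.zeros((n_mc, ds.n_genes))
    dense = lognorm_kept.T.tocsr()
    for mc in range(n_mc):
        members = np.flatnonzero(mc_ids == mc)
        profile_sum[mc] = np.asarray(dense[members].mean(axis=0)).ravel()
    profiles = pd.DataFrame(
        profile_sum, index=pd.RangeIndex(n_mc, name="metacell"), columns=ds.gene_ids
    )

    if scores is not None:
        kept_scores = scores.loc[assignment.index]
        score_means = kept_scores.groupby(assignment.values).mean()
        score_means.index.name = "metacell"
    else:
        score_means = pd.DataFrame(index=pd.RangeIndex(n_mc, name="metacell"))

    return MetaCellTable(
        assignment=assignment,
        profiles=profiles,
        score_means=score_means,
        sizes=pd.Series(sizes, index=pd.RangeIndex(n_mc, name="metacell")),
    )


def score_gene_correlation(
    mc: MetaCellTable,
    score_name: str,
    exclude_genes=(),
    top_n: int = 100,
) -> pd.DataFrame:
    """Pearson r between a score and every gene across meta-cells.

    Genes in ``exclude_genes`` — normally the score's own gene set, which
    would trivially dominate — are removed before ranking.  Descending by
    r, ties broken by symbol; constant genes get r = 0.
    """
    if mc.n_metacells < 3:
        raise NichescoreError("need >= 3 meta-cells for correlation")
    if score_name not in mc.score_means.columns:
        raise KeyError(f"score {score_name!r} not in meta-cell score means")
    score = mc.score_means[score_name].to_numpy()
    exclude = set(exclude_genes)
    genes = [g for g in mc.profiles.columns if g not in exclude]
    x = mc.profiles[genes].to_numpy()
    r = _columnwise_pearson(x, score)
    out = pd.DataFrame({"gene": genes, "r": r}).sort_values(
        ["r", "gene"], ascending=[False, True], kind="mergesort"
    )
    return out.head(top_n).reset_index(drop=True)


def _columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson of each column of x against y; constant columns -> 0."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    x_sd = xc.std(axis=0)
    y_sd = yc.std()
    denom = x_sd * y_sd * len(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0
    if y_sd == 0:
        r[:] = 0.0
    return r


def regulon_activity(mc: MetaCellTable, regulons) -> pd.DataFrame:
    """Meta-cell x TF activity: weighted signed mean of z-scored targets.

    activity(m, tf) = sum_t w_t * mode_t * z_t(m) / sum_t w_t over the
    regulon's targets present in the profiles; genes are z-scored across
    meta-cells (constant genes contribute 0).  Regulons with no present
    target are excluded with a warning.
    """
    profiles = mc.profiles
    z = profiles - profiles.mean(axis=0)
    sd = profiles.std(axis=0)
    sd[sd == 0] = np.inf  # constant genes -> z = 0
    z = z / sd

    activities = {}
    for reg in regulons:
        present = [(g, m, w) for (g, m, w) in reg.targets if g in profiles.columns]
        dropped = len(reg.targets) - len(present)
        if not present:
            warnings.warn(
                f"regulon {reg.tf!r} has no targets in the gene universe; excluded"
            )
            continue
        if dropped:
            warnings.warn(f"regulon {reg.tf!r}: {dropped} missing targets dropped")
        wsum = sum(w for (_, _, w) in present)
        acc = np.zeros(mc.n_metacells)
        for g, m, w in present:
            acc += w * m * z[g].to_numpy()
        activities[reg.tf] = acc / wsum
    if not activities:
        raise NichescoreError("no regulon overlapped the gene universe")
    return pd.DataFrame(activities, index=profiles.index)


def score_score_correlation(
    mc: MetaCellTable,
    activities: pd.DataFrame,
    score_name: str,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank TF activities by Pearson correlation with a score across meta-cells."""
    if mc.n_metacells < 3:
        raise NichescoreError("need >= 3 meta-cells for correlation")
    if score_name not in mc.score_means.columns:
        raise KeyError(f"score {score_name!r} not in meta-cell score means")
    if not activities.index.equals(mc.score_means.index):
        raise ValidationError("activities and score means are misaligned")
    score = mc.score_means[score_name].to_numpy()
    r = _columnwise_pearson(activities.to_numpy(), score)
    out = pd.DataFrame({"tf": activities.columns, "r": r}).sort_values(
        ["r", "tf"], ascending=[False, True], kind="mergesort"
    )
    return out.head(top_n).reset_index(drop=True)
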