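"""Consensus ligand-receptor database and cluster-pair crosstalk testing.

The database is the union of several published pair tables; only pairs
backed by at least ``min_sources`` sources survive.  For every ordered
cluster pair and database pair, the interaction score MeanLR is the mean
log-normalized ligand expression in the sender plus the mean receptor
expression in the receiver, halved.  A one-sided permutation test (cells
reassigned to clusters preserving cluster sizes) asks whether the observed
mean is specifically high for that pair.  Differential networks between
two conditions aggregate significant interactions into directed edge
weights and split the participating symbols into up/down gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, NichescoreError, ValidationError

__all__ = [
    "LRDatabase",
    "build_consensus_db",
    "map_orthologs",
    "interaction_test",
    "differential_network",
]


@dataclass
class LRDatabase:
    """Ligand-receptor pairs with per-pair source provenance."""

    pairs: dict  # (ligand, receptor) -> frozenset of source names
    min_sources: int = 1
    n_dropped_unmapped: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ligand": l,
                "receptor": r,
                "n_sources": len(srcs),
                "sources": ",".join(sorted(srcs)),
            }
            for (l, r), srcs in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["ligand", "receptor", "n_sources", "sources"])


def build_consensus_db(source_tables, min_sources: int = 2) -> LRDatabase:
    """Union of source pair tables filtered to >= ``min_sources`` support.

    ``source_tables`` is a list of (name, table) where each table has
    ``ligand`` and ``receptor`` columns (ordered pairs).
    """
    names = [name for name, _ in source_tables]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate source names: {dup}")
    if len(source_tables) < min_sources:
        raise ValidationError(
            f"need >= min_sources={min_sources} source tables, got {len(source_tables)}"
        )
    support: dict[tuple, set] = {}
    for name, table in source_tables:
        for lig, rec in zip(table["ligand"], table["receptor"]):
            support.setdefault((str(lig), str(rec)), set()).add(name)
    pairs = {
        pair: frozenset(srcs)
        for pair, srcs in support.items()
        if len(srcs) >= min_sources
    }
    return LRDatabase(pairs=pairs, min_sources=min_sources)


def map_orthologs(db: LRDatabase, ortholog_table: pd.DataFrame) -> LRDatabase:
    """Translate both pair members through a many-to-one symbol mapping.

    Pairs with any unmapped member are dropped (counted in
    ``n_dropped_unmapped``); one-to-many mapping rows are an error.
    """
    counts = ortholog_table["from"].value_counts()
    ambiguous = counts[counts > 1].index.tolist()
    if ambiguous:
        raise ValidationError(
            f"one-to-many ortholog rows for: {sorted(ambiguous)[:10]}"
        )
    mapping = dict(zip(ortholog_table["from"], ortholog_table["to"]))
    pairs: dict[tuple, frozenset] = {}
    dropped = 0
    for (lig, rec), srcs in db.pairs.items():
        if lig in mapping and rec in mapping:
            key = (mapping[lig], mapping[rec])
            pairs[key] = frozenset(pairs.get(key, frozenset()) | srcs)
        else:
            dropped += 1
    return LRDatabase(
        pairs=pairs, min_sources=db.min_sources, n_dropped_unmapped=dropped
    )


def interaction_test(
    ds: ExpressionDataset,
    db: LRDatabase,
    min_fraction: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of MeanLR for every ordered cluster pair.

    An interaction is testable only if the ligand is detected in at least
    ``min_fraction`` of sender cells and the receptor in at least
    ``min_fraction`` of receiver cells; otherwise the row is reported with
    ``expressed = False`` and no p-value.  The null shuffles cells across
    clusters preserving cluster sizes; p is one-sided (specifically high
    means) with the add-one estimator.
    """
    if len(db) == 0:
        raise ValidationError("empty ligand-receptor database")
    clusters = ds.clusters
    if clusters is None or clusters.isna().any():
        raise ValidationError("every cell needs a cluster label")
    lognorm = ds.require_lognorm()

    cluster_names, codes = np.unique(clusters.to_numpy(), return_inverse=True)
    k = len(cluster_names)
    if k < 2:
        raise NichescoreError("need >= 2 clusters for crosstalk analysis")

    # genes the database actually needs
    needed: list[str] = []
    usable_pairs = []
    for (lig, rec) in sorted(db.pairs):
        if not (ds.has_gene(lig) and ds.has_gene(rec)):
            warnings.warn(
                f"interaction ({lig}, {rec}) skipped: gene absent from dataset"
            )
            continue
        usable_pairs.append((lig, rec))
        needed.extend([lig, rec])
    if not usable_pairs:
        raise NichescoreError("no database pair overlaps the gene universe")
    needed = sorted(set(needed))
    gene_pos = {g: i for i, g in enumerate(needed)}
    rows = ds.gene_ids.get_indexer(needed)
    expr = np.asarray(lognorm[rows, :].todense())  # genes x cells

    sizes = np.bincount(codes, minlength=k)
    indicator = np.zeros((ds.n_cells, k))
    indicator[np.arange(ds.n_cells), codes] = 1.0
    mean_by_cluster = expr @ indicator / sizes  # genes x clusters
    frac_by_cluster = (expr > 0).astype(np.float64) @ indicator / sizes

    rng = np.random.default_rng(seed)
    # null cluster means: permute cell order, same size partition
    null_means = np.empty((n_perm, len(needed), k))
    for p in range(n_perm):
        perm = rng.permutation(ds.n_cells)
        perm_codes = codes[perm]
        ind = np.zeros((ds.n_cells, k))
        ind[np.arange(ds.n_cells), perm_codes] = 1.0
        null_means[p] = expr @ ind / sizes

    records = []
    for si, sender in enumerate(cluster_names):
        for ri, receiver in enumerate(cluster_names):
            for lig, rec in usable_pairs:
                li, ci = gene_pos[lig], gene_pos[rec]
                frac_l = frac_by_cluster[li, si]
                frac_r = frac_by_cluster[ci, ri]
                expressed = frac_l >= min_fraction and frac_r >= min_fraction
                if expressed:
                    mean_lr = 0.5 * (mean_by_cluster[li, si] + mean_by_cluster[ci, ri])
                    null = 0.5 * (null_means[:, li, si] + null_means[:, ci, ri])
                    p_perm = (1.0 + np.sum(null >= mean_lr)) / (1.0 + n_perm)
                    significant = p_perm < alpha
                else:
                    mean_lr, p_perm, significant = np.nan, np.nan, False
                records.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "ligand": lig,
                        "receptor": rec,
                        "expressed": expressed,
                        "mean_lr": mean_lr,
                        "p_perm": p_perm,
                        "expressed_fraction_l": frac_l,
                        "expressed_fraction_r": frac_r,
                        "significant": significant,
                    }
                )
    return pd.DataFrame.from_records(records)


def differential_network(
    results_a: pd.DataFrame, results_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Condition-vs-condition crosstalk change (B minus A).

    Edge weights per directed cluster pair sum MeanLR over significant
    interactions; per-interaction deltas substitute 0 when an interaction
    is absent or not significant in a condition.  The gene-set split emits
    ligand-up/down and receptor-up/down symbol sets, removing any symbol
    appearing on both sides of the same role.
    """
    vocab_a = set(results_a["sender"]) | set(results_a["receiver"])
    vocab_b = set(results_b["sender"]) | set(results_b["receiver"])
    if vocab_a != vocab_b:
        raise ValidationError(
            f"cluster vocabulary mismatch: {sorted(vocab_a ^ vocab_b)}"
        )

    def significant_scores(res: pd.DataFrame) -> pd.Series:
        sig = res[res["significant"] & res["expressed"]]
        return sig.set_index(["sender", "receiver", "ligand", "receptor"])["mean_lr"]

    score_a = significant_scores(results_a)
    score_b = significant_scores(results_b)
    keys = score_a.index.union(score_b.index)
    a_vals = score_a.reindex(keys, fill_value=0.0)
    b_vals = score_b.reindex(keys, fill_value=0.0)
    delta = (b_vals - a_vals).rename("delta_mean_lr")

    inter = delta.reset_index()
    edges = (
        inter.assign(weight_a=a_vals.to_numpy(), weight_b=b_vals.to_numpy())
        .groupby(["sender", "receiver"], sort=True)
        .agg(
            weight_a=("weight_a", "sum"),
            weight_b=("weight_b", "sum"),
            delta_weight=("delta_mean_lr", "sum"),
        )
        .reset_index()
    )

    lig_up = set(inter.loc[inter["delta_mean_lr"] > 0, "ligand"])
    lig_down = set(inter.loc[inter["delta_mean_lr"] < 0, "ligand"])
    rec_up = set(inter.loc[inter["delta_mean_lr"] > 0, "receptor"])
    rec_down = set(inter.loc[inter["delta_mean_lr"] < 0, "receptor"])
    lig_both = lig_up & lig_down
    rec_both = rec_up & rec_down
    gene_sets = {
        "ligand_up": sorted(lig_up - lig_both),
        "ligand_down": sorted(lig_down - lig_both),
        "receptor_up": sorted(rec_up - rec_both),
        "receptor_down": sorted(rec_down - rec_both),
    }
    return edges, gene_sets
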