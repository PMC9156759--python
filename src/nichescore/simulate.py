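"""Synthetic lineage-traced count data with known ground truth.

The generator emulates the statistical structure of a multi-sample,
multi-condition, reporter-sorted single-cell experiment: negative-binomial
counts over a gene universe with mitochondrial genes, immune/erythroid
contaminant markers and a reporter transcript; an injury-scaled ECM
program whose per-cell activity rises with condition severity; planted
score-correlated driver genes and a planted transcription factor; planted
composition shifts; and planted directional ligand-receptor interactions.

Counts follow ``count(g, i) ~ NegBin(mean = lib_i * p_{t(i), g} * m_{g, i},
size = theta)`` where ``p`` is the cell type's normalized rate profile and
``m`` multiplies ECM-program targets and drivers by ``(1 + beta * a_i)``
(``a_i`` the cell's program activity) and ligand/receptor genes by their
fold boost in sender/receiver types.  Reporter counts are Poisson:
``lambda_pos`` for labelled lineage cells (probability
``labeling_efficiency``), an ambient channel (probability ``ambient_rate``
of Poisson(``lambda_ambient``)) otherwise; contaminant types only ever see
the ambient channel.  Mitochondrial genes receive a per-type fraction of
each cell's rate mass.

Every downstream stage has a named preset that plants exactly the effect
that stage is designed to detect (see :data:`PRESETS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import (
    DEFAULT_EXCLUSION_GENES,
    DEFAULT_REPORTER,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    NichescoreError,
    ValidationError,
)
from .metacells import Regulon

__all__ = [
    "SyntheticSpec",
    "CellTypeSpec",
    "SampleSpec",
    "GroundTruth",
    "generate_dataset",
    "generate_lr_fixture",
    "default_gene_sets",
    "default_regulons",
    "preset",
    "PRESETS",
]

# ---------------------------------------------------------------------------
# The synthetic gene universe
# ---------------------------------------------------------------------------
# Membership of the functional sets is illustrative fixture content aligned
# with the generator's planted programs, not a published catalogue.

MITO_GENES = tuple(f"mt-Nd{i}" for i in range(1, 8)) + ("mt-Co1", "mt-Co2", "mt-Cytb")

FIBRILLAR_COLLAGENS = ("Col1a1", "Col1a2", "Col3a1", "Col5a1", "Col5a2", "Col11a1")
NETWORK_COLLAGENS = ("Col4a1", "Col4a2", "Col6a1", "Col6a2", "Col6a3", "Col8a1")
MULTIPLEXIN_COLLAGENS = ("Col15a1", "Col18a1")
COLLAGENS = FIBRILLAR_COLLAGENS + NETWORK_COLLAGENS + MULTIPLEXIN_COLLAGENS
GLYCOPROTEINS = ("Postn", "Comp", "Thbs4", "Fn1", "Sparc", "Fbn1", "Cthrc1", "Eln")
PROTEOGLYCANS = ("Dcn", "Bgn", "Lum", "Vcan", "Aspn", "Fmod")
ECM_PROGRAM_GENES = COLLAGENS + GLYCOPROTEINS + PROTEOGLYCANS

S_PHASE_GENES = ("Mcm3", "Mcm5", "Pcna", "Rrm1", "Gins2", "Cdc45", "Uhrf1", "Slbp")
G2M_GENES = ("Top2a", "Mki67", "Ccnb1", "Cdk1", "Ube2c", "Bub1", "Birc5", "Aurka")
MIGRATION_GENES = tuple(f"Mig{i:02d}" for i in range(1, 11))
ENDMA_GENES = tuple(f"Endma{i:02d}" for i in range(1, 11))

DRIVER_GENES = tuple(f"Drv{i:02d}" for i in range(1, 21))
TF_TARGET_GENES = tuple(f"Tgt{i:02d}" for i in range(1, 11))
PLANTED_TF = "Tead1"

LIGAND_GENES = tuple(f"Lig{i:02d}" for i in range(1, 11))
RECEPTOR_GENES = tuple(f"Rec{i:02d}" for i in range(1, 11))

NAMED_GENES = (
    (DEFAULT_REPORTER,)
    + MITO_GENES
    + DEFAULT_EXCLUSION_GENES
    + ECM_PROGRAM_GENES
    + S_PHASE_GENES
    + G2M_GENES
    + MIGRATION_GENES
    + ENDMA_GENES
    + DRIVER_GENES
    + TF_TARGET_GENES
    + LIGAND_GENES
    + RECEPTOR_GENES
)


@dataclass(frozen=True)
class CellTypeSpec:
    """One synthetic cell type: rate profile modifiers and program behavior."""

    name: str
    lineage: str = "Col1a1"
    traced: bool = True  # lineage-labelled; False = contaminant
    marker_boost: dict = field(default_factory=dict)  # symbol -> fold
    mito_fraction: float = 0.02
    #: condition -> Beta(alpha, beta) parameters of program activity
    activity: dict = field(default_factory=dict)
    program_beta: float = 0.0  # effect multiplier on ECM targets/drivers


@dataclass(frozen=True)
class SampleSpec:
    name: str
    condition: str
    n_cells: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Full study-condition description; the defaults come from the presets."""

    samples: tuple
    cell_types: tuple
    composition: dict  # condition -> {type name: fraction}
    n_filler_genes: int = 400
    lib_mu: float = np.log(5000.0)
    lib_sigma: float = 0.3
    theta: float = 10.0  # negative-binomial size (UMI-scale overdispersion)
    labeling_efficiency: float = 0.95
    ambient_rate: float = 0.01
    lambda_pos: float = 3.0
    lambda_ambient: float = 0.5
    #: (ligand, receptor, sender type, receiver type, fold boost)
    lr_boost: tuple = ()
    #: fraction of cells with elevated mitochondrial content (QC fodder)
    damaged_fraction: float = 0.0
    damaged_mito_fraction: float = 0.15
    #: condition -> {cluster: {gene: fold}} planted condition-response genes
    condition_deg: dict = field(default_factory=dict)
    seed: int = 0
    #: seed of the baseline rate profile; datasets sharing it share their
    #: gene universe and cell-type profiles even when ``seed`` differs
    universe_seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ValidationError("spec has no cell types")
        if self.n_filler_genes < 0:
            raise ValidationError("n_filler_genes must be >= 0")
        if not self.samples:
            raise ValidationError("spec has no samples")
        type_names = {t.name for t in self.cell_types}
        for cond, comp in self.composition.items():
            total = sum(comp.values())
            if not np.isclose(total, 1.0):
                raise ValidationError(
                    f"composition for {cond!r} sums to {total}, not 1"
                )
            unknown = set(comp) - type_names
            if unknown:
                raise ValidationError(f"unknown cell types in composition: {unknown}")
        for s in self.samples:
            if s.condition not in self.composition:
                raise ValidationError(f"no composition vector for {s.condition!r}")
        for value, name in [
            (self.labeling_efficiency, "labeling_efficiency"),
            (self.ambient_rate, "ambient_rate"),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.theta <= 0:
            raise ValidationError("theta must be positive")
        for t in self.cell_types:
            if t.program_beta < 0:
                raise ValidationError("program_beta must be >= 0")
            if not 0 <= t.mito_fraction < 1:
                raise ValidationError("mito_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Per-cell truth plus the lists of planted effects."""

    cells: pd.DataFrame  # index cell_id: cell_type, lineage, labeled, activity
    drivers: tuple = DRIVER_GENES
    ecm_targets: tuple = ECM_PROGRAM_GENES
    planted_tf: str = PLANTED_TF
    tf_targets: tuple = TF_TARGET_GENES
    planted_interactions: tuple = ()
    expanded_clusters: tuple = ()


def _gene_universe(n_filler: int) -> pd.Index:
    fillers = tuple(f"Gene{i:04d}" for i in range(1, n_filler + 1))
    return pd.Index(NAMED_GENES + fillers, name="gene_id")


def _base_rates(genes: pd.Index, rng: np.random.Generator) -> np.ndarray:
    """Baseline relative rates: lognormal with boosts for the planted genes.

    The planted programs sit on moderate-to-high baselines so that their
    fold changes are detectable at realistic sequencing depth.
    """
    rates = rng.lognormal(mean=0.0, sigma=1.2, size=len(genes))
    boost = {g: 8.0 for g in ECM_PROGRAM_GENES}
    boost.update({g: 4.0 for g in DRIVER_GENES})
    boost.update({g: 4.0 for g in TF_TARGET_GENES})
    boost.update({g: 3.0 for g in LIGAND_GENES + RECEPTOR_GENES})
    boost.update({g: 2.0 for g in S_PHASE_GENES + G2M_GENES})
    boost.update({g: 2.0 for g in MIGRATION_GENES + ENDMA_GENES})
    for i, g in enumerate(genes):
        if g in boost:
            rates[i] = boost[g] * (1.0 + 0.2 * rng.random())
        elif g == DEFAULT_REPORTER or g.startswith("mt-"):
            rates[i] = 0.0  # filled per cell
        elif g in DEFAULT_EXCLUSION_GENES:
            rates[i] = 0.0  # only contaminant types express these
    return rates


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a full dataset plus ground truth; reproducible given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec.n_filler_genes)
    if len(genes) == 0:
        raise ValidationError("empty gene universe")
    g_pos = {g: i for i, g in enumerate(genes)}
    base = _base_rates(genes, np.random.default_rng(spec.universe_seed))

    mito_idx = np.array([g_pos[g] for g in MITO_GENES])
    reporter_idx = g_pos[DEFAULT_REPORTER]
    program_idx = np.array(
        [g_pos[g] for g in ECM_PROGRAM_GENES + DRIVER_GENES + TF_TARGET_GENES]
    )

    types = {t.name: t for t in spec.cell_types}
    # per-type rate templates (without per-cell program/mito adjustments)
    type_rates = {}
    for t in spec.cell_types:
        r = base.copy()
        for gene, fold in t.marker_boost.items():
            if gene in g_pos:
                r[g_pos[gene]] = max(r[g_pos[gene]], 1.0) * fold
        type_rates[t.name] = r

    lr_by_type: dict[str, list] = {}
    for lig, rec, sender, receiver, fold in spec.lr_boost:
        lr_by_type.setdefault(sender, []).append((g_pos[lig], fold))
        lr_by_type.setdefault(receiver, []).append((g_pos[rec], fold))

    all_counts = []
    meta_rows = []
    truth_rows = []
    cell_ids = []
    cell_no = 0
    for sample in spec.samples:
        comp = spec.composition[sample.condition]
        type_names = sorted(comp)
        probs = np.array([comp[t] for t in type_names])
        drawn = rng.choice(len(type_names), size=sample.n_cells, p=probs)
        libs = rng.lognormal(spec.lib_mu, spec.lib_sigma, size=sample.n_cells)
        damaged = rng.random(sample.n_cells) < spec.damaged_fraction
        cond_deg = spec.condition_deg.get(sample.condition, {})
        for i in range(sample.n_cells):
            t = types[type_names[drawn[i]]]
            rates = type_rates[t.name].copy()
            # program activity
            if t.activity:
                alpha, beta_p = t.activity.get(sample.condition, (1.0, 20.0))
            else:
                alpha, beta_p = 1.0, 20.0
            a = float(rng.beta(alpha, beta_p))
            if t.program_beta > 0:
                rates[program_idx] *= 1.0 + t.program_beta * a
            for gi, fold in lr_by_type.get(t.name, []):
                rates[gi] *= fold
            for gene, fold in cond_deg.get(t.name, {}).items():
                rates[g_pos[gene]] *= fold
            # mitochondrial mass fraction
            f = spec.damaged_mito_fraction if damaged[i] else t.mito_fraction
            rest = rates.sum()
            if f > 0 and rest > 0:
                rates[mito_idx] = (f / (1.0 - f)) * rest / len(mito_idx)
            p = rates / rates.sum()
            mean = libs[i] * p
            nb_p = spec.theta / (spec.theta + mean)
            counts = rng.negative_binomial(spec.theta, nb_p)
            # reporter channel
            labeled = False
            if t.traced and rng.random() < spec.labeling_efficiency:
                labeled = True
                counts[reporter_idx] = rng.poisson(spec.lambda_pos)
            elif rng.random() < spec.ambient_rate:
                counts[reporter_idx] = rng.poisson(spec.lambda_ambient)
            else:
                counts[reporter_idx] = 0
            cell_no += 1
            cid = f"{sample.name}-{cell_no:06d}"
            cell_ids.append(cid)
            all_counts.append(counts)
            meta_rows.append(
                {
                    "cell_id": cid,
                    "sample": sample.name,
                    "lineage": t.lineage if t.traced else "none",
                    "condition": sample.condition,
                    "cluster": t.name,
                }
            )
            truth_rows.append(
                {
                    "cell_id": cid,
                    "cell_type": t.name,
                    "lineage": t.lineage if t.traced else "none",
                    "labeled": labeled,
                    "activity": a,
                }
            )

    matrix = sp.csr_matrix(
        np.asarray(all_counts, dtype=np.int64).T  # genes x cells
    )
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    gene_meta = pd.DataFrame(index=genes)
    gene_meta["is_mito"] = genes.str.startswith("mt-")
    gene_meta["is_reporter"] = genes == DEFAULT_REPORTER
    gene_meta["is_excluded_contaminant"] = genes.isin(DEFAULT_EXCLUSION_GENES)

    ds = ExpressionDataset(
        counts=matrix,
        gene_ids=genes,
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
        gene_meta=gene_meta,
    )
    expanded = _expanded_clusters(spec)
    truth = GroundTruth(
        cells=pd.DataFrame(truth_rows).set_index("cell_id"),
        planted_interactions=tuple(
            (lig, rec, s, r) for (lig, rec, s, r, _) in spec.lr_boost
        ),
        expanded_clusters=expanded,
    )
    return ds, truth


def _expanded_clusters(spec: SyntheticSpec) -> tuple:
    """Cluster names whose share differs >1.5x between any two conditions."""
    conds = list(spec.composition)
    if len(conds) < 2:
        return ()
    out = []
    for t in spec.cell_types:
        shares = [spec.composition[c].get(t.name, 0.0) for c in conds]
        lo, hi = min(shares), max(shares)
        if lo > 0 and hi / lo > 1.5:
            out.append(t.name)
        elif lo == 0 and hi > 0:
            out.append(t.name)
    return tuple(out)


# ---------------------------------------------------------------------------
# Fixture databases
# ---------------------------------------------------------------------------

LR_SOURCE_NAMES = ("cellphonedb", "talklr", "sctensor", "sca", "italk")


def generate_lr_fixture(
    n_pairs: int = 40, seed: int = 0
) -> tuple[list, pd.DataFrame]:
    """Source pair tables with engineered overlap plus the truth key.

    Returns ``(source_tables, key)`` where ``source_tables`` is a list of
    (name, DataFrame) and ``key`` lists each pair with its source count.
    The planted interaction pair appears in three sources, so it survives
    any consensus threshold up to 3.
    """
    rng = np.random.default_rng(seed)
    pairs = [("Lig01", "Rec01")] + [
        (f"Lig{rng.integers(1, 11):02d}", f"Rec{rng.integers(1, 11):02d}")
        for _ in range(n_pairs * 2)
    ]
    # dedupe preserving order, cap at n_pairs
    seen: dict[tuple, None] = {}
    for p in pairs:
        seen.setdefault(p)
    pairs = list(seen)[:n_pairs]

    membership: dict[tuple, set] = {}
    for i, pair in enumerate(pairs):
        if i == 0:
            srcs = set(LR_SOURCE_NAMES[:3])  # the planted pair: 3 sources
        else:
            k = int(rng.integers(1, len(LR_SOURCE_NAMES) + 1))
            srcs = set(rng.choice(LR_SOURCE_NAMES, size=k, replace=False))
        membership[pair] = srcs

    tables = []
    for name in LR_SOURCE_NAMES:
        rows = [
            {"ligand": l, "receptor": r}
            for (l, r), srcs in membership.items()
            if name in srcs
        ]
        tables.append((name, pd.DataFrame(rows, columns=["ligand", "receptor"])))
    key = pd.DataFrame(
        [
            {"ligand": l, "receptor": r, "n_sources": len(srcs)}
            for (l, r), srcs in membership.items()
        ]
    )
    return tables, key


def default_gene_sets() -> GeneSetCollection:
    """Gene sets aligned with the synthetic universe and planted programs."""
    sets = [
        GeneSet("collagens", COLLAGENS, "collagens"),
        GeneSet("glycoproteins", GLYCOPROTEINS, "glycoproteins"),
        GeneSet("proteoglycans", PROTEOGLYCANS, "proteoglycans"),
        GeneSet("fibrillar_collagens", FIBRILLAR_COLLAGENS, "fibrillar"),
        GeneSet("network_collagens", NETWORK_COLLAGENS, "network"),
        GeneSet("multiplexin_collagens", MULTIPLEXIN_COLLAGENS, "multiplexin"),
        GeneSet("s_phase", S_PHASE_GENES, "s_phase"),
        GeneSet("g2m_phase", G2M_GENES, "g2m_phase"),
        GeneSet("migration", MIGRATION_GENES, "migration"),
        GeneSet("endma", ENDMA_GENES, "endma"),
    ]
    return GeneSetCollection(sets)


def default_regulons(n_null: int = 50, seed: int = 0) -> list:
    """The planted TF regulon plus null regulons over filler genes."""
    rng = np.random.default_rng(seed)
    regs = [
        Regulon(
            tf=PLANTED_TF,
            targets=tuple((g, 1, 1.0) for g in TF_TARGET_GENES),
        )
    ]
    for i in range(1, n_null + 1):
        size = int(rng.integers(5, 11))
        targets = tuple(
            (f"Gene{int(rng.integers(1, 401)):04d}", int(rng.choice([-1, 1])), 1.0)
            for _ in range(size)
        )
        # deduplicate target symbols within the regulon
        uniq = {}
        for g, m, w in targets:
            uniq.setdefault(g, (g, m, w))
        regs.append(Regulon(tf=f"NullTf{i:02d}", targets=tuple(uniq.values())))
    return regs


# ---------------------------------------------------------------------------
# Presets: the study conditions each pipeline stage is exercised under
# ---------------------------------------------------------------------------

_FIB_ACTIVITY = {"sham": (1.0, 5.0), "TAC14": (5.0, 2.0), "TAC28": (5.0, 2.0)}
_QUIET_ACTIVITY = {"sham": (1.0, 20.0), "TAC14": (1.0, 20.0), "TAC28": (1.0, 20.0)}


def _fib(name="Fib1", lineage="Col1a1", beta=2.0, activity=_FIB_ACTIVITY, **kw):
    markers = {"Gene0009": 6.0, "Gene0011": 4.0}
    markers.update(kw.pop("marker_boost", {}))
    return CellTypeSpec(
        name=name,
        lineage=lineage,
        marker_boost=markers,
        activity=activity,
        program_beta=beta,
        **kw,
    )


def _endo(name="Endo", **kw):
    markers = {"Gene0001": 6.0, "Gene0002": 6.0, "Gene0003": 4.0}
    markers.update(kw.pop("marker_boost", {}))
    return CellTypeSpec(
        name=name,
        lineage="Cdh5",
        marker_boost=markers,
        activity=_QUIET_ACTIVITY,
        program_beta=0.5,
        **kw,
    )


def _mural(name="Mural", **kw):
    markers = {"Gene0004": 6.0, "Gene0005": 6.0, "Gene0006": 4.0}
    markers.update(kw.pop("marker_boost", {}))
    return CellTypeSpec(
        name=name,
        lineage="Myh11",
        marker_boost=markers,
        activity=_QUIET_ACTIVITY,
        program_beta=0.5,
        **kw,
    )


def _contaminant(name="Contam", **kw):
    markers = {"Gene0007": 8.0, "Gene0008": 8.0}
    markers.update(kw.pop("marker_boost", {}))
    return CellTypeSpec(
        name=name,
        lineage="",
        traced=False,
        marker_boost=markers,
        activity=_QUIET_ACTIVITY,
        **kw,
    )


def _immune(name="Immune", **kw):
    # expresses the exclusion genes: removed by QC, not by purity filtering
    markers = {"Ptprc": 50.0, "Hba-a1": 20.0}
    markers.update(kw.pop("marker_boost", {}))
    return CellTypeSpec(
        name=name, lineage="", traced=False, marker_boost=markers,
        activity=_QUIET_ACTIVITY, **kw,
    )


def _purity_preset(seed: int) -> SyntheticSpec:
    """Lineage-purity filtering: one reporter-negative contaminant cluster."""
    comp = {"Fib1": 0.4, "Endo": 0.25, "Mural": 0.2, "Contam": 0.15}
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", 1700),
            SampleSpec("tac14_1", "TAC14", 1700),
            SampleSpec("tac28_1", "TAC28", 1600),
        ),
        cell_types=(_fib(), _endo(), _mural(), _contaminant()),
        composition={"sham": comp, "TAC14": comp, "TAC28": comp},
        n_filler_genes=200,
        labeling_efficiency=0.95,
        ambient_rate=0.01,
        lambda_pos=3.0,
        lambda_ambient=0.5,
        seed=seed,
    )


def _ecm_preset(seed: int) -> SyntheticSpec:
    """Module scoring: a single fibroblast type with injury-scaled program."""
    comp = {"Fib1": 1.0}
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", 1000),
            SampleSpec("tac14_1", "TAC14", 1000),
        ),
        cell_types=(_fib(beta=2.0),),
        composition={"sham": comp, "TAC14": comp},
        n_filler_genes=1000,
        seed=seed,
    )


def _drivers_preset(seed: int) -> SyntheticSpec:
    """Score-gene correlation: 20 drivers among ~1000 genes, 3000 cells."""
    comp = {"Fib1": 1.0}
    n_named = len(NAMED_GENES)
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", 1500),
            SampleSpec("tac14_1", "TAC14", 1500),
        ),
        cell_types=(_fib(beta=2.0),),
        composition={"sham": comp, "TAC14": comp},
        n_filler_genes=max(1000 - n_named, 0),
        seed=seed,
    )


def _composition_preset(seed: int, n_per_condition: int = 2000) -> SyntheticSpec:
    """Composition shift: one cluster triples its share after injury."""
    sham = {"Fib1": 0.225, "ECM-Fib": 0.1, "Endo": 0.225, "Mural": 0.225, "Fib2": 0.225}
    tac = {"Fib1": 0.175, "ECM-Fib": 0.3, "Endo": 0.175, "Mural": 0.175, "Fib2": 0.175}
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", n_per_condition),
            SampleSpec("tac14_1", "TAC14", n_per_condition),
        ),
        cell_types=(
            _fib("Fib1"),
            _fib("ECM-Fib", beta=3.0, marker_boost={"Postn": 3.0, "Comp": 3.0}),
            _endo(),
            _mural(),
            _fib("Fib2", marker_boost={"Gene0010": 6.0}),
        ),
        composition={"sham": sham, "TAC14": tac},
        n_filler_genes=150,
        seed=seed,
    )


def _crosstalk_preset(seed: int, planted: bool = True) -> SyntheticSpec:
    """Directional LR interaction: ligand high in sender, receptor in receiver."""
    comp = {"Fib1": 0.25, "ECM-Fib": 0.25, "Endo": 0.25, "Mural": 0.25}
    boost = (
        (("Lig01", "Rec01", "ECM-Fib", "Endo", 6.0),) if planted else ()
    )
    return SyntheticSpec(
        samples=(SampleSpec("tac14_1", "TAC14", 2000),),
        cell_types=(
            _fib("Fib1", activity=_QUIET_ACTIVITY, beta=0.0),
            _fib("ECM-Fib", activity=_QUIET_ACTIVITY, beta=0.0,
                 marker_boost={"Postn": 3.0}),
            _endo(),
            _mural(),
        ),
        composition={"TAC14": comp},
        n_filler_genes=150,
        lr_boost=boost,
        seed=seed,
    )


def _null_crosstalk_preset(seed: int) -> SyntheticSpec:
    """Calibration: all clusters drawn from one distribution."""
    comp = {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}
    shared = CellTypeSpec(
        name="A", lineage="Col1a1", activity=_QUIET_ACTIVITY, program_beta=0.0
    )
    types = tuple(replace(shared, name=n) for n in ("A", "B", "C", "D"))
    return SyntheticSpec(
        samples=(SampleSpec("s1", "sham", 1200),),
        cell_types=types,
        composition={"sham": comp},
        n_filler_genes=150,
        seed=seed,
    )


def _markers_preset(seed: int) -> SyntheticSpec:
    """Condition DEG: 30 genes doubled in TAC cells of one cluster."""
    comp = {"Fib1": 0.5, "Endo": 0.5}
    deg_genes = {f"Gene{i:04d}": 2.0 for i in range(101, 131)}
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", 600),
            SampleSpec("tac14_1", "TAC14", 600),
        ),
        cell_types=(
            _fib("Fib1", activity=_QUIET_ACTIVITY, beta=0.0),
            _endo(),
        ),
        composition={"sham": comp, "TAC14": comp},
        n_filler_genes=300,
        condition_deg={"TAC14": {"Fib1": deg_genes}},
        seed=seed,
    )


def _smoke_preset(seed: int) -> SyntheticSpec:
    """Small, fast preset exercising every pipeline stage."""
    sham = {"Fib1": 0.35, "ECM-Fib": 0.1, "Endo": 0.25, "Mural": 0.15,
            "Contam": 0.075, "Immune": 0.075}
    tac = {"Fib1": 0.25, "ECM-Fib": 0.25, "Endo": 0.2, "Mural": 0.15,
           "Contam": 0.075, "Immune": 0.075}
    return SyntheticSpec(
        samples=(
            SampleSpec("sham1", "sham", 400),
            SampleSpec("tac14_1", "TAC14", 400),
        ),
        cell_types=(
            _fib("Fib1"),
            _fib("ECM-Fib", beta=3.0, marker_boost={"Postn": 3.0, "Comp": 3.0}),
            _endo(),
            _mural(),
            _contaminant(),
            _immune(),
        ),
        composition={"sham": sham, "TAC14": tac},
        n_filler_genes=150,
        damaged_fraction=0.05,
        lr_boost=(("Lig01", "Rec01", "ECM-Fib", "Endo", 6.0),),
        seed=seed,
    )


PRESETS = {
    "purity": _purity_preset,
    "ecm": _ecm_preset,
    "drivers": _drivers_preset,
    "composition": _composition_preset,
    "crosstalk": _crosstalk_preset,
    "null_crosstalk": _null_crosstalk_preset,
    "markers": _markers_preset,
    "smoke": _smoke_preset,
}


def preset(name: str, seed: int = 0, **kwargs) -> SyntheticSpec:
    """Look up a named preset spec (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise NichescoreError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name](seed, **kwargs)
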