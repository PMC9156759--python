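"""Pipeline orchestration: config validation, stage sequencing, manifest.

``run_pipeline`` drives the stage sequence
simulate/ingest -> qc -> purity -> score -> composition -> correlate ->
crosstalk -> markers, writing every stage output as TSV (floats fixed to
six significant digits) plus a JSON run manifest with hashes, so a re-run
with the same config and seed reproduces all outputs byte-identically.

A single config seed fans out to per-stage seeds by a fixed counter
scheme — ``stage_seed = (seed * 100 + stage_index) mod 2^31`` — so stages
can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .composition import flag_significant, proportion_shift_test
from .crosstalk import build_consensus_db, differential_network, interaction_test
from .dataset import ExpressionDataset, NichescoreError
from .io import write_counts, write_gmt, write_regulons
from .markers import marker_genes
from .metacells import (
    build_metacells,
    regulon_activity,
    score_gene_correlation,
    score_score_correlation,
)
from .preprocess import lognormalize
from .qc import QcThresholds, filter_cells_qc, filter_lineage_purity
from .scoring import ECM_AGGREGATE_CATEGORIES, ECM_SCORE_NAME, score_battery
from .simulate import (
    default_gene_sets,
    default_regulons,
    generate_dataset,
    generate_lr_fixture,
    preset,
)

__all__ = ["validate_config", "run_pipeline", "ConfigError", "RunManifest"]

FLOAT_FORMAT = "%.6g"

STAGES = (
    "simulate",
    "qc",
    "purity",
    "score",
    "composition",
    "correlate",
    "crosstalk",
    "markers",
)


class ConfigError(NichescoreError):
    """Config validation failed; ``errors`` lists every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(f"- {e}" for e in self.errors))


#: schema: key -> (default, validator or None); None default means required
_SCHEMA: dict = {
    "seed": (None, lambda v: isinstance(v, int) and v >= 0),
    "reporter": (None, lambda v: isinstance(v, str) and v),
    "outdir": ("nichescore_run", lambda v: isinstance(v, str) and v),
    "scale_factor": (1e4, lambda v: isinstance(v, (int, float)) and v > 0),
    "stages": (list(STAGES), lambda v: isinstance(v, list)),
    "simulate": ({}, None),
    "qc": ({}, None),
    "purity": ({}, None),
    "score": ({}, None),
    "composition": ({}, None),
    "correlate": ({}, None),
    "crosstalk": ({}, None),
    "markers": ({}, None),
}

_SECTION_DEFAULTS: dict = {
    "simulate": {"preset": "smoke"},
    "qc": {
        "min_features": 50,
        "max_features": 5000,
        "max_mito_fraction": 0.06,
    },
    "purity": {"threshold": 0.8},
    "score": {"n_bins": 24, "n_ctrl": 100},
    "composition": {
        "n_permutations": 1000,
        "fdr_max": 0.05,
        "min_abs_log2fd": 0.58,
        "condition_a": None,
        "condition_b": None,
    },
    "correlate": {
        "resolution": 10.0,
        "n_pcs": 20,
        "k_neighbors": 20,
        "min_size": 5,
        "top_n_genes": 100,
        "top_n_tfs": 10,
    },
    "crosstalk": {"min_sources": 2, "min_fraction": 0.1, "n_perm": 1000},
    "markers": {"min_pct": 0.3, "logfc_threshold": 0.25},
}


def validate_config(source) -> dict:
    """Validate and normalize a config (path, YAML string or dict).

    All defaults are materialized; unknown keys are rejected; every error
    found is reported at once.  Fails fast — no compute happens here.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        if os.path.exists(str(source)):
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(str(source))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    errors = []
    unknown = set(raw) - set(_SCHEMA)
    for key in sorted(unknown):
        errors.append(f"unknown key {key!r}")
    config: dict = {}
    for key, (default, check) in _SCHEMA.items():
        if key in raw:
            value = raw[key]
        elif default is None:
            errors.append(f"missing required key {key!r}")
            continue
        else:
            value = default
        if check is not None and not check(value):
            errors.append(f"invalid value for {key!r}: {value!r}")
        config[key] = value

    for section, defaults in _SECTION_DEFAULTS.items():
        given = config.get(section, {}) or {}
        if not isinstance(given, dict):
            errors.append(f"section {section!r} must be a mapping")
            given = {}
        unknown = set(given) - set(defaults)
        for key in sorted(unknown):
            errors.append(f"unknown key {section}.{key}")
        merged = {**defaults, **{k: v for k, v in given.items() if k in defaults}}
        config[section] = merged

    comp = config.get("composition", {})
    if comp.get("n_permutations") is not None and comp["n_permutations"] < 0:
        errors.append("composition.n_permutations must be positive")
    if config.get("crosstalk", {}).get("n_perm", 1) < 0:
        errors.append("crosstalk.n_perm must be positive")
    if "stages" in config:
        bad = [s for s in config["stages"] if s not in STAGES]
        for s in bad:
            errors.append(f"unknown stage {s!r}")
    if errors:
        raise ConfigError(errors)
    return config


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)  # per-stage records

    def add_stage(self, name, outputs, n_cells=None, n_genes=None, warnings_=()):
        self.stages.append(
            {
                "stage": name,
                "outputs": {
                    os.path.basename(p): _sha256(p) for p in outputs
                },
                "n_cells": n_cells,
                "n_genes": n_genes,
                "warnings": list(warnings_),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "stage_seeds": self.stage_seeds,
                "config": self.config,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, index: int) -> int:
    return (seed * 100 + index) % (2**31)


def _write_tsv(frame: pd.DataFrame, path: str, index: bool = False) -> str:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def run_pipeline(config, outdir: str | None = None) -> RunManifest:
    """Run the configured stage sequence; returns the manifest.

    A stage failure halts the run with the stage name; the manifest of
    completed stages is attached to the raised error.
    """
    config = validate_config(config)
    outdir = outdir or config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = config["seed"]
    manifest = RunManifest(config=config, version=__version__, seed=seed)
    for i, stage in enumerate(STAGES):
        manifest.stage_seeds[stage] = _stage_seed(seed, i)

    state: dict = {}
    for stage in config["stages"]:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _run_stage(stage, config, outdir, manifest, state)
                stage_warnings = [str(w.message) for w in caught]
            if manifest.stages and manifest.stages[-1]["stage"] == stage:
                manifest.stages[-1]["warnings"] = stage_warnings
        except NichescoreError as err:
            err.manifest = manifest  # completed stages so far
            raise NichescoreError(f"stage {stage!r} failed: {err}") from err

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise NichescoreError(
            f"stage {stage!r} needs {key!r}; run its producing stage first"
        )
    return state[key]


def _ensure_lognorm(state: dict, config: dict) -> ExpressionDataset:
    ds = state["dataset"]
    if ds.lognorm is None:
        ds = lognormalize(ds, scale_factor=config["scale_factor"])
        state["dataset"] = ds
    return ds


def _run_stage(stage, config, outdir, manifest: RunManifest, state: dict):
    seed = manifest.stage_seeds[stage]
    if stage == "simulate":
        spec = preset(config["simulate"]["preset"], seed=seed)
        ds, truth = generate_dataset(spec)
        state["dataset"] = ds
        state["truth"] = truth
        paths = write_counts(ds, outdir)
        gmt_path = os.path.join(outdir, "gene_sets.gmt")
        write_gmt(default_gene_sets(), gmt_path)
        reg_path = os.path.join(outdir, "regulons.tsv")
        write_regulons(default_regulons(seed=seed), reg_path)
        lr_tables, lr_key = generate_lr_fixture(seed=seed)
        state["lr_tables"] = lr_tables
        lr_paths = []
        for name, table in lr_tables:
            p = os.path.join(outdir, f"lr_source_{name}.csv")
            table.to_csv(p, index=False)
            lr_paths.append(p)
        manifest.add_stage(
            "simulate",
            list(paths.values()) + [gmt_path, reg_path] + lr_paths,
            n_cells=ds.n_cells,
            n_genes=ds.n_genes,
        )
    elif stage == "qc":
        ds = _require(state, "dataset", stage)
        qc_cfg = config["qc"]
        thresholds = QcThresholds(
            min_features=qc_cfg["min_features"],
            max_features=qc_cfg["max_features"],
            max_mito_fraction=qc_cfg["max_mito_fraction"],
        )
        ds, report = filter_cells_qc(ds, thresholds)
        state["dataset"] = ds
        path = _write_tsv(report.to_frame(), os.path.join(outdir, "qc_report.tsv"))
        manifest.add_stage("qc", [path], n_cells=ds.n_cells, n_genes=ds.n_genes)
    elif stage == "purity":
        ds = _require(state, "dataset", stage)
        ds, report = filter_lineage_purity(
            ds, reporter=config["reporter"], threshold=config["purity"]["threshold"]
        )
        state["dataset"] = ds
        path = _write_tsv(
            report.groups_removed, os.path.join(outdir, "purity_report.tsv")
        )
        manifest.add_stage("purity", [path], n_cells=ds.n_cells, n_genes=ds.n_genes)
    elif stage == "score":
        ds = _ensure_lognorm(state, config)
        collection = default_gene_sets()
        scores = score_battery(
            ds,
            collection,
            n_bins=config["score"]["n_bins"],
            n_ctrl=config["score"]["n_ctrl"],
            seed=seed,
        )
        state["scores"] = scores
        state["gene_sets"] = collection
        out = scores.copy()
        out.index.name = "cell_id"
        path = _write_tsv(out, os.path.join(outdir, "scores.tsv"), index=True)
        manifest.add_stage("score", [path], n_cells=ds.n_cells)
    elif stage == "composition":
        ds = _require(state, "dataset", stage)
        cfg = config["composition"]
        result = proportion_shift_test(
            ds.clusters.to_numpy(),
            ds.cell_meta["condition"].to_numpy(),
            n_permutations=cfg["n_permutations"],
            seed=seed,
            condition_a=cfg["condition_a"],
            condition_b=cfg["condition_b"],
        )
        result = flag_significant(result, cfg["fdr_max"], cfg["min_abs_log2fd"])
        path = _write_tsv(result.table, os.path.join(outdir, "composition.tsv"))
        manifest.add_stage("composition", [path], n_cells=ds.n_cells)
    elif stage == "correlate":
        ds = _ensure_lognorm(state, config)
        scores = _require(state, "scores", stage)
        cfg = config["correlate"]
        mc = build_metacells(
            ds,
            scores=scores,
            n_pcs=cfg["n_pcs"],
            k_neighbors=cfg["k_neighbors"],
            resolution=cfg["resolution"],
            min_size=cfg["min_size"],
            seed=seed,
        )
        collection = state.get("gene_sets", default_gene_sets())
        exclude = collection.union_genes(*ECM_AGGREGATE_CATEGORIES)
        gene_corr = score_gene_correlation(
            mc, ECM_SCORE_NAME, exclude_genes=exclude, top_n=cfg["top_n_genes"]
        )
        activities = regulon_activity(mc, default_regulons(seed=seed))
        tf_corr = score_score_correlation(
            mc, activities, ECM_SCORE_NAME, top_n=cfg["top_n_tfs"]
        )
        p1 = _write_tsv(gene_corr, os.path.join(outdir, "score_gene_corr.tsv"))
        p2 = _write_tsv(tf_corr, os.path.join(outdir, "score_tf_corr.tsv"))
        assign = mc.assignment.rename("metacell").to_frame()
        assign.index.name = "cell_id"
        p3 = _write_tsv(assign, os.path.join(outdir, "metacells.tsv"), index=True)
        manifest.add_stage("correlate", [p1, p2, p3], n_cells=int(mc.sizes.sum()))
    elif stage == "crosstalk":
        ds = _ensure_lognorm(state, config)
        cfg = config["crosstalk"]
        lr_tables = state.get("lr_tables")
        if lr_tables is None:
            lr_tables, _ = generate_lr_fixture(seed=seed)
        db = build_consensus_db(lr_tables, min_sources=cfg["min_sources"])
        conditions = sorted(ds.cell_meta["condition"].unique())
        results = {}
        paths = []
        for cond in conditions:
            sub = ds.subset_cells(
                (ds.cell_meta["condition"] == cond).to_numpy()
            )
            res = interaction_test(
                sub,
                db,
                min_fraction=cfg["min_fraction"],
                n_perm=cfg["n_perm"],
                seed=seed,
            )
            results[cond] = res
            paths.append(
                _write_tsv(res, os.path.join(outdir, f"interactions_{cond}.tsv"))
            )
        if len(conditions) == 2:
            edges, gene_sets = differential_network(
                results[conditions[0]], results[conditions[1]]
            )
            paths.append(
                _write_tsv(edges, os.path.join(outdir, "network_edges.tsv"))
            )
            gs_path = os.path.join(outdir, "crosstalk_gene_sets.json")
            with open(gs_path, "w") as fh:
                json.dump(gene_sets, fh, indent=2, sort_keys=True)
            paths.append(gs_path)
        manifest.add_stage("crosstalk", paths, n_cells=ds.n_cells)
    elif stage == "markers":
        ds = _ensure_lognorm(state, config)
        cfg = config["markers"]
        table = marker_genes(
            ds, min_pct=cfg["min_pct"], logfc_threshold=cfg["logfc_threshold"]
        )
        path = _write_tsv(table, os.path.join(outdir, "markers.tsv"))
        manifest.add_stage("markers", [path], n_cells=ds.n_cells)
    else:  # pragma: no cover - guarded by validate_config
        raise NichescoreError(f"unknown stage {stage!r}")
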