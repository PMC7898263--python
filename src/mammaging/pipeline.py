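"""End-to-end orchestration: simulate (or load) -> qc -> classify ->
signatures -> de -> composition -> enrich, with a provenance manifest.

Every run writes ``run_manifest.json`` holding the configuration snapshot,
the seed, the package version and a content digest for each output file;
the manifest is written even when a stage fails, recording the stage
reached.  Identical configuration and seed reproduce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .celltypes import (annotate_clusters, cluster_cells, derive_type_signatures,
                        log_normalize)
from .composition import composition_table
from .de import consensus_de, de_summary
from .enrichment import map_homologs, ora_hypergeom
from .io import (AGED, YOUNG, CountMatrix, DEConfig, GeneSetCollection,
                 QCThresholds, SampleMeta, ValidationError, age_of_samples,
                 concat_matrices, load_yaml, read_10x_mtx, read_gmt, write_gmt,
                 write_10x_mtx)
from .qc import compute_cell_qc, filter_cells, summarize_depth
from .simulate import (SimConfig, SimTruth, hybrid_config, null_config,
                       recovery_config, simulate_atlas, study_config,
                       truth_de_table)

log = logging.getLogger("mammaging")

STAGES = ("simulate", "qc", "classify", "signatures", "de", "composition",
          "enrich")
_PRESETS = {"recovery": recovery_config, "study": study_config,
            "null": null_config, "hybrid": hybrid_config}
_KNOWN_KEYS = {"simulate", "input", "qc", "classify", "signatures", "de",
               "composition", "enrich", "stages", "seed"}


def validate_config(config: dict) -> dict:
    config = dict(config or {})
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" in config and "input" in config:
        raise ValidationError("give either 'simulate' or 'input', not both")
    if "simulate" not in config and "input" not in config:
        raise ValidationError("config needs a 'simulate' or 'input' section")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValidationError(f"unknown stages: {bad}")
    return config


def build_sim_config(section: dict, seed: int) -> SimConfig:
    preset = (section or {}).get("preset", "recovery")
    if preset not in _PRESETS:
        raise ValidationError(f"unknown simulate preset {preset!r}")
    cfg = _PRESETS[preset](seed=int(section.get("seed", seed)))
    overrides = dict(section.get("overrides", {}))
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown SimConfig field {key!r}")
        if key == "cells_per_sample":
            value = tuple(int(v) for v in value)
        setattr(cfg, key, value)
    if overrides:
        cfg.__post_init__()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict, out_dir: Path, seed: int):
        self.config = config
        self.out_dir = out_dir
        self.seed = seed
        self.matrix: CountMatrix | None = None
        self.meta: list[SampleMeta] = []
        self.truth: SimTruth | None = None
        self.sim_cfg: SimConfig | None = None
        self.kept: list[str] = []
        self.labels: pd.Series | None = None
        self.de_results: dict[str, pd.DataFrame] = {}
        self.manifest: dict = {
            "package_version": __version__, "seed": seed, "config": config,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": [],
        }

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.manifest["stages"].append({
            "name": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def write_manifest(self) -> None:
        path = self.out_dir / "run_manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, default=str))


def _marker_panel(run: _Run) -> dict[str, list[str]]:
    section = run.config.get("classify", {}) or {}
    if section.get("markers"):
        return {k: list(v) for k, v in load_yaml(section["markers"]).items()}
    if run.sim_cfg is not None:
        return {t.name: list(t.marker_genes) for t in run.sim_cfg.cell_types
                if t.marker_genes}
    panel_path = Path(__file__).parent / "data" / "marker_panel.yaml"
    return {k: list(v) for k, v in load_yaml(panel_path).items()}


def _hybrid_labels(run: _Run) -> dict[str, tuple[str, str]]:
    if run.sim_cfg is None:
        return {"hs-av": ("hs", "av")}
    return {t.name: tuple(t.hybrid_of) for t in run.sim_cfg.cell_types
            if t.hybrid_of is not None}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(run: _Run) -> None:
    if "input" in run.config:
        section = run.config["input"]
        meta_df = pd.read_csv(section["meta"])
        run.meta = [SampleMeta(r.sample_id, r.age_group)
                    for r in meta_df.itertuples()]
        parts = [read_10x_mtx(path, sample_id=sid)
                 for sid, path in section["sample_dirs"].items()]
        run.matrix = concat_matrices(parts)
        run.record("simulate", [])
        return
    run.sim_cfg = build_sim_config(run.config.get("simulate", {}), run.seed)
    run.matrix, run.meta, run.truth = simulate_atlas(run.sim_cfg)
    outputs = []
    meta_path = run.out_dir / "samples.csv"
    pd.DataFrame([{"sample_id": m.sample_id, "age_group": m.age_group,
                   "n_cells_loaded": m.n_cells_loaded} for m in run.meta]
                 ).to_csv(meta_path, index=False)
    outputs.append(meta_path)
    truth_path = run.out_dir / "truth.json"
    truth_path.write_text(json.dumps({
        "type_of_cell": run.truth.type_of_cell.to_dict(),
        "planted_de": {f"{t}\t{g}": lfc
                       for (t, g), lfc in run.truth.planted_de.items()},
        "planted_props": run.truth.planted_props.to_dict(),
        "doublets": run.truth.doublet_flags[run.truth.doublet_flags]
                       .index.tolist(),
    }))
    outputs.append(truth_path)
    if (run.config.get("simulate", {}) or {}).get("write_matrices", False):
        for m in run.meta:
            cells = [b for b in run.matrix.barcodes
                     if run.matrix.sample_of_cell[b] == m.sample_id]
            sub = run.matrix.subset_cells(cells)
            write_10x_mtx(sub, run.out_dir / "data" / m.sample_id)
    run.record("simulate", outputs)


def _stage_qc(run: _Run) -> None:
    section = run.config.get("qc", {}) or {}
    thresholds = QCThresholds(**{k: v for k, v in section.items()
                                 if k in QCThresholds.__dataclass_fields__})
    qc = compute_cell_qc(run.matrix, thresholds=thresholds)
    run.kept = filter_cells(qc, thresholds)
    if not run.kept:
        raise ValidationError("QC removed every cell")
    med_genes, med_umi = summarize_depth(run.matrix, run.kept)
    log.info("QC kept %d/%d cells; median %d genes / %d UMI per cell",
             len(run.kept), run.matrix.n_cells, med_genes, med_umi)
    qc_path = run.out_dir / "cell_qc.csv"
    qc.to_csv(qc_path, index=False)
    kept_path = run.out_dir / "kept_barcodes.txt"
    kept_path.write_text("\n".join(run.kept) + "\n")
    run.matrix = run.matrix.subset_cells(run.kept)
    run.record("qc", [qc_path, kept_path])


def _stage_classify(run: _Run) -> None:
    section = run.config.get("classify", {}) or {}
    if section.get("use_truth_labels", False):
        if run.truth is None:
            raise ValidationError("use_truth_labels requires simulated input")
        run.labels = run.truth.type_of_cell.reindex(run.matrix.barcodes)
        report = pd.DataFrame()
    else:
        nm = log_normalize(run.matrix)
        clusters = cluster_cells(
            nm, n_hvg=int(section.get("n_hvg", 2000)),
            n_pcs=int(section.get("n_pcs", 30)),
            k=int(section.get("k", 20)),
            resolution=float(section.get("resolution", 1.0)),
            seed=run.seed)
        run.labels, report = annotate_clusters(
            clusters, nm, _marker_panel(run),
            hybrid_labels=_hybrid_labels(run),
            margin=float(section.get("margin", 0.25)), seed=run.seed)
    ann_path = run.out_dir / "cell_annotation.csv"
    ann = pd.DataFrame({
        "barcode": run.matrix.barcodes,
        "sample": run.matrix.samples.to_numpy(),
        "cell_type": run.labels.reindex(run.matrix.barcodes).to_numpy(),
    })
    ann.to_csv(ann_path, index=False)
    outputs = [ann_path]
    if len(report):
        report_path = run.out_dir / "cluster_report.csv"
        report.to_csv(report_path)
        outputs.append(report_path)
    run.record("classify", outputs)


def _stage_signatures(run: _Run) -> None:
    nm = log_normalize(run.matrix)
    sig = derive_type_signatures(nm, run.labels)
    sig_path = run.out_dir / "signatures.csv"
    sig.to_frame().to_csv(sig_path, index=False)
    run.record("signatures", [sig_path])


def _requested_cell_types(run: _Run) -> list[str]:
    section = run.config.get("de", {}) or {}
    requested = section.get("cell_types", "all")
    observed = sorted(set(run.labels.dropna()) - {"unassigned"})
    if requested == "all":
        age_of = age_of_samples(run.meta)
        ages = run.matrix.samples.map(age_of)
        lab = run.labels.reindex(run.matrix.barcodes)
        both = [t for t in observed
                if {YOUNG, AGED} <= set(ages[(lab == t).to_numpy()])]
        return both
    return list(requested)


def _de_config(run: _Run) -> DEConfig:
    section = run.config.get("de", {}) or {}
    return DEConfig(**{k: v for k, v in section.items()
                       if k in DEConfig.__dataclass_fields__})


def _stage_de(run: _Run) -> None:
    cfg = _de_config(run)
    outputs = []
    for cell_type in _requested_cell_types(run):
        result = consensus_de(run.matrix, run.labels, run.meta, cell_type, cfg)
        run.de_results[cell_type] = result
        path = run.out_dir / f"de_{cell_type}.csv"
        result.to_csv(path)
        outputs.append(path)
        log.info("DE %s: %s", cell_type, de_summary(result))
    run.record("de", outputs)


def _stage_composition(run: _Run) -> None:
    section = run.config.get("composition", {}) or {}
    compartments = section.get("compartments", {"total": None})
    outputs = []
    for name, types in compartments.items():
        table = composition_table(run.labels, run.meta,
                                  run.matrix.sample_of_cell, compartment=types)
        path = run.out_dir / f"composition_{name}.csv"
        table.to_csv(path)
        outputs.append(path)
    run.record("composition", outputs)


def _truth_collection(run: _Run) -> GeneSetCollection:
    sets, desc = {}, {}
    for cell_type in run.truth.planted_props.index:
        table = truth_de_table(run.truth, cell_type)
        for direction, sub in table.groupby("direction"):
            if len(sub) >= 3:
                name = f"planted_{cell_type}_{direction}"
                sets[name] = sub.gene.tolist()
                desc[name] = f"planted {direction} genes of {cell_type}"
    return GeneSetCollection(sets, desc)


def _stage_enrich(run: _Run) -> None:
    section = run.config.get("enrich", {}) or {}
    if section.get("gmt"):
        collection = read_gmt(section["gmt"])
    elif run.truth is not None:
        collection = _truth_collection(run)
        write_gmt(collection, run.out_dir / "genesets.gmt")
    else:
        raise ValidationError("enrich stage needs a GMT file")
    mapping = pd.read_csv(section["map"], sep="\t") if section.get("map") \
        else None
    outputs = []
    for cell_type, result in run.de_results.items():
        de_genes = result.index[result.consensus].tolist()
        universe = result.index.tolist()
        if mapping is not None:
            de_genes, _ = map_homologs(de_genes, mapping)
            universe, _ = map_homologs(universe, mapping)
        ora = ora_hypergeom(de_genes, universe, collection)
        path = run.out_dir / f"ora_{cell_type}.csv"
        ora.to_csv(path)
        outputs.append(path)
    run.record("enrich", outputs)


_STAGE_FN = {
    "simulate": _stage_simulate, "qc": _stage_qc, "classify": _stage_classify,
    "signatures": _stage_signatures, "de": _stage_de,
    "composition": _stage_composition, "enrich": _stage_enrich,
}


def run_all(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``run_manifest.json``, even on failure, with the stage reached)."""
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out_dir, seed)
    stages = config.get("stages", list(STAGES))
    current = None
    try:
        for stage in STAGES:
            if stage in stages:
                current = stage
                log.info("stage: %s", stage)
                _STAGE_FN[stage](run)
    except Exception as exc:
        run.manifest["failed_stage"] = current
        run.manifest["error"] = str(exc)
        run.write_manifest()
        raise
    run.manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    run.write_manifest()
    return run.manifest
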