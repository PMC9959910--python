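"""End-to-end pipeline: simulate/load -> rollup -> qc -> qualify -> diff ->
enrich -> classify.

Each stage writes its TSV artifact plus a JSON-lines log entry (stage name,
parameters, input hashes, row counts). Outputs are written atomically: a
stage writes ``<name>.partial`` and renames on success, so an aborted run
leaves its partial artifact behind for inspection. A manifest of stage
hashes makes re-runs resumable: with ``resume=True`` a stage whose inputs,
parameters and outputs are unchanged is skipped.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import contamination as contam
from . import differential as diff
from . import io as cio
from . import qc as qcm
from . import rollup as rol
from . import simulate as sim
from .errors import ConfigError, LFQCohortError


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: dict = field(default_factory=lambda: {"enabled": True, "preset": "desk"})
    inputs: dict = field(default_factory=dict)
    rollup: dict = field(default_factory=lambda: {"enabled": False, "min_peptides": 3, "r_min": 0.2})
    qc: dict = field(default_factory=lambda: {"top_n": 3, "high_fraction": 0.75})
    qualify: dict = field(default_factory=lambda: {"panel": "full16", "threshold": None, "k_mad": 3.0})
    diff: dict = field(default_factory=lambda: {"alpha": 0.05, "lfc": 0.25})
    enrich: dict = field(default_factory=lambda: {"min_universe_count": 3})
    classify: dict = field(
        default_factory=lambda: {
            "enabled": True,
            "k": 30,
            "folds": 10,
            "repeats": 3,
            "ntree": 1000,
            "mtry": None,
            "cost": 1.0,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown pipeline config keys: {sorted(bad)}")
        cfg = cls()
        for key, val in raw.items():
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(params: dict, input_paths: list[Path]) -> str:
    payload = {
        "params": params,
        "inputs": {str(p): _hash_file(p) for p in input_paths if p.exists()},
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


class _Runner:
    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.log_path = self.out / "pipeline_log.jsonl"
        self.manifest_path = self.out / "manifest.json"
        self.manifest: dict[str, str] = {}
        if resume and self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        elif self.log_path.exists():
            self.log_path.unlink()
        self.report: dict[str, Any] = {}

    def log(self, stage: str, **payload) -> None:
        entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **payload}
        with open(self.log_path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")

    def path(self, name: str) -> Path:
        return self.out / name

    def should_skip(self, stage: str, h: str, outputs: list[Path]) -> bool:
        return (
            self.resume
            and self.manifest.get(stage) == h
            and all(p.exists() for p in outputs)
        )

    def mark(self, stage: str, h: str) -> None:
        self.manifest[stage] = h
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))


def _atomic_write(write_fn, path: Path) -> None:
    partial = path.with_suffix(path.suffix + ".partial")
    write_fn(partial)
    partial.rename(path)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict[str, Any]:
    """Run all enabled stages in fixed order; return the run report."""
    r = _Runner(config, resume=resume)
    stage = "setup"
    try:
        matrix, metadata, annotations = _stage_inputs(r)
        matrix = _stage_rollup(r, matrix)
        _stage_qc(r, matrix, metadata)
        matrix, metadata = _stage_qualify(r, matrix, metadata)
        table = _stage_diff(r, matrix, metadata)
        _stage_enrich(r, table, annotations)
        _stage_classify(r, matrix, metadata, table)
    except LFQCohortError as exc:
        r.log("failure", failed_stage=r.report.get("current_stage", stage), error=str(exc))
        raise
    r.report.pop("current_stage", None)
    r.log("done", artifacts=sorted(p.name for p in r.out.glob("*.tsv")))
    return r.report


def _stage_inputs(r: _Runner):
    r.report["current_stage"] = "inputs"
    cfg = r.config
    if cfg.simulate.get("enabled", True):
        preset = cfg.simulate.get("preset", "desk")
        sim_cfg = (
            sim.default_study_config(seed=cfg.seed)
            if preset == "study"
            else sim.desk_config(seed=cfg.seed)
        )
        h = _stage_hash({"preset": preset, "seed": cfg.seed}, [])
        outs = [r.path(n) for n in ("matrix.tsv", "metadata.tsv", "annotations.tsv", "truth_proteins.tsv", "truth_samples.tsv")]
        if r.should_skip("simulate", h, outs):
            r.log("simulate", skipped=True)
        else:
            matrix, metadata, annotations, truth = sim.simulate_cohort(sim_cfg)
            _atomic_write(lambda p: cio.write_matrix(matrix, p), r.path("matrix.tsv"))
            _atomic_write(lambda p: cio.write_metadata(metadata, p), r.path("metadata.tsv"))
            _atomic_write(lambda p: cio.write_annotations(annotations, p), r.path("annotations.tsv"))
            _atomic_write(lambda p: truth.proteins.to_csv(p, sep="\t", float_format="%.6g"), r.path("truth_proteins.tsv"))
            _atomic_write(lambda p: truth.samples.to_csv(p, sep="\t", float_format="%.6g"), r.path("truth_samples.tsv"))
            r.mark("simulate", h)
            r.log("simulate", preset=preset, seed=cfg.seed,
                  n_proteins=matrix.data.shape[0], n_samples=matrix.data.shape[1])
        r.matrix_path = r.path("matrix.tsv")
        r.metadata_path = r.path("metadata.tsv")
        r.annotations_path = r.path("annotations.tsv")
        matrix = cio.read_matrix(r.matrix_path)
        metadata = cio.read_metadata(r.metadata_path)
        annotations = cio.read_annotations(r.annotations_path)
    else:
        r.matrix_path = Path(cfg.inputs["matrix"])
        r.metadata_path = Path(cfg.inputs["metadata"])
        r.annotations_path = (
            Path(cfg.inputs["annotations"]) if cfg.inputs.get("annotations") else None
        )
        matrix = cio.read_matrix(r.matrix_path)
        metadata = cio.read_metadata(r.metadata_path)
        annotations = (
            cio.read_annotations(r.annotations_path)
            if r.annotations_path
            else cio.AnnotationMap({})
        )
        r.log("inputs", **{k: str(v) for k, v in cfg.inputs.items()})
    r.report["n_proteins"] = matrix.data.shape[0]
    r.report["n_samples"] = matrix.data.shape[1]
    return matrix, metadata, annotations


def _stage_rollup(r: _Runner, matrix: cio.IntensityMatrix):
    cfg = r.config.rollup
    if not cfg.get("enabled", False):
        return matrix
    r.report["current_stage"] = "rollup"
    peptides = cio.read_matrix(cfg["peptides"], level="peptide")
    mapping = pd.read_csv(cfg["map"], sep="\t", index_col="peptide_id")["protein_id"]
    result = rol.rollup(
        peptides,
        mapping,
        min_peptides=int(cfg.get("min_peptides", 3)),
        r_min=float(cfg.get("r_min", 0.2)),
    )
    _atomic_write(lambda p: cio.write_matrix(result.proteins, p), r.path("proteins_rolled.tsv"))
    r.log(
        "rollup",
        n_excluded_peptides=len(result.excluded_peptides),
        n_dropped_proteins=len(result.dropped_proteins),
    )
    r.report["rollup"] = {"excluded_peptides": len(result.excluded_peptides)}
    return result.proteins


def _stage_qc(r: _Runner, matrix, metadata):
    r.report["current_stage"] = "qc"
    cfg = r.config.qc
    qc_ids = metadata.qc_ids()
    if len(qc_ids) < 3:
        r.log("qc", skipped=True, reason="fewer than 3 QC runs")
        return
    h = _stage_hash(cfg, [r.matrix_path, r.metadata_path])
    if r.should_skip("qc", h, [r.path("qc_report.tsv")]):
        r.log("qc", skipped=True)
        return
    report = qcm.qc_report(
        matrix, qc_ids,
        top_n=int(cfg.get("top_n", 3)),
        high_fraction=float(cfg.get("high_fraction", 0.75)),
    )
    _atomic_write(lambda p: cio.write_report(qcm.qc_report_frame(report), p), r.path("qc_report.tsv"))
    r.log(
        "qc",
        missing_free_fraction=report.missing_free_fraction,
        dynamic_range_log10=report.dynamic_range_log10,
        high_median_cv=report.stratified_cv["high"].median_cv_percent,
        low_median_cv=report.stratified_cv["low"].median_cv_percent,
    )
    r.mark("qc", h)
    r.report["qc"] = {
        "missing_free_fraction": report.missing_free_fraction,
        "dynamic_range_log10": report.dynamic_range_log10,
    }


def _stage_qualify(r: _Runner, matrix, metadata):
    r.report["current_stage"] = "qualify"
    cfg = r.config.qualify
    panel_name = cfg.get("panel", "full16")
    if panel_name in contam.BUILTIN_PANELS:
        panel = contam.BUILTIN_PANELS[panel_name]()
    else:
        panel = _read_panel(panel_name, cfg.get("threshold"))
    if cfg.get("threshold") is not None:
        panel.threshold_percent = float(cfg["threshold"])
    h = _stage_hash(cfg, [r.matrix_path, r.metadata_path])
    outs = [r.path("contamination_report.tsv"), r.path("metadata_qualified.tsv")]
    if r.should_skip("qualify", h, outs):
        updated = cio.read_metadata(r.path("metadata_qualified.tsv"))
        kept = [
            s for s in updated.sample_ids
            if updated.table.loc[s, "group"] != "QC" and not updated.table.loc[s, "excluded"]
        ]
        r.log("qualify", skipped=True)
        r.report["qualify"] = {"n_kept": len(kept)}
        return matrix.subset_samples(kept), updated
    report, updated = contam.qualify(matrix, metadata, panel, k_mad=float(cfg.get("k_mad", 3.0)))
    _atomic_write(lambda p: cio.write_report(contam.report_frame(report), p), r.path("contamination_report.tsv"))
    _atomic_write(lambda p: cio.write_metadata(updated, p), r.path("metadata_qualified.tsv"))
    kept = [
        s for s in updated.sample_ids
        if updated.table.loc[s, "group"] != "QC" and not updated.table.loc[s, "excluded"]
    ]
    r.log(
        "qualify",
        panel=panel.name,
        threshold_percent=panel.threshold_percent,
        excluded=report.excluded_samples,
        intra_group_cv_before=report.intra_group_cv_before,
        intra_group_cv_after=report.intra_group_cv_after,
    )
    r.mark("qualify", h)
    r.report["qualify"] = {
        "excluded": report.excluded_samples,
        "n_kept": len(kept),
    }
    return matrix.subset_samples(kept), updated


def _read_panel(path: str, threshold) -> contam.ContaminationPanel:
    df = pd.read_csv(path, sep="\t", names=["class", "accession"], header=None)
    markers: dict[str, list[str]] = {}
    for cls, acc in zip(df["class"], df["accession"]):
        markers.setdefault(cls, []).append(acc)
    return contam.ContaminationPanel(
        class_markers=markers,
        threshold_percent=float(threshold if threshold is not None else 10.0),
        name=Path(path).stem,
    )


def _stage_diff(r: _Runner, matrix, metadata):
    r.report["current_stage"] = "diff"
    cfg = r.config.diff
    h = _stage_hash(cfg, [r.matrix_path, r.path("metadata_qualified.tsv")])
    if r.should_skip("diff", h, [r.path("diff.tsv")]):
        saved = cio.read_report(r.path("diff.tsv")).set_index("protein_id")
        table = diff.DifferentialTable(
            results=saved,
            n_dropped=0,
            alpha=float(cfg.get("alpha", 0.05)),
            lfc_cut=float(cfg.get("lfc", 0.25)),
        )
        r.log("diff", skipped=True)
        r.report["diff"] = {"n_ap": len(table.ap_ids())}
        return table
    table = diff.call_aps(
        matrix, metadata,
        alpha=float(cfg.get("alpha", 0.05)),
        lfc_cut=float(cfg.get("lfc", 0.25)),
    )
    out = table.results.copy()
    out.insert(0, "protein_id", out.index)
    _atomic_write(lambda p: cio.write_report(out.reset_index(drop=True), p), r.path("diff.tsv"))
    counts = table.results["category"].value_counts().to_dict()
    r.log(
        "diff",
        n_tested=len(table.results),
        n_dropped=table.n_dropped,
        n_ap=len(table.ap_ids()),
        categories=counts,
    )
    r.mark("diff", h)
    r.report["diff"] = {"n_ap": len(table.ap_ids()), "categories": counts}
    return table


def _stage_enrich(r: _Runner, table, annotations):
    r.report["current_stage"] = "enrich"
    ap_ids = table.ap_ids()
    if not ap_ids or not annotations.mapping:
        r.log("enrich", skipped=True, reason="no APs or no annotations")
        return
    h = _stage_hash(
        r.config.enrich,
        [r.path("diff.tsv")] + ([r.annotations_path] if r.annotations_path else []),
    )
    if r.should_skip("enrich", h, [r.path("enrich.tsv")]):
        r.log("enrich", skipped=True)
        return
    result = diff.enrich_terms(
        ap_ids,
        list(table.results.index),
        annotations,
        min_universe_count=int(r.config.enrich.get("min_universe_count", 3)),
    )
    _atomic_write(lambda p: cio.write_report(result, p), r.path("enrich.tsv"))
    r.mark("enrich", h)
    r.log("enrich", n_terms=len(result), skipped_terms=result.attrs.get("skipped_terms", []))
    r.report["enrich"] = {"n_terms": len(result)}


def _stage_classify(r: _Runner, matrix, metadata, table):
    r.report["current_stage"] = "classify"
    cfg = r.config.classify
    if not cfg.get("enabled", True):
        return
    ap_ids = table.ap_ids()
    if len(ap_ids) < 2:
        r.log("classify", skipped=True, reason="fewer than 2 AP features")
        return
    h = _stage_hash(
        {**cfg, "seed": r.config.seed},
        [r.matrix_path, r.path("diff.tsv"), r.path("metadata_qualified.tsv")],
    )
    if r.should_skip("classify", h, [r.path("clf_report.tsv")]):
        r.log("classify", skipped=True)
        return
    cohort_ids = [
        s for s in metadata.sample_ids
        if metadata.table.loc[s, "group"] != "QC" and not metadata.table.loc[s, "excluded"]
    ]
    sub = matrix.subset_samples(cohort_ids).subset_proteins(ap_ids)
    labels = metadata.table.loc[cohort_ids, "group"].to_numpy()
    smallest = min(np.unique(labels, return_counts=True)[1])
    folds = min(int(cfg.get("folds", 10)), int(smallest))
    clf_cfg = clf.ClassifierConfig(
        folds=folds,
        repeats=int(cfg.get("repeats", 3)),
        ntree=int(cfg.get("ntree", 1000)),
        mtry=cfg.get("mtry"),
        cost=float(cfg.get("cost", 1.0)),
    )
    report = clf.run_classifiers(sub, labels, clf_cfg, seed=r.config.seed)
    k = min(int(cfg.get("k", 30)), len(ap_ids))
    overlap = clf.top_overlap(report.importance["RF"], report.importance["SVM"], k=k)
    report.overlap_k = k
    report.overlap_set = overlap
    rows = pd.DataFrame(
        {
            "feature": report.importance["RF"].index,
            "importance_rf": report.importance["RF"].to_numpy(),
            "importance_svm": report.importance["SVM"].reindex(report.importance["RF"].index).to_numpy(),
        }
    )
    rows["in_overlap"] = rows["feature"].isin(overlap)
    _atomic_write(lambda p: cio.write_report(rows, p), r.path("clf_report.tsv"))
    r.log(
        "classify",
        folds=folds,
        repeats=clf_cfg.repeats,
        mean_accuracy=report.mean_accuracy,
        ci95=report.ci95,
        overlap_k=k,
        overlap_size=len(overlap),
    )
    r.mark("classify", h)
    r.report["classify"] = {
        "mean_accuracy": report.mean_accuracy,
        "overlap_size": len(overlap),
    }
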