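"""End-to-end orchestration: QC -> quantify -> controls -> normalize ->
differential -> panel -> scores -> survival.

Two modes share the same artifact layout. ``run_discovery`` fits
everything on a discovery bundle; ``run_validation`` applies the frozen
normalization reference (cross-cohort factors F_12) and the frozen target
panel to a validation bundle without refitting. Every intermediate is
persisted as TSV/BED/JSON, and a manifest records the parameters actually
used; rerunning with the same inputs reproduces the outputs byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .controls import (ControlSet, DEFAULT_K_SET, consensus_peaks,
                       filter_by_annotation, select_controls)
from .differential import (DifferentialPeakSelector, rank_representatives)
from .intervals import GenomicInterval, read_bed, subtract_blacklist, write_bed
from .normalize import ControlNormalizer, NormalizationModel
from .qc import QcReport, qc_report
from .scoring import OpennessPanel, TargetPanel, classification_metrics, roc_auroc
from .survival import km_curve, km_median, logrank_test
from .tracks import AreaMatrix, SignalTrack, build_area_matrix, read_bedgraph

__all__ = ["PipelineConfig", "load_sample_sheet", "load_tracks",
           "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    """Parameters of the full analysis; defaults follow the method."""

    cv_max: float = 0.3
    width_max: int = 500
    k_set: tuple[int, ...] = DEFAULT_K_SET
    alpha: float = 0.05
    panel_size: int = 9
    panel_control_k: int = 20          # control set used for ranking/panel
    responder: tuple[str, ...] = ("CR", "PR")
    selection_nonresponder: tuple[str, ...] = ("PD",)
    evaluation_nonresponder: tuple[str, ...] = ("PD", "SD")
    qc: bool = True
    anchor: str = "cut"


def load_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "response", "pfs_months", "event"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks column(s): {sorted(missing)}")
    bad = ~sheet["response"].isin(["CR", "PR", "SD", "PD"])
    if bad.any():
        raise ValueError(
            f"invalid RECIST categories: {sheet.loc[bad, 'response'].tolist()}"
        )
    if (sheet["pfs_months"] < 0).any():
        raise ValueError("pfs_months must be non-negative")
    return sheet


def load_tracks(samples_dir: str | Path, sample_ids: Sequence[str]
                ) -> dict[str, SignalTrack]:
    samples_dir = Path(samples_dir)
    out = {}
    for sid in sample_ids:
        path = samples_dir / f"{sid}.bedgraph"
        if not path.exists():
            raise FileNotFoundError(f"no signal track for sample {sid}: {path}")
        out[sid] = read_bedgraph(path)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _survival_summary(
    sheet: pd.DataFrame, predicted: Mapping[str, bool], out: Path
) -> dict:
    """KM per predicted openness group + log-rank, persisted as TSV/JSON."""
    sheet = sheet.set_index("sample_id")
    groups = np.array([
        "high" if predicted[s] else "low" for s in sheet.index
    ])
    times = sheet["pfs_months"].to_numpy(dtype=float)
    events = sheet["event"].to_numpy(dtype=bool)
    summary: dict = {"groups": {}}
    for g in ("high", "low"):
        mask = groups == g
        if mask.sum() == 0:
            summary["groups"][g] = {"n": 0, "median_pfs_months": None}
            continue
        curve = km_curve(times[mask], events[mask])
        med = km_median(curve)
        curve.to_tsv(out / f"km_{g}.tsv")
        summary["groups"][g] = {
            "n": int(mask.sum()),
            "median_pfs_months": None if med == float("inf") else med,
        }
    if 0 < (groups == "high").sum() < len(groups):
        chi2, p = logrank_test(times, events, groups)
        summary["logrank"] = {"chi_square": chi2, "p": p}
    else:
        summary["logrank"] = None
    (out / "survival.json").write_text(json.dumps(summary, indent=2))
    return summary


def _qc_stage(bundle, sheet: pd.DataFrame, peaks, config: PipelineConfig,
              out: Path) -> list[QcReport]:
    tss = read_bed(bundle.tss_site_bed)
    reports = []
    for sid in sheet["sample_id"]:
        reports.append(
            qc_report(sid, bundle.reads[sid], peaks, tss, anchor=config.anchor)
        )
    QcReport.write_table(reports, out / "qc.tsv")
    return reports


def _discover_controls(bundle, tracks, config: PipelineConfig, out: Path
                       ) -> dict[int, ControlSet]:
    refsets = [read_bed(p) for p in bundle.refset_beds]
    consensus = consensus_peaks(refsets)
    annotated = filter_by_annotation(
        consensus, read_bed(bundle.dh_bed), read_bed(bundle.tss_region_bed)
    )
    if not annotated:
        raise RuntimeError("control discovery produced no annotated peaks")
    control_matrix = build_area_matrix(tracks, annotated)
    control_matrix.to_tsv(out / "control_candidate_areas.tsv")
    sets = {}
    for k in config.k_set:
        cs = select_controls(control_matrix, k=k, cv_max=config.cv_max,
                             width_max=config.width_max)
        cs.write(out / f"controls_k{k}.bed", out / f"controls_k{k}.tsv")
        sets[k] = cs
    return sets


def run_discovery(bundle, out_dir: str | Path,
                  config: PipelineConfig | None = None) -> dict:
    """Fit the full pipeline on a discovery bundle; returns a result dict."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = load_sample_sheet(bundle.sheet_path)
    labels = dict(zip(sheet["sample_id"], sheet["response"]))
    tracks = bundle.tracks

    candidates = subtract_blacklist(
        read_bed(bundle.candidate_bed), read_bed(bundle.blacklist_bed)
    )
    write_bed(candidates, out / "candidates_filtered.bed")

    if config.qc and bundle.reads:
        _qc_stage(bundle, sheet, candidates, config, out)

    control_sets = _discover_controls(bundle, tracks, config, out)

    raw = build_area_matrix(tracks, candidates,
                            samples=list(sheet["sample_id"]))
    raw.to_tsv(out / "areas_raw.tsv")

    normalizers: dict[int, ControlNormalizer] = {}
    normalized: dict[str, AreaMatrix] = {}
    for k, cs in control_sets.items():
        norm = ControlNormalizer(cs, reference_cohort=bundle.cohort_id)
        norm.fit(tracks)
        norm.model_().to_json(out / f"normalization_k{k}.json")
        normalized[f"k{k}"] = norm.transform(raw)
        normalized[f"k{k}"].to_tsv(out / f"areas_normalized_k{k}.tsv")
        normalizers[k] = norm

    selector = DifferentialPeakSelector(
        alpha=config.alpha,
        responder=frozenset(config.responder),
        nonresponder=frozenset(config.selection_nonresponder),
    ).fit(normalized, labels)
    result = selector.result_()
    result.to_tsv(out / "differential.tsv")

    panel_matrix = normalized[f"k{config.panel_control_k}"]
    targets = rank_representatives(
        panel_matrix, result.intersection, labels,
        n_per_criterion=config.panel_size // 3,
        responder=frozenset(config.responder),
        nonresponder=frozenset(config.selection_nonresponder),
    )
    write_bed([panel_matrix.peak_by_id(t) for t in targets],
              out / "targets.bed")

    panel_est = OpennessPanel(
        targets=targets,
        panel_size=config.panel_size,
        responder=frozenset(config.responder),
        fit_nonresponder=frozenset(config.selection_nonresponder),
        eval_nonresponder=frozenset(config.evaluation_nonresponder),
    ).fit(panel_matrix, labels)
    panel_est.panel_.to_json(out / "panel.json")
    score_table = panel_est.score_table(panel_matrix)
    score_table.to_csv(out / "scores.tsv", sep="\t", index=False)

    predicted = dict(zip(score_table["sample_id"],
                         score_table["predicted_class"] == "R"))
    survival = _survival_summary(sheet, predicted, out)

    manifest = {
        "mode": "discovery",
        "version": __version__,
        "cohort": bundle.cohort_id,
        "config": dataclasses.asdict(config),
        "inputs": {
            "sample_sheet": _sha256(Path(bundle.sheet_path)),
            "candidate_peaks": _sha256(Path(bundle.candidate_bed)),
        },
        "n_samples": int(len(sheet)),
        "n_candidates": len(candidates),
        "intersection_size": len(result.intersection),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "config": config,
        "sheet": sheet,
        "control_sets": control_sets,
        "normalizers": normalizers,
        "normalized": normalized,
        "differential": result,
        "targets": targets,
        "panel": panel_est,
        "scores": score_table,
        "survival": survival,
        "candidates": candidates,
    }


def run_validation(bundle, discovery_out: str | Path, out_dir: str | Path,
                   config: PipelineConfig | None = None) -> dict:
    """Apply frozen normalization reference + panel to a validation bundle."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    disc = Path(discovery_out)

    sheet = load_sample_sheet(bundle.sheet_path)
    labels = dict(zip(sheet["sample_id"], sheet["response"]))
    tracks = bundle.tracks

    candidates = subtract_blacklist(
        read_bed(bundle.candidate_bed), read_bed(bundle.blacklist_bed)
    )
    if config.qc and bundle.reads:
        _qc_stage(bundle, sheet, candidates, config, out)

    raw = build_area_matrix(tracks, candidates,
                            samples=list(sheet["sample_id"]))

    k = config.panel_control_k
    model = NormalizationModel.from_json(disc / f"normalization_k{k}.json")
    norm = ControlNormalizer.from_model(model)
    normalized = norm.transform(raw, tracks=tracks)   # F_12 factors
    normalized.to_tsv(out / f"areas_normalized_k{k}.tsv")

    panel = TargetPanel.from_json(disc / "panel.json")
    panel_est = OpennessPanel.from_panel(panel)
    score_table = panel_est.score_table(normalized)
    score_table.to_csv(out / "scores.tsv", sep="\t", index=False)

    eval_groups = set(config.responder) | set(config.evaluation_nonresponder)
    eval_samples = [s for s in normalized.samples if labels[s] in eval_groups]
    y = np.array([labels[s] in set(config.responder) for s in eval_samples])
    scores = panel_est.decision_function(normalized, samples=eval_samples)
    metrics = classification_metrics(scores, panel.combined_threshold, y)
    auroc = roc_auroc(scores, y)

    predicted = dict(zip(score_table["sample_id"],
                         score_table["predicted_class"] == "R"))
    survival = _survival_summary(sheet, predicted, out)

    summary = {
        "mode": "validation",
        "version": __version__,
        "cohort": bundle.cohort_id,
        "n_samples": int(len(sheet)),
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "auroc": auroc,
    }
    (out / "manifest.json").write_text(json.dumps(summary, indent=2))
    return {
        "config": config,
        "sheet": sheet,
        "normalized": normalized,
        "scores": score_table,
        "metrics": metrics,
        "auroc": auroc,
        "survival": survival,
    }
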