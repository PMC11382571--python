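"""End-to-end orchestration: register -> crop -> evaluate -> label -> report.

`run_evaluation` mirrors the benchmark workflow: optional
correspondence-based initialization, optional crop to an evaluation box,
ICP refinement, metric evaluation at the scenario threshold, a
precision-recall curve, and dual-direction point labeling (the precision
pass labels the reconstruction against the ground truth; the recall pass
labels the ground truth against the reconstruction).  `run_monitor` runs
the plateau detector over a metric series.

Every run writes a manifest (config echo, input hashes, package version)
sufficient to re-run deterministically.  Outputs are staged in a
temporary directory and moved into place only on success, so a failed
stage leaves no partial bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from plantrecon import __version__
from plantrecon.cloud_io import (
    BoundingVolume,
    PointCloud,
    crop_to_bounds,
    load_bounds,
    load_cloud,
    write_cloud,
)
from plantrecon.geometry_metrics import (
    INDOOR_THRESHOLD,
    OUTDOOR_THRESHOLD,
    evaluate_reconstruction,
    label_points,
    labeled_cloud,
    pr_curve,
)
from plantrecon.registration import (
    IcpConfig,
    SimilarityTransform,
    apply_transform,
    estimate_initial_transform,
    icp_refine,
    load_correspondences,
)
from plantrecon.training_monitor import (
    MetricSeries,
    PlateauConfig,
    interpolate_series,
    load_series,
    recommend_stop,
)

__all__ = ["EvalConfig", "StageError", "run_evaluation", "run_monitor"]

log = logging.getLogger("plantrecon")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EvalConfig:
    """Scenario-level configuration of an evaluation run.

    ``scenario`` picks the default distance threshold (0.005 m indoor,
    0.01 m outdoor); ``custom`` requires ``threshold_d`` explicitly.
    """

    scenario: str = "indoor"
    threshold_d: Optional[float] = None
    icp: IcpConfig = field(default_factory=IcpConfig)
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    seed: int = 0
    output_dir: Union[str, Path] = "plantrecon_out"
    run_icp: bool = True
    pr_steps: int = 20

    def __post_init__(self) -> None:
        if self.scenario not in ("indoor", "outdoor", "custom"):
            raise ValueError("scenario must be indoor, outdoor, or custom")
        if self.threshold_d is None:
            if self.scenario == "indoor":
                self.threshold_d = INDOOR_THRESHOLD
            elif self.scenario == "outdoor":
                self.threshold_d = OUTDOOR_THRESHOLD
            else:
                raise ValueError("custom scenario requires an explicit threshold_d")
        if self.threshold_d <= 0:
            raise ValueError("threshold_d must be > 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
    return wrap


def run_evaluation(
    recon_path: Union[str, Path],
    gt_path: Union[str, Path],
    correspondences_path: Optional[Union[str, Path]] = None,
    bounds_path: Optional[Union[str, Path]] = None,
    config: EvalConfig = None,
) -> dict:
    """Run the full evaluation workflow and write a report bundle.

    Returns the report dictionary.  The bundle under ``config.output_dir``
    holds ``report.json``, ``pr_curve.csv``, ``labeled_precision.ply``,
    ``labeled_recall.ply``, ``manifest.json``, and ``run.log``.
    """
    config = config or EvalConfig()
    recon_path, gt_path = Path(recon_path), Path(gt_path)
    out_dir = Path(config.output_dir)

    staging = Path(tempfile.mkdtemp(prefix="plantrecon_"))
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    try:
        recon = _stage("load-reconstruction")(load_cloud, recon_path)
        gt = _stage("load-ground-truth")(load_cloud, gt_path)
        note(f"loaded reconstruction: {recon.count} points, ground truth: {gt.count} points")

        transform = SimilarityTransform.identity()
        if correspondences_path is not None:
            src, tgt = _stage("load-correspondences")(
                load_correspondences, correspondences_path)
            transform = _stage("initial-alignment")(
                estimate_initial_transform, src, tgt)
            note(f"initial alignment from {len(src)} correspondences, "
                 f"scale {transform.scale:.6g}")
        recon = apply_transform(recon, transform)

        if bounds_path is not None:
            bounds = _stage("load-bounds")(load_bounds, bounds_path)
            recon = _stage("crop-reconstruction")(crop_to_bounds, recon, bounds)
            gt = _stage("crop-ground-truth")(crop_to_bounds, gt, bounds)
            note(f"cropped to bounds: reconstruction {recon.count}, ground truth {gt.count}")

        if config.run_icp:
            result = _stage("icp-refinement")(
                icp_refine, recon, gt, SimilarityTransform.identity(), config.icp)
            recon = apply_transform(recon, result.transform)
            transform = result.transform.compose(transform)
            note(f"ICP: fitness {result.fitness:.4f}, inlier RMSE "
                 f"{result.inlier_rmse:.6g} m, {result.iterations_run} iterations")

        d = config.threshold_d
        report = _stage("evaluate")(evaluate_reconstruction, recon, gt, d)
        note(f"P(d)={report.precision:.2f} R(d)={report.recall:.2f} "
             f"F(d)={report.f1:.2f} at d={d} m")

        curve = _stage("pr-curve")(pr_curve, recon, gt, d / 5, d * 4, config.pr_steps)
        prec_labels = _stage("label-precision")(label_points, recon, gt, d)
        rec_labels = _stage("label-recall")(label_points, gt, recon, d)

        # --- write bundle to staging, then move into place
        report_dict = report.to_dict()
        report_dict["scenario"] = config.scenario
        report_dict["transform"] = transform.to_dict()
        with open(staging / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2)
        pd.DataFrame({
            "threshold": curve.thresholds,
            "precision": curve.precision_values,
            "recall": curve.recall_values,
            "f1": curve.f1_values,
        }).to_csv(staging / "pr_curve.csv", index=False)
        write_cloud(labeled_cloud(recon, prec_labels), staging / "labeled_precision.ply")
        write_cloud(labeled_cloud(gt, rec_labels), staging / "labeled_recall.ply")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
            "threshold_d": d,
            "icp": {
                "voxel_size": config.icp.voxel_size,
                "distance_threshold": config.icp.distance_threshold,
                "base_iterations": config.icp.base_iterations,
                "iteration_multiplier": config.icp.iteration_multiplier,
                "stages": config.icp.stages,
            },
            "inputs": {
                "reconstruction": {"path": str(recon_path), "sha256": _sha256(recon_path)},
                "ground_truth": {"path": str(gt_path), "sha256": _sha256(gt_path)},
            },
        }
        if correspondences_path is not None:
            manifest["inputs"]["correspondences"] = {
                "path": str(correspondences_path),
                "sha256": _sha256(Path(correspondences_path))}
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        (staging / "run.log").write_text("\n".join(log_lines) + "\n")

        out_dir.mkdir(parents=True, exist_ok=True)
        for item in staging.iterdir():
            shutil.move(str(item), out_dir / item.name)
        return report_dict
    finally:
        shutil.rmtree(staging, ignore_errors=True)


def run_monitor(
    series_path: Union[str, Path],
    config: EvalConfig = None,
) -> dict:
    """Plateau detection over a metric-series CSV; writes a decision bundle.

    The bundle holds ``decision.json`` and ``monitor_curve.csv`` (raw and
    interpolated series with the recommended iteration marked).
    """
    config = config or EvalConfig()
    out_dir = Path(config.output_dir)
    series = _stage("load-series")(load_series, series_path)
    pc = config.plateau
    interp = _stage("interpolate")(interpolate_series, series, pc)
    iteration, result = _stage("detect-plateau")(recommend_stop, series, pc)

    out_dir.mkdir(parents=True, exist_ok=True)
    decision = {
        "found": result.found,
        "plateau_index": result.plateau_index,
        "recommended_iteration": iteration,
        "config": {"theta": pc.theta, "consistency": pc.consistency,
                   "granularity": pc.granularity,
                   "total_iterations": pc.total_iterations},
    }
    with open(out_dir / "decision.json", "w") as fh:
        json.dump(decision, fh, indent=2)
    raw = pd.DataFrame({"iteration": series.iterations, "value": series.values,
                        "kind": "raw"})
    grid = pd.DataFrame({"iteration": interp.iterations, "value": interp.values,
                         "kind": "interpolated"})
    grid["recommended"] = grid["iteration"] == iteration
    raw["recommended"] = False
    pd.concat([raw, grid]).to_csv(out_dir / "monitor_curve.csv", index=False)
    return decision
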