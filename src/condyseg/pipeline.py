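"""End-to-end orchestration: volume -> presence -> segmentation -> thickness -> mesh.

``run_pipeline`` executes the full chain on one volume and writes every stage
output plus a manifest (configs, seeds, stage hashes, timings) sufficient to
reproduce the run bit for bit.  ``run_experiment`` drives Monte Carlo
cross-validation and writes per-repeat metric tables and distribution-overlay
figures.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .classifier import smooth_presence, predict_presence
from .core import LabelVolume, ValidationError, Volume
from .metrics import write_reports
from .thickness import (
    ThicknessReport,
    compare_distributions,
    extract_surfaces,
    measure_thickness,
    plot_distribution_overlay,
    thickness_distribution,
    thickness_table,
)
from .training import TrainedModels, load_models
from .unet import segment_slices, stack_to_labelvolume
from .viz import DEFAULT_COLORMAP, DEFAULT_RANGE_MM, colorize_mesh, mesh_from_labels, render_views

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_STAGE = 0, 2, 3


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    checkpoint_path: str | None = None
    input_format: str | None = None
    spacing_mm: float | None = None
    use_gold_labels: bool = False
    gold_labels_path: str | None = None
    presence_kernel_width: int = 5
    presence_threshold: float = 0.5
    bin_width_mm: float = 0.1
    colormap: str = DEFAULT_COLORMAP
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM
    view_angles: tuple = ((20.0, 30.0), (20.0, 210.0))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise ValidationError(f"input_path: {self.input_path} does not exist")
        if not self.use_gold_labels:
            if self.checkpoint_path is None or not Path(self.checkpoint_path).exists():
                raise ValidationError("checkpoint_path: missing (or set use_gold_labels)")


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage on one volume; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "seed": cfg.seed}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result, digest, info = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"hash": digest, "seconds": round(dt, 3), **info}
        logger.info("stage %-14s %6.2fs  %s", name, dt, info)
        return result

    if cfg.use_gold_labels:
        src = cfg.gold_labels_path or cfg.input_path
        labels = stage("labels", lambda: (
            (lv := vio.read_labelmap(src, cfg.input_format, cfg.spacing_mm)),
            _hash_array(lv.labels), {"source": "gold"}))
        volume = Volume((labels.labels > 0).astype(np.float64), labels.voxel_spacing_mm)
    else:
        volume = stage("read", lambda: (
            (v := vio.read_volume(cfg.input_path, cfg.input_format, cfg.spacing_mm)),
            _hash_array(v.intensities), {"shape": list(v.shape)}))
        models = load_models(cfg.checkpoint_path)
        presence = stage("presence", lambda: (
            (p := predict_presence(models.classifier, volume)),
            _hash_array(p.values), {"positive_slices": int(p.values.sum())}))
        smoothed = stage("smoothing", lambda: (
            (s := smooth_presence(presence, cfg.presence_kernel_width, cfg.presence_threshold)),
            _hash_array(s.values), {"positive_slices": int(s.values.sum())}))
        labels = stage("segmentation", lambda: (
            (lv := stack_to_labelvolume(
                segment_slices(models.unet, volume, smoothed), volume)),
            _hash_array(lv.labels), {"class_counts": np.bincount(
                lv.labels.ravel(), minlength=3).tolist()}))
        vio.write_labelmap(labels, out / "labels.nii.gz")

    tm = stage("thickness", lambda: (
        (t := measure_thickness(*extract_surfaces(labels))),
        _hash_array(t.thickness_mm), asdict(ThicknessReport.from_map(t))))
    thickness_table(tm).to_csv(out / "thickness.csv", index=False)

    curve = stage("distribution", lambda: (
        (c := thickness_distribution(tm, cfg.bin_width_mm)),
        _hash_array(c.density), {"bins": len(c.density)}))
    np.savetxt(out / "distribution.csv",
               np.column_stack([curve.bin_centers_mm, curve.density]),
               delimiter=",", header="bin_center_mm,density", comments="")

    cmesh = stage("mesh", lambda: (
        (cm := colorize_mesh(mesh_from_labels(labels, "outer"), tm,
                             cfg.colormap, tuple(cfg.range_mm))),
        _hash_array(cm.vertices), {"n_vertices": len(cm.vertices),
                                   "clamp_fraction": cm.clamp_fraction}))
    vio.write_mesh(cmesh, out / "condyle.ply")

    render = stage("render", lambda: (
        (r := render_views(cmesh, list(cfg.view_angles), out / "views")),
        "-", {"n_views": len(r.view_paths)}))

    manifest["outputs"] = {
        "labels": str(out / "labels.nii.gz") if not cfg.use_gold_labels else cfg.input_path,
        "thickness_csv": str(out / "thickness.csv"),
        "distribution_csv": str(out / "distribution.csv"),
        "mesh_ply": str(out / "condyle.ply"),
        "views": render.view_paths,
        "legend": render.legend_path,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_experiment(
    dataset,
    out_dir,
    ratio=(18, 5, 2),
    n_repeats: int = 50,
    cfg=None,
    unet_config=None,
    clf_config=None,
) -> "CVResult":
    """Monte Carlo cross-validation plus metric tables and overlay figures."""
    from .training import monte_carlo_cv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = monte_carlo_cv(dataset, ratio, n_repeats, cfg, unet_config, clf_config)
    frame = result.frame()
    frame.to_csv(out / "cv_metrics.csv", index=False)
    result.summary().to_csv(out / "cv_summary.csv")
    write_reports(result.reports, json_path=out / "cv_reports.json")

    # gold-vs-predicted thickness overlays for the last repeat's test subjects
    subjects = {s.subject_id: s for s in dataset}
    last = result.splits[-1]
    for sid in last.test_ids:
        s = subjects[sid]
        try:
            gold_curve = thickness_distribution(measure_thickness(*extract_surfaces(s.labels)))
            presence = smooth_presence(predict_presence(result.last_models.classifier, s.volume))
            pred_labels = stack_to_labelvolume(
                segment_slices(result.last_models.unet, s.volume, presence), s.volume)
            pred_curve = thickness_distribution(measure_thickness(*extract_surfaces(pred_labels)))
            report = compare_distributions(gold_curve, pred_curve)
            plot_distribution_overlay(report, out / f"overlay_{sid}.png")
        except ValidationError as exc:
            logger.warning("overlay for %s skipped: %s", sid, exc)
    return result
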