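"""End-to-end orchestration of processing stages 1–5.

The pipeline is a pure composition of the module operations: Stage 1
(optional bias correction, ROI, threshold, classification), Stage 2 (frame
selection), Stage 3 (QA map and pixel exclusions), Stage 4 (outlining with
A* bridging) and Stage 5 (scripted correction).  Stages 2, 3 and 5 are
optional and pass their inputs through unchanged when disabled.  Every
intermediate artifact is written to the output directory and content-hashed
into a manifest, so identical configuration and inputs yield an identical
manifest — the provenance an interactive workflow cannot provide.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from . import __version__
from .bias import correct_run, estimate_bias_field
from .correction import EditScript, apply_edit_script
from .errors import ValidationError
from .io import (
    read_logfile,
    read_run,
    write_mask_series,
    write_outlines,
    write_run,
)
from .masking import DEFAULT_SEED_QUANTILE, classify_run, compute_variance_map, edit_roi, fit_threshold, seed_roi
from .outlining import DEFAULT_EPS, outline_run
from .selection import apply_exclusions, compute_qa_map, exclusion_from_polygons, render_qa_png, select_frames
from .types import AnchorPoints, RegionOfInterest


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline invocation."""

    run_path: str
    out_dir: str
    bias_enabled: bool = False
    bias_scale: float = 30.0
    bias_model: str = "gaussian"
    roi_mask_path: Optional[str] = None
    roi_seed_quantile: float = DEFAULT_SEED_QUANTILE
    roi_additions_path: Optional[str] = None
    roi_removals_path: Optional[str] = None
    stage2_enabled: bool = False
    logfile_path: Optional[str] = None
    stage3_enabled: bool = False
    exclusions_path: Optional[str] = None
    anchors_path: Optional[str] = None
    astar_eps: float = DEFAULT_EPS
    stage5_enabled: bool = False
    edit_script_path: Optional[str] = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def required_inputs(self) -> list[str]:
        paths = [self.run_path]
        for flag, p in (
            (self.roi_mask_path is not None, self.roi_mask_path),
            (self.roi_additions_path is not None, self.roi_additions_path),
            (self.roi_removals_path is not None, self.roi_removals_path),
            (self.stage2_enabled, self.logfile_path),
            (self.stage3_enabled and self.exclusions_path is not None, self.exclusions_path),
            (self.anchors_path is not None, self.anchors_path),
            (self.stage5_enabled, self.edit_script_path),
        ):
            if flag:
                if p is None:
                    raise ValidationError("an enabled stage is missing its input path")
                paths.append(p)
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_roi(roi: RegionOfInterest, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, roi.mask.astype(np.uint8))
    return path


def read_roi(path) -> RegionOfInterest:
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValidationError("ROI file must hold a single 2-D page")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError("ROI file contains non-binary values")
    return RegionOfInterest(data.astype(bool))


def _load_polygons(path) -> list:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("polygons", [])
    return data


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    inputs = config.required_inputs()
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise ValidationError(f"missing input file(s): {missing}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    params: dict = {
        "bias": {"enabled": config.bias_enabled, "scale": config.bias_scale, "model": config.bias_model},
        "roi": {"seed_quantile": config.roi_seed_quantile, "mask_path": config.roi_mask_path},
        "astar_eps": config.astar_eps,
        "stages": {
            "2": config.stage2_enabled,
            "3": config.stage3_enabled,
            "5": config.stage5_enabled,
        },
    }

    run = read_run(config.run_path)

    # ---- stage 1: bias (optional) + ROI + threshold + classification ----
    if config.bias_enabled:
        field = estimate_bias_field(run, smoothing_scale=config.bias_scale, model=config.bias_model)
        run = correct_run(run, field)
        tifffile.imwrite(out / "bias_field.tif", field.field.astype(np.float64))
        artifacts["bias_field"] = out / "bias_field.tif"
        write_run(run, out / "corrected.nii")
        artifacts["corrected_run"] = out / "corrected.nii"

    if config.roi_mask_path:
        roi = read_roi(config.roi_mask_path)
    else:
        roi = seed_roi(compute_variance_map(run), quantile=config.roi_seed_quantile)
    additions = _load_polygons(config.roi_additions_path) if config.roi_additions_path else []
    removals = _load_polygons(config.roi_removals_path) if config.roi_removals_path else []
    if additions or removals:
        roi = edit_roi(roi, additions, removals)
    artifacts["roi"] = write_roi(roi, out / "roi.tif")

    model = fit_threshold(run, roi)
    _write_json(
        {
            "threshold": model.threshold,
            "mode_locations": list(model.mode_locations) if model.mode_locations else None,
            "bimodality_ok": model.bimodality_ok,
        },
        out / "threshold.json",
    )
    artifacts["threshold"] = out / "threshold.json"

    masks = classify_run(run, roi, model)
    artifacts["masks"] = write_mask_series(masks, out / "masks.nii")

    # ---- stage 2: frame selection ----
    if config.stage2_enabled:
        log = read_logfile(config.logfile_path, fps=run.fps if math.isfinite(run.fps) else None,
                           n_frames=run.frames)
        masks, mapping = select_frames(masks, log)
        run = run.with_intensities(run.intensities[sorted(mapping)])
        artifacts["masks_selected"] = write_mask_series(masks, out / "masks_selected.nii")
        _write_json({str(k): v for k, v in mapping.items()}, out / "frame_mapping.json")
        artifacts["frame_mapping"] = out / "frame_mapping.json"

    # ---- stage 3: QA + exclusions ----
    if config.stage3_enabled:
        qa = compute_qa_map(masks)
        tifffile.imwrite(out / "qa.tif", qa.proportion.astype(np.float64))
        artifacts["qa_map"] = out / "qa.tif"
        render_qa_png(qa, run.intensities[0], out / "qa.png")
        artifacts["qa_png"] = out / "qa.png"
        if config.exclusions_path:
            excl = exclusion_from_polygons(masks.shape[1:], _load_polygons(config.exclusions_path))
            masks = apply_exclusions(masks, excl)
    artifacts["masks_final"] = write_mask_series(masks, out / "masks_final.nii")

    # ---- stage 4: outlining ----
    anchors = None
    if config.anchors_path:
        a = json.loads(Path(config.anchors_path).read_text())
        anchors = AnchorPoints(
            larynx=(int(a["larynx"][0]), int(a["larynx"][1])),
            lips=(int(a["lips"][0]), int(a["lips"][1])),
        )
    outlines, records = outline_run(masks, run, anchors=anchors, eps=config.astar_eps)
    if outlines:
        artifacts["outlines"] = write_outlines(outlines, out / "outlines.csv", run_id=run.run_id)
    _write_json(records, out / "bridging.json")
    artifacts["bridging"] = out / "bridging.json"

    # ---- stage 5: scripted correction ----
    if config.stage5_enabled:
        script = EditScript.from_dict(json.loads(Path(config.edit_script_path).read_text()))
        outlines, audit = apply_edit_script(outlines, script)
        artifacts["outlines_corrected"] = write_outlines(
            outlines, out / "outlines_corrected.csv", run_id=run.run_id
        )
        _write_json(audit, out / "audit.json")
        artifacts["audit"] = out / "audit.json"

    manifest = {
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "artifacts": {name: _sha256(p) for name, p in sorted(artifacts.items())},
        "n_frames_out": masks.frames,
        "n_outlines": len(outlines),
        "bridged_frames": [r["frame"] for r in records if r["status"] == "bridged"],
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
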