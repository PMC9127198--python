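"""End-to-end analysis: video in, contraction metrics out.

``analyze_sequence`` chains DIC -> strain -> mask -> trace -> metrics on
an in-memory sequence; ``run_pipeline`` wraps it with a run directory,
an immutable config snapshot, per-stage artifact outputs and a manifest
with checksums, so a run is reproducible from its directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import beatrate as br
from . import dic as dicmod
from . import mask as maskmod
from . import strain as strainmod
from .config import ExperimentConfig
from .io import ImageSequence, write_metrics_json, write_trace_csv

log = logging.getLogger("cardiostrain")


@dataclass
class AnalysisResult:
    """All intermediate and final products of one video analysis."""

    displacement: dicmod.DisplacementField
    strain: strainmod.StrainField
    cell_mask: maskmod.CellMask
    trace: br.ContractionTrace
    metrics: br.BeatMetrics
    config: ExperimentConfig


def analyze_sequence(
    seq: ImageSequence,
    config: Optional[ExperimentConfig] = None,
    per_frame_mask: bool = False,
    progress: bool = False,
) -> AnalysisResult:
    """Run the full mechanical analysis on one image sequence.

    The cell mask is built once from the relaxed reference frame and
    reused for all frames (frame-to-frame cell motion is small compared
    with the subset size); ``per_frame_mask=True`` rebuilds it per frame.
    """
    cfg = config or ExperimentConfig(frame_rate=seq.frame_rate, pixel_size=seq.pixel_size)
    cfg.validate()

    log.info("DIC: %d frames, subset %d px, spacing %d px",
             seq.n_frames, cfg.subset_size, cfg.subset_spacing)
    disp = dicmod.correlate_sequence(seq, cfg, progress=progress)
    sf = strainmod.strain_from_displacement(disp)

    cm = maskmod.detect_cell_regions(
        np.asarray(seq.frames[0], dtype=float),
        sobel_threshold=cfg.sobel_threshold,
        dilation_radius=cfg.dilation_radius,
    )
    grid = (disp.grid_x, disp.grid_y)
    if per_frame_mask:
        valid = sf.valid.copy()
        for k in range(seq.n_frames):
            cmk = maskmod.detect_cell_regions(
                np.asarray(seq.frames[k], dtype=float),
                sobel_threshold=cfg.sobel_threshold,
                dilation_radius=cfg.dilation_radius,
            )
            gk = maskmod.mask_to_grid(cmk.pixel_mask, grid, cfg.subset_size)
            valid[k] &= gk
        sf = dataclasses.replace(sf, valid=valid)
        masked = sf
        if not valid.any():
            raise maskmod.EmptyMaskError("per-frame masking removed all points")
    else:
        cm.grid_mask = maskmod.mask_to_grid(cm.pixel_mask, grid, cfg.subset_size)
        masked, _ = maskmod.apply_mask(sf, cm.grid_mask)

    trace = br.compute_trace(masked)
    metrics = br.beat_metrics(trace, cfg.threshold_fraction)
    return AnalysisResult(
        displacement=disp,
        strain=masked,
        cell_mask=cm,
        trace=trace,
        metrics=metrics,
        config=cfg,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    seq: ImageSequence,
    out_dir,
    config: Optional[ExperimentConfig] = None,
    save_fields: bool = True,
) -> dict:
    """Analyze a video and persist every stage under one run directory.

    Writes config.json (immutable snapshot), displacement/strain field
    dumps, the cell mask, the trace CSV, the metrics JSON, and a
    manifest listing every artifact with its SHA-256 checksum.  Returns
    the manifest dict.  On stage failure, partial outputs are retained
    and the manifest records the failed stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or ExperimentConfig(frame_rate=seq.frame_rate, pixel_size=seq.pixel_size)
    cfg.validate()
    cfg.to_json(out_dir / "config.json")

    manifest = {"id": seq.id, "status": "running", "artifacts": {}, "failed_stage": None}
    try:
        result = analyze_sequence(seq, cfg)
    except Exception as exc:  # record, re-raise with context retained on disk
        manifest["status"] = "failed"
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    if save_fields:
        np.savez_compressed(
            out_dir / "displacement.npz",
            grid_x=result.displacement.grid_x,
            grid_y=result.displacement.grid_y,
            u_x=result.displacement.u_x,
            u_y=result.displacement.u_y,
            quality=result.displacement.quality,
            valid=result.displacement.valid,
        )
        np.savez_compressed(
            out_dir / "strain.npz",
            eps_xx=result.strain.eps_xx,
            eps_yy=result.strain.eps_yy,
            eps_xy=result.strain.eps_xy,
            eps_1=result.strain.eps_1,
            eps_2=result.strain.eps_2,
            valid=result.strain.valid,
        )
        np.save(out_dir / "cell_mask.npy", result.cell_mask.pixel_mask)
    write_trace_csv(result.trace, out_dir / "trace.csv")
    write_metrics_json(
        result.metrics,
        out_dir / "metrics.json",
        extra={"video_id": seq.id, "frame_rate": seq.frame_rate},
    )

    for p in sorted(out_dir.iterdir()):
        if p.name != "manifest.json":
            manifest["artifacts"][p.name] = _sha256(p)
    manifest["status"] = "ok"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
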