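"""Reading image sequences and writing pipeline outputs.

An :class:`ImageSequence` is the raw observable: ordered grayscale
frames with acquisition metadata (frame rate in fps, pixel size in
um/px).  Sequences are read from multi-page TIFF stacks or directories
of ordered single-frame images; metadata comes from an optional sidecar
JSON, overridable by explicit arguments (explicit beats implicit:
caller arguments > sidecar JSON > file tags).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .config import DEFAULT_FRAME_RATE_FPS, DEFAULT_PIXEL_SIZE_UM


class FormatError(ValueError):
    """Input data violates the expected file structure."""


@dataclass
class ImageSequence:
    """Ordered grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W)
    frame_rate: float = DEFAULT_FRAME_RATE_FPS
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be a (n, H, W) stack, got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise FormatError(
                f"an image sequence needs at least 2 frames, got {self.n_frames}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def read_sequence(
    path,
    frame_rate: Optional[float] = None,
    pixel_size: Optional[float] = None,
    id: Optional[str] = None,
) -> ImageSequence:
    """Read a multi-page TIFF or a directory of ordered frame images.

    Directory frames are taken in lexical filename order.  Explicit
    ``frame_rate`` / ``pixel_size`` arguments override sidecar-JSON
    metadata, which overrides defaults.  Bit depth is preserved.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp", ".jpg"}
        )
        if len(files) < 2:
            raise FormatError(f"directory {path} holds {len(files)} frame(s); need >= 2")
        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
        sidecar_meta = _read_sidecar(path / "metadata") if (path / "metadata.json").exists() else {}
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            raise FormatError(f"{path} holds a single frame; a sequence needs >= 2")
        if stack.ndim != 3:
            raise FormatError(f"{path}: expected grayscale pages, got shape {stack.shape}")
        sidecar_meta = _read_sidecar(path)

    meta = dict(sidecar_meta)
    fr = frame_rate if frame_rate is not None else meta.get("frame_rate", DEFAULT_FRAME_RATE_FPS)
    px = pixel_size if pixel_size is not None else meta.get("pixel_size", DEFAULT_PIXEL_SIZE_UM)
    seq_id = id if id is not None else meta.get("id", path.stem if not path.is_dir() else path.name)
    return ImageSequence(frames=stack, frame_rate=fr, pixel_size=px, id=seq_id, metadata=meta)


def write_sequence(seq: ImageSequence, path, sidecar: bool = True) -> None:
    """Write a sequence as a multi-page TIFF plus a metadata sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    if sidecar:
        meta = {
            "frame_rate": seq.frame_rate,
            "pixel_size": seq.pixel_size,
            "id": seq.id,
            **seq.metadata,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def seeding_density(cells: float, area_mm2: float) -> int:
    """Seeding density in cells/mm^2, truncated toward zero.

    Truncation (not rounding to nearest) reproduces the convention of
    reporting 3,370 cells/mm^2 for 120,000 cells over 35.6 mm^2.
    """
    if cells <= 0:
        raise ValueError(f"cells must be positive, got {cells}")
    if area_mm2 <= 0:
        raise ValueError(f"area_mm2 must be positive, got {area_mm2}")
    return math.trunc(cells / area_mm2)


def write_trace_csv(trace, path) -> None:
    """Write a contraction trace as CSV (frame, time_s, mean_eps2, abs_mean_eps2)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "frame": trace.frame_index,
            "time_s": trace.frame_index / trace.frame_rate,
            "mean_eps2": trace.mean_eps2,
            "abs_mean_eps2": trace.abs_mean_eps2,
        }
    )
    df.to_csv(path, index=False)


def write_metrics_json(metrics, path, extra: Optional[dict] = None) -> None:
    d = {
        "max_contractile_strain": metrics.max_contractile_strain,
        "rate_bpm": metrics.rate,
        "n_beats_used": metrics.n_beats_used,
        "peak_frames": list(metrics.peak_frames),
    }
    if metrics.rate_undefined_reason:
        d["rate_undefined_reason"] = metrics.rate_undefined_reason
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, default=_json_default)


def write_field_npz(path, **grids) -> None:
    """Dump gridded per-frame fields into one stacked array container."""
    np.savez_compressed(path, **grids)
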