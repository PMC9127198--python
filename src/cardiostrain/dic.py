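"""Subset-based digital image correlation (DIC).

Displacements are measured on a regular grid of square interrogation
subsets (default 48 x 48 px, spaced 12 px) by maximizing normalized
cross-correlation between each reference subset and a search window in
the deformed frame, then refining to sub-pixel precision with a locally
upsampled cross-correlation (matrix-multiply DFT).  Every frame is
correlated against frame 0 — the relaxed state — not incrementally.

Subsets whose reference texture is too flat to track, or whose
correlation peak is weak, are flagged invalid rather than silently
zeroed, so they can be excluded from downstream spatial averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from .config import ExperimentConfig
from .io import ImageSequence


@dataclass
class DisplacementField:
    """Per-frame gridded displacements relative to the reference frame.

    grid_x / grid_y are subset-center coordinates (px, reference frame);
    u_x / u_y are (n_frames, ny, nx) displacement grids in px; quality
    is the normalized-correlation peak in [0, 1]; valid flags subsets
    that tracked reliably.  Frame 0 is identically zero by construction.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    quality: np.ndarray
    valid: np.ndarray
    subset_size: int
    subset_spacing: int
    frame_rate: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.u_x.shape[0]

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.grid_x.shape


def build_grid(
    image_shape: Tuple[int, int], subset_size: int, spacing: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Subset-center grid, inset so every subset lies inside the image.

    Centers start at ``subset_size // 2`` and step by ``spacing``; for a
    480 px axis with 48 px subsets at 12 px spacing this yields
    floor((480 - 48) / 12) + 1 = 37 centers.
    """
    h, w = image_shape
    if subset_size > h or subset_size > w:
        raise ValueError(
            f"subset_size {subset_size} exceeds image shape {image_shape}"
        )
    if spacing <= 0 or subset_size <= 0:
        raise ValueError("subset_size and spacing must be positive")
    half = subset_size // 2
    ys = np.arange(half, h - subset_size + half + 1, spacing)
    xs = np.arange(half, w - subset_size + half + 1, spacing)
    grid_x, grid_y = np.meshgrid(xs, ys)
    return grid_x, grid_y


def _subset(img: np.ndarray, cy: int, cx: int, size: int) -> np.ndarray:
    half = size // 2
    return img[cy - half : cy - half + size, cx - half : cx - half + size]


@lru_cache(maxsize=8)
def _hann2d(size: int) -> np.ndarray:
    w = np.hanning(size)
    return w[:, None] * w[None, :]


def correlate_frame(
    reference: np.ndarray,
    deformed: np.ndarray,
    grid: Tuple[np.ndarray, np.ndarray],
    subset_size: int,
    search_radius: int = 10,
    upsample_factor: int = 50,
    texture_std_floor: float = 1e-3,
    quality_floor: float = 0.3,
) -> dict:
    """Correlate one deformed frame against the reference.

    Two stages per subset: an exhaustive integer-shift search over
    ``+/- search_radius`` maximizing zero-normalized cross-correlation,
    then sub-pixel refinement of the residual by upsampled
    cross-correlation on the integer-aligned subset pair.  Identical
    images therefore yield exactly zero at the integer stage.

    Returns dict with u_x, u_y, quality, valid grids.
    """
    reference = np.asarray(reference, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if reference.shape != deformed.shape:
        raise ValueError(
            f"frame shape mismatch: {reference.shape} vs {deformed.shape}"
        )
    grid_x, grid_y = grid
    ny, nx = grid_x.shape
    h, w = reference.shape
    half = subset_size // 2

    u_x = np.zeros((ny, nx))
    u_y = np.zeros((ny, nx))
    quality = np.zeros((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)

    for i in range(ny):
        for j in range(nx):
            cy, cx = int(grid_y[i, j]), int(grid_x[i, j])
            ref_sub = _subset(reference, cy, cx, subset_size)
            if ref_sub.std() < texture_std_floor:
                valid[i, j] = False
                continue

            # search window in the deformed frame, clipped at borders
            y0 = max(cy - half - search_radius, 0)
            x0 = max(cx - half - search_radius, 0)
            y1 = min(cy - half + subset_size + search_radius, h)
            x1 = min(cx - half + subset_size + search_radius, w)
            window = deformed[y0:y1, x0:x1]
            if window.shape[0] < subset_size or window.shape[1] < subset_size:
                valid[i, j] = False
                continue

            ncc = match_template(window, ref_sub, pad_input=False)
            peak_flat = int(np.argmax(ncc))
            py, px = np.unravel_index(peak_flat, ncc.shape)
            q = float(ncc[py, px])
            # integer displacement: template position inside window minus
            # the position corresponding to zero shift
            dy = (y0 + py) - (cy - half)
            dx = (x0 + px) - (cx - half)

            if q < quality_floor:
                valid[i, j] = False
                quality[i, j] = max(q, 0.0)
                continue

            # sub-pixel refinement on the integer-aligned pair; the Hann
            # window suppresses the periodic-boundary leakage that
            # otherwise dominates the sub-pixel error
            sy, sx = cy - half + dy, cx - half + dx
            frac_y = frac_x = 0.0
            if 0 <= sy and sy + subset_size <= h and 0 <= sx and sx + subset_size <= w:
                def_sub = deformed[sy : sy + subset_size, sx : sx + subset_size]
                if not np.array_equal(def_sub, ref_sub):
                    window = _hann2d(subset_size)
                    shift, _err, _ = phase_cross_correlation(
                        (ref_sub - ref_sub.mean()) * window,
                        (def_sub - def_sub.mean()) * window,
                        upsample_factor=upsample_factor,
                        normalization=None,
                    )
                    # shift registers def_sub onto ref_sub; content moved by -shift
                    ry, rx = -float(shift[0]), -float(shift[1])
                    if abs(ry) <= 1.5 and abs(rx) <= 1.5:
                        frac_y, frac_x = ry, rx

            u_y[i, j] = dy + frac_y
            u_x[i, j] = dx + frac_x
            quality[i, j] = min(max(q, 0.0), 1.0)

    return {"u_x": u_x, "u_y": u_y, "quality": quality, "valid": valid}


def correlate_sequence(
    seq: ImageSequence,
    config: Optional[ExperimentConfig] = None,
    progress: bool = False,
) -> DisplacementField:
    """DIC over a whole sequence: every frame vs frame 0 (relaxed state).

    Cumulative referencing (never incremental chaining) follows the
    standard workflow for contracting monolayers: frame 0 is the zero-
    strain configuration and all displacements are Lagrangian with
    respect to it.
    """
    cfg = config or ExperimentConfig()
    cfg.validate()
    frames = np.asarray(seq.frames, dtype=float)
    grid_x, grid_y = build_grid(frames.shape[1:], cfg.subset_size, cfg.subset_spacing)
    ny, nx = grid_x.shape
    n = frames.shape[0]

    u_x = np.zeros((n, ny, nx))
    u_y = np.zeros((n, ny, nx))
    quality = np.zeros((n, ny, nx))
    valid = np.ones((n, ny, nx), dtype=bool)
    quality[0] = 1.0

    ref = frames[0]
    for k in range(1, n):
        res = correlate_frame(
            ref,
            frames[k],
            (grid_x, grid_y),
            cfg.subset_size,
            search_radius=cfg.search_radius,
            upsample_factor=cfg.upsample_factor,
            texture_std_floor=cfg.texture_std_floor,
            quality_floor=cfg.quality_floor,
        )
        u_x[k], u_y[k] = res["u_x"], res["u_y"]
        quality[k], valid[k] = res["quality"], res["valid"]
        if progress:
            print(f"  DIC frame {k}/{n - 1}", end="\r")
    # frame 0 validity = reference texture check (its displacement is zero
    # by definition, but textureless subsets can never be tracked)
    half = cfg.subset_size // 2
    for i in range(ny):
        for j in range(nx):
            cy, cx = int(grid_y[i, j]), int(grid_x[i, j])
            sub = ref[cy - half : cy - half + cfg.subset_size,
                      cx - half : cx - half + cfg.subset_size]
            if sub.std() < cfg.texture_std_floor:
                valid[0, i, j] = False

    return DisplacementField(
        grid_x=grid_x,
        grid_y=grid_y,
        u_x=u_x,
        u_y=u_y,
        quality=quality,
        valid=valid,
        subset_size=cfg.subset_size,
        subset_spacing=cfg.subset_spacing,
        frame_rate=seq.frame_rate,
        meta={"reference": "frame0-cumulative", "criterion": "zncc+upsampled-dft"},
    )
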