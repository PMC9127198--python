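"""Cell-occupancy masking.

Contraction of a monolayer deforms the whole substrate, so unpopulated
regions carry small spurious strains.  A binary mask built from the
relaxed reference frame removes them: cell edges are found with a Sobel
filter and a user-defined threshold, dilated into enclosed areas, the
enclosed areas filled, and the footprint eroded back to the original
edge positions.  Unpopulated background is the inverse of the result.

The pixel-resolution mask is resampled onto the DIC subset grid by a
majority rule over each subset footprint, so a grid point is
cell-occupied iff most of its subset's pixels are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import filters, morphology


class EmptyMaskError(ValueError):
    """Masking removed every grid point; spatial averages are undefined."""


@dataclass
class CellMask:
    """Binary cell-occupancy mask at pixel and subset-grid resolution."""

    pixel_mask: np.ndarray
    grid_mask: Optional[np.ndarray] = None
    sobel_threshold: float = 0.0

    @property
    def coverage_fraction(self) -> float:
        return float(self.pixel_mask.mean())


def detect_cell_regions(
    image: np.ndarray,
    sobel_threshold: Optional[float] = None,
    dilation_radius: int = 5,
    erode_back: bool = True,
) -> CellMask:
    """Build a cell mask from a single grayscale frame.

    ``sobel_threshold`` is applied to the Sobel gradient magnitude;
    ``None`` uses Otsu's threshold on the gradient image as a
    data-driven default.  A threshold above the maximum gradient yields
    an empty mask with a warning, not an exception.  ``erode_back``
    erodes the filled regions by the dilation radius so the mask tracks
    the true cell boundary rather than the dilated one.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a single grayscale frame, got shape {image.shape}")
    grad = filters.sobel(image)
    if sobel_threshold is None:
        if grad.max() == 0:
            sobel_threshold = np.inf
        else:
            sobel_threshold = float(filters.threshold_otsu(grad))
    elif sobel_threshold <= 0:
        raise ValueError(f"sobel_threshold must be positive, got {sobel_threshold}")

    edges = grad > sobel_threshold
    if not edges.any():
        warnings.warn(
            "sobel_threshold exceeds the maximum gradient magnitude; "
            "cell mask is empty",
            stacklevel=2,
        )
        return CellMask(
            pixel_mask=np.zeros(image.shape, dtype=bool),
            sobel_threshold=float(sobel_threshold),
        )

    if dilation_radius > 0:
        selem = morphology.disk(dilation_radius)
        dilated = ndimage.binary_dilation(edges, structure=selem)
    else:
        dilated = edges
    filled = ndimage.binary_fill_holes(dilated)
    if erode_back and dilation_radius > 0:
        filled = ndimage.binary_erosion(
            filled, structure=morphology.disk(dilation_radius)
        )
    return CellMask(pixel_mask=filled, sobel_threshold=float(sobel_threshold))


def mask_to_grid(
    pixel_mask: np.ndarray,
    grid: Tuple[np.ndarray, np.ndarray],
    subset_size: int,
    rule: str = "majority",
) -> np.ndarray:
    """Resample a pixel mask onto the subset grid.

    ``majority``: occupied iff >= 50 % of the subset footprint is
    occupied.  ``any``: occupied iff any footprint pixel is.
    """
    pixel_mask = np.asarray(pixel_mask, dtype=bool)
    grid_x, grid_y = grid
    h, w = pixel_mask.shape
    half = subset_size // 2
    ny, nx = grid_x.shape
    out = np.zeros((ny, nx), dtype=bool)
    # integral image for O(1) footprint sums
    integral = np.pad(pixel_mask.astype(np.int64), ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    for i in range(ny):
        for j in range(nx):
            cy, cx = int(grid_y[i, j]), int(grid_x[i, j])
            y0, x0 = cy - half, cx - half
            y1, x1 = y0 + subset_size, x0 + subset_size
            if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
                raise ValueError(
                    f"subset footprint at grid ({i}, {j}) lies outside the image"
                )
            count = (
                integral[y1, x1] - integral[y0, x1] - integral[y1, x0] + integral[y0, x0]
            )
            frac = count / (subset_size * subset_size)
            out[i, j] = frac >= 0.5 if rule == "majority" else count > 0
    return out


def apply_mask(strain_field, grid_mask: np.ndarray):
    """Restrict a StrainField's validity to cell-occupied grid points.

    Returns (masked_field, n_retained).  Raises :class:`EmptyMaskError`
    if no grid point survives — silent NaN propagation downstream would
    be worse than an explicit failure.
    """
    grid_mask = np.asarray(grid_mask, dtype=bool)
    if grid_mask.shape != strain_field.valid.shape[1:]:
        raise ValueError(
            f"grid mask shape {grid_mask.shape} != strain grid "
            f"{strain_field.valid.shape[1:]}"
        )
    new_valid = strain_field.valid & grid_mask[None, :, :]
    n_retained = int(new_valid.any(axis=0).sum())
    if n_retained == 0:
        raise EmptyMaskError(
            "mask excludes every valid grid point; masked averages undefined"
        )
    import dataclasses

    masked = dataclasses.replace(strain_field, valid=new_valid)
    masked.meta = {**strain_field.meta, "masked": True, "n_retained": n_retained}
    return masked, n_retained
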