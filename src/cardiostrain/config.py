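"""Experiment configuration for the contractility pipeline.

Holds the analysis parameters of the standard workflow: DIC subset
geometry, beat-detection threshold, cell-mask parameters, and the
acquisition metadata (frame rate, pixel size) plus the grouping factors
used for statistics (cell line, substrate stiffness).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

#: Microscope pixel size implied by a 48 px subset spanning 31.2 um.
DEFAULT_PIXEL_SIZE_UM = 0.65

#: Acquisition frame rate used for rate conversion (frames per second).
DEFAULT_FRAME_RATE_FPS = 11.02

VALID_CELL_LINES = ("control", "patient")
VALID_STIFFNESS_KPA = (10, 30, 50)


@dataclass
class SeedingSpec:
    """Cell seeding: count of cells plated over a patterned area."""

    cells: int = 120_000
    area_mm2: float = 35.6


@dataclass
class ExperimentConfig:
    """Parameters of one analysis run.

    subset_size / subset_spacing are in pixels and control the DIC grid;
    threshold_fraction is the fraction of the global trace peak used for
    beat detection; sobel_threshold (None = Otsu on the gradient
    magnitude) and dilation_radius control the cell mask.
    """

    subset_size: int = 48
    subset_spacing: int = 12
    threshold_fraction: float = 0.6
    sobel_threshold: Optional[float] = None
    dilation_radius: int = 5
    frame_rate: float = DEFAULT_FRAME_RATE_FPS
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    cell_line: Optional[str] = None
    stiffness_kpa: Optional[int] = None
    seeding: SeedingSpec = field(default_factory=SeedingSpec)
    search_radius: int = 12
    upsample_factor: int = 50
    quality_floor: float = 0.3
    texture_std_floor: float = 1e-3

    def validate(self) -> None:
        """Raise ``ValueError`` on any invariant violation, before compute."""
        if self.subset_size <= 0:
            raise ValueError(f"subset_size must be positive, got {self.subset_size}")
        if self.subset_spacing <= 0:
            raise ValueError(
                f"subset_spacing must be positive, got {self.subset_spacing}"
            )
        if self.subset_spacing > self.subset_size:
            raise ValueError(
                "subset_spacing must not exceed subset_size "
                f"({self.subset_spacing} > {self.subset_size})"
            )
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be non-negative")
        if self.cell_line is not None and self.cell_line not in VALID_CELL_LINES:
            raise ValueError(
                f"cell_line must be one of {VALID_CELL_LINES}, got {self.cell_line!r}"
            )
        if self.stiffness_kpa is not None and self.stiffness_kpa not in VALID_STIFFNESS_KPA:
            raise ValueError(
                f"stiffness_kpa must be one of {VALID_STIFFNESS_KPA}, "
                f"got {self.stiffness_kpa!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        seeding = d.pop("seeding", None)
        cfg = cls(**d)
        if seeding is not None:
            cfg.seeding = SeedingSpec(**seeding)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
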