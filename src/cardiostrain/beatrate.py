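"""Contraction traces and beat metrics.

The masked second-principal-strain field is reduced to a per-frame
spatial mean — the contraction trace — from which the two headline
metrics follow:

* **maximum contractile strain** ``|eps2_max|``: the maximum over frames
  of the magnitude of the masked mean eps_2;
* **spontaneous contraction rate** in beats/min, from the midpoints of
  the crossings of the trace with a line at 60 % of its global peak.

For each maximal contiguous excursion of the trace above the 60 % line,
the two threshold crossings are located by linear interpolation between
the bracketing frames and their (frame-axis) midpoint marks the beat.
Mean successive midpoint spacing, divided by the frame rate, gives
seconds per beat, hence BPM.  Excursions truncated by the video start
or end are discarded — their midpoints would be biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .mask import EmptyMaskError


@dataclass
class ContractionTrace:
    """Per-frame masked spatial mean of the contractile strain."""

    frame_index: np.ndarray
    mean_eps2: np.ndarray
    frame_rate: float
    n_valid_points: Optional[np.ndarray] = None

    @property
    def abs_mean_eps2(self) -> np.ndarray:
        return np.abs(self.mean_eps2)

    @property
    def times(self) -> np.ndarray:
        return self.frame_index / self.frame_rate

    def __len__(self) -> int:
        return len(self.frame_index)


@dataclass
class BeatMetrics:
    """Headline metrics of one video."""

    max_contractile_strain: float
    rate: Optional[float]
    n_beats_used: int
    peak_frames: List[float] = field(default_factory=list)
    rate_undefined_reason: Optional[str] = None


def compute_trace(strain_field) -> ContractionTrace:
    """Spatial mean of eps_2 over valid, cell-occupied grid points, per frame.

    Frames with zero valid points are flagged as gaps (NaN mean) but do
    not abort the trace; a field with no valid points at all does.
    """
    valid = strain_field.valid
    if not valid.any():
        raise EmptyMaskError("no valid grid points anywhere in the sequence")
    n = strain_field.n_frames
    if n < 2:
        raise ValueError("trace needs at least 2 frames")
    mean = np.full(n, np.nan)
    counts = valid.reshape(n, -1).sum(axis=1)
    for k in range(n):
        if counts[k]:
            mean[k] = strain_field.eps_2[k][valid[k]].mean()
    return ContractionTrace(
        frame_index=np.arange(n),
        mean_eps2=mean,
        frame_rate=strain_field.frame_rate,
        n_valid_points=counts,
    )


def max_contractile_strain(trace: ContractionTrace) -> float:
    """Maximum over frames of |mean eps_2| — the contractility metric."""
    y = trace.abs_mean_eps2
    return float(np.nanmax(y))


def detect_beats(
    trace: ContractionTrace,
    threshold_fraction: float = 0.6,
    min_excursion_frames: int = 2,
) -> np.ndarray:
    """Beat locations (fractional frames) by the 60 %-crossing midpoint rule.

    The threshold is ``threshold_fraction`` of the global trace peak
    (whole-video peak, not per-beat).  Each maximal run of frames
    strictly above the threshold contributes one beat at the midpoint of
    its two interpolated threshold crossings.  Runs cut by the video
    boundary, or shorter than ``min_excursion_frames``, are discarded.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError(
            f"threshold_fraction must be in (0, 1), got {threshold_fraction}"
        )
    y = np.nan_to_num(trace.abs_mean_eps2, nan=0.0)
    peak = y.max()
    if peak <= 0:
        return np.array([])
    thr = threshold_fraction * peak

    above = y > thr
    midpoints = []
    n = len(y)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # run i..j inclusive
        if i > 0 and j < n - 1 and (j - i + 1) >= min_excursion_frames:
            # rising crossing between i-1 and i
            t_left = (i - 1) + (thr - y[i - 1]) / (y[i] - y[i - 1])
            # falling crossing between j and j+1
            t_right = j + (y[j] - thr) / (y[j] - y[j + 1])
            midpoints.append(0.5 * (t_left + t_right))
        i = j + 1
    return np.asarray(midpoints)


def contraction_rate(peak_frames: np.ndarray, frame_rate: float) -> float:
    """Spontaneous rate in beats/min from beat midpoints.

    Mean successive spacing (frames) -> seconds per beat -> BPM.
    """
    peak_frames = np.asarray(peak_frames, dtype=float)
    if len(peak_frames) < 2:
        raise ValueError(
            f"rate needs >= 2 beats, got {len(peak_frames)} midpoint(s)"
        )
    if frame_rate <= 0:
        raise ValueError(f"frame_rate must be positive, got {frame_rate}")
    mean_spacing = float(np.diff(peak_frames).mean())
    seconds_per_beat = mean_spacing / frame_rate
    return 60.0 / seconds_per_beat


def beat_metrics(
    trace: ContractionTrace,
    threshold_fraction: float = 0.6,
    min_excursion_frames: int = 2,
) -> BeatMetrics:
    """Both headline metrics; rate is None (with reason) below 2 beats."""
    peaks = detect_beats(trace, threshold_fraction, min_excursion_frames)
    strain_max = max_contractile_strain(trace)
    if len(peaks) >= 2:
        rate = contraction_rate(peaks, trace.frame_rate)
        reason = None
    else:
        rate = None
        reason = (
            f"only {len(peaks)} complete beat(s) detected; "
            "rate needs at least 2"
        )
    return BeatMetrics(
        max_contractile_strain=strain_max,
        rate=rate,
        n_beats_used=len(peaks),
        peak_frames=list(peaks),
        rate_undefined_reason=reason,
    )
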