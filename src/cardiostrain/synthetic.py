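"""Synthetic contracting-monolayer videos with analytic ground truth.

The generator emulates the observable the pipeline is designed for:
a chevron-micropatterned monolayer (vertical lanes of prescribed width
joined by angled bridges) carrying a high-contrast speckle texture,
contracting periodically with a prescribed peak contractile strain and
spontaneous rate, imaged at a fixed frame rate.

Every video comes with a :class:`GroundTruth` carrying the analytic
displacement and strain fields, so each downstream stage (DIC, strain,
masking, beat detection) is testable by parameter recovery rather than
by eyeballing.

Motion models
-------------
``rigid_translation``
    whole-field translation, zero strain everywhere — a pure DIC check.
``uniaxial_contraction``
    vertical contraction toward a horizontal centerline,
    ``U_y = -a(t) (y - y0)``, so ``eps_yy = -a(t)`` uniformly; mimics
    lane-aligned myofibril shortening.
``biaxial_contraction``
    the uniaxial field plus a transverse component
    ``U_x = -r a(t) (x - x0)`` with ratio ``r < 1``.

The twitch amplitude ``a(t)`` is a train of raised-cosine pulses: any
smooth unimodal pulse supports the 60 %-crossing rate algorithm, and the
raised cosine has exact, simple threshold crossings.  Beat centers sit
at ``(k + 1/2) * period`` so frame 0 is always the relaxed state and the
first pulse is not truncated by the video start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import DEFAULT_FRAME_RATE_FPS, DEFAULT_PIXEL_SIZE_UM
from .io import ImageSequence

MOTION_MODELS = ("rigid_translation", "uniaxial_contraction", "biaxial_contraction")


@dataclass
class PatternSpec:
    """Geometry of the chevron micropattern, physical units.

    lane_width and lane_pitch in um; bridge_angle in degrees from
    vertical; field_size in pixels (rows, cols); pixel_size in um/px.
    bridge_pitch is the perpendicular spacing of the bridge stripes.
    """

    lane_width: float = 30.0
    bridge_angle: float = 15.0
    lane_pitch: float = 60.0
    field_size: Tuple[int, int] = (480, 480)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    bridge_pitch: float = 180.0

    def validate(self) -> None:
        if self.lane_width <= 0:
            raise ValueError(f"lane_width must be positive, got {self.lane_width}")
        if not 0 <= self.bridge_angle < 90:
            raise ValueError(
                f"bridge_angle must be in [0, 90) degrees, got {self.bridge_angle}"
            )
        if self.lane_pitch <= self.lane_width:
            raise ValueError(
                f"lane_pitch ({self.lane_pitch}) must exceed lane_width ({self.lane_width})"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.bridge_pitch <= self.lane_width:
            raise ValueError("bridge_pitch must exceed lane_width")
        min_px = 3 * self.lane_pitch / self.pixel_size
        if min(self.field_size) < min_px:
            raise ValueError(
                f"field_size {self.field_size} must span >= 3 lane pitches "
                f"({min_px:.0f} px)"
            )


@dataclass
class ContractionWaveformSpec:
    """Prescribed contraction waveform of a synthetic video.

    rate in beats/min; peak_strain is the magnitude of the prescribed
    contractile strain at systole (dimensionless); pulse_width in
    seconds (None = half the beat period); duration in seconds;
    noise_sd in intensity units of the 0..1 template.
    """

    rate: float = 42.0
    peak_strain: float = 0.05
    pulse_width: Optional[float] = None
    duration: float = 10.0
    frame_rate: float = DEFAULT_FRAME_RATE_FPS
    noise_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not 0 < self.peak_strain < 0.5:
            raise ValueError(
                f"peak_strain must be in (0, 0.5), got {self.peak_strain}"
            )
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if self.pulse_width is not None and self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")

    @property
    def period(self) -> float:
        """Beat period in seconds."""
        return 60.0 / self.rate

    @property
    def effective_pulse_width(self) -> float:
        """Twitch duration in seconds.

        Default 0.7 of the beat period: spontaneous stem-cell-derived
        cardiomyocyte twitches are slow relative to the cycle, and the
        region above 60 % of peak (0.31 of the period for a raised
        cosine of this width) then always spans at least two frames at
        11 fps for rates up to ~100 BPM.
        """
        return self.pulse_width if self.pulse_width is not None else 0.7 * self.period

    def beat_centers(self) -> np.ndarray:
        """Times of systolic peaks whose pulses lie fully inside the video."""
        centers = []
        k = 0
        half = self.effective_pulse_width / 2.0
        while True:
            tc = (k + 0.5) * self.period
            if tc + half > self.duration:
                break
            centers.append(tc)
            k += 1
        return np.asarray(centers)

    def amplitude(self, t) -> np.ndarray:
        """Twitch amplitude a(t): raised-cosine pulses peaking at peak_strain."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        w = self.effective_pulse_width
        for tc in self.beat_centers():
            inside = np.abs(t - tc) <= w / 2.0
            out = np.where(
                inside,
                np.maximum(out, self.peak_strain * 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - tc) / w))),
                out,
            )
        return out


@dataclass
class GroundTruth:
    """Analytic truth attached to a synthetic video.

    displacement_fn(x, y, t) -> (U_x, U_y) in px; strain_fn(x, y, t) ->
    (eps_xx, eps_yy, eps_xy).  strain_fn is the exact symmetric gradient
    of displacement_fn.
    """

    displacement_fn: Callable
    strain_fn: Callable
    true_rate: float
    true_peak_mean_contractile_strain: float
    motion_model: str = ""
    pattern_mask: Optional[np.ndarray] = None
    waveform: Optional[ContractionWaveformSpec] = None
    params: dict = field(default_factory=dict)


def generate_chevron_mask(spec: PatternSpec) -> np.ndarray:
    """Binary chevron-pattern mask: vertical lanes plus angled bridges.

    Foreground (True) pixels are pattern area available to cells.
    With bridge_angle == 0 the bridges would be parallel to the lanes,
    so the degenerate case yields plain lanes with no bridges.
    """
    spec.validate()
    h, w = spec.field_size
    y, x = np.mgrid[0:h, 0:w].astype(float)
    x_um = x * spec.pixel_size
    y_um = y * spec.pixel_size

    lanes = (x_um % spec.lane_pitch) < spec.lane_width
    if spec.bridge_angle == 0:
        return lanes
    theta = np.deg2rad(spec.bridge_angle)
    # stripes running at `theta` from vertical: perpendicular coordinate q
    q = x_um * np.cos(theta) - y_um * np.sin(theta)
    bridges = (q % spec.bridge_pitch) < spec.lane_width
    return lanes | bridges


def analytic_foreground_fraction(spec: PatternSpec) -> float:
    """Exact area fraction of the vector pattern within the field.

    Computed from the vector geometry (union of lane and bridge stripe
    polygons clipped to the field rectangle), independent of the pixel
    rasterization, so it can serve as an oracle for the rasterized mask.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    h, w = spec.field_size
    # pixel centers sit at k * pixel_size; the sampled field spans
    # [-px/2, (n - 1/2) * px] along each axis
    x_lo, x_hi = -0.5 * spec.pixel_size, (w - 0.5) * spec.pixel_size
    y_lo, y_hi = -0.5 * spec.pixel_size, (h - 0.5) * spec.pixel_size
    field = box(x_lo, y_lo, x_hi, y_hi)

    polys = []
    k0 = int(np.floor(x_lo / spec.lane_pitch)) - 1
    k1 = int(np.ceil(x_hi / spec.lane_pitch)) + 1
    for k in range(k0, k1 + 1):
        polys.append(
            box(k * spec.lane_pitch, y_lo, k * spec.lane_pitch + spec.lane_width, y_hi)
        )
    if spec.bridge_angle != 0:
        theta = np.deg2rad(spec.bridge_angle)
        # stripe: k*bp <= q < k*bp + w with q = x cos(theta) - y sin(theta);
        # corners of the field bound the q range
        corners_q = [
            xx * np.cos(theta) - yy * np.sin(theta)
            for xx in (x_lo, x_hi)
            for yy in (y_lo, y_hi)
        ]
        q_min, q_max = min(corners_q), max(corners_q)
        kb0 = int(np.floor(q_min / spec.bridge_pitch)) - 1
        kb1 = int(np.ceil(q_max / spec.bridge_pitch)) + 1
        # stripe polygon from its two bounding lines intersected with the field:
        # parametrize by the along-stripe direction d = (sin t, cos t)
        d = np.array([np.sin(theta), np.cos(theta)])
        n_hat = np.array([np.cos(theta), -np.sin(theta)])
        span = 2 * max(x_hi - x_lo, y_hi - y_lo) + abs(q_max) + abs(q_min)
        from shapely.geometry import Polygon

        for k in range(kb0, kb1 + 1):
            q_a = k * spec.bridge_pitch
            q_b = q_a + spec.lane_width
            p1 = q_a * n_hat - span * d
            p2 = q_a * n_hat + span * d
            p3 = q_b * n_hat + span * d
            p4 = q_b * n_hat - span * d
            polys.append(Polygon([p1, p2, p3, p4]))

    pattern = unary_union(polys).intersection(field)
    return float(pattern.area / field.area)


def generate_speckle(
    shape: Tuple[int, int],
    density: float = 0.10,
    rng_seed: int = 0,
    dot_sigma: float = 1.0,
) -> np.ndarray:
    """Random high-contrast speckle texture in [0, 1], reproducible by seed.

    Random impulses at the given areal density are blurred to ~2 px
    grains, giving an autocorrelation width far below the 48 px subset.
    density == 0 returns a uniform (featureless) image.
    """
    if not 0 <= density < 1:
        raise ValueError(f"density must be in [0, 1), got {density}")
    if density == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(rng_seed)
    dots = (rng.random(shape) < density).astype(float)
    img = ndimage.gaussian_filter(dots, dot_sigma)
    peak = img.max()
    if peak > 0:
        img = img / peak
    return img


def _make_motion(model: str, waveform: ContractionWaveformSpec, shape, params: dict):
    """Build (displacement_fn, strain_fn, inverse_map_fn) for a motion model.

    inverse_map_fn(t) returns a function (x_out, y_out) -> (x_src, y_src)
    for backward warping; all models here are affine so the inverse is
    exact.
    """
    h, w = shape
    a_of_t = waveform.amplitude
    peak = waveform.peak_strain

    if model == "rigid_translation":
        dx, dy = params.get("shift", (3.0, -2.0))

        def displacement_fn(x, y, t):
            s = a_of_t(t) / peak
            return s * dx * np.ones_like(np.asarray(x, float)), s * dy * np.ones_like(
                np.asarray(y, float)
            )

        def strain_fn(x, y, t):
            z = np.zeros_like(np.asarray(x, float))
            return z, z.copy(), z.copy()

        def inverse_map(t):
            s = float(a_of_t(t))

            def inv(xo, yo):
                return xo - s * dx, yo - s * dy

            return inv

        true_peak = 0.0

    elif model in ("uniaxial_contraction", "biaxial_contraction"):
        y0 = params.get("y0", (h - 1) / 2.0)
        x0 = params.get("x0", (w - 1) / 2.0)
        r = params.get("transverse_ratio", 0.5) if model == "biaxial_contraction" else 0.0

        def displacement_fn(x, y, t):
            a = a_of_t(t)
            ux = -r * a * (np.asarray(x, float) - x0)
            uy = -a * (np.asarray(y, float) - y0)
            return ux, uy

        def strain_fn(x, y, t):
            a = a_of_t(t)
            shp = np.broadcast(np.asarray(x, float), np.asarray(y, float)).shape
            exx = np.full(shp, -r * a)
            eyy = np.full(shp, -a)
            exy = np.zeros(shp)
            return exx, eyy, exy

        def inverse_map(t):
            a = float(a_of_t(t))

            def inv(xo, yo):
                xs = (xo - r * a * x0) / (1.0 - r * a) if r else xo
                ys = (yo - a * y0) / (1.0 - a)
                return xs, ys

            return inv

        # eps_2 = -a everywhere (most compressive), so the mean over any
        # mask peaks at -peak_strain
        true_peak = peak
    else:
        raise ValueError(f"unknown motion_model {model!r}; choose from {MOTION_MODELS}")

    return displacement_fn, strain_fn, inverse_map, true_peak


def synthesize_video(
    mask: Optional[np.ndarray],
    speckle: np.ndarray,
    waveform: ContractionWaveformSpec,
    motion_model: str = "uniaxial_contraction",
    motion_params: Optional[dict] = None,
    background: float = 0.15,
    subset_size: int = 48,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    video_id: str = "synthetic",
) -> Tuple[ImageSequence, GroundTruth]:
    """Warp a speckled pattern template by a known displacement field.

    Frame 0 is the relaxed state (zero displacement) and is bit-identical
    to the undeformed template.  Warping is backward mapping with bicubic
    interpolation; intensity noise, if any, is added after warping
    (camera noise, not tissue motion).  Returns the video and its
    analytic :class:`GroundTruth`.
    """
    waveform.validate()
    motion_params = dict(motion_params or {})
    speckle = np.asarray(speckle, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != speckle.shape:
            raise ValueError(
                f"mask shape {mask.shape} != speckle shape {speckle.shape}"
            )
        template = np.where(mask, background + (1.0 - background) * speckle, background * 0.6)
    else:
        template = background + (1.0 - background) * speckle

    h, w = template.shape
    disp_fn, strain_fn, inverse_map, true_peak = _make_motion(
        motion_model, waveform, template.shape, motion_params
    )

    times = np.arange(int(round(waveform.duration * waveform.frame_rate))) / waveform.frame_rate
    if len(times) < 2:
        raise ValueError("duration x frame_rate must give at least 2 frames")

    # DIC search-range sanity: peak displacement vs half subset
    yy, xx = np.mgrid[0:h, 0:w]
    t_peak = waveform.beat_centers()
    if len(t_peak):
        ux, uy = disp_fn(xx[:: h // 8 or 1, :: w // 8 or 1], yy[:: h // 8 or 1, :: w // 8 or 1], t_peak[0])
        peak_disp = float(np.max(np.hypot(ux, uy)))
        if peak_disp > subset_size / 2:
            warnings.warn(
                f"peak displacement {peak_disp:.1f} px exceeds subset_size/2 "
                f"({subset_size / 2:.0f} px): DIC search range at risk",
                stacklevel=2,
            )

    rng = np.random.default_rng(waveform.rng_seed)
    out_y, out_x = np.mgrid[0:h, 0:w].astype(float)
    frames = np.empty((len(times), h, w), dtype=float)
    frames[0] = template
    for i, t in enumerate(times[1:], start=1):
        inv = inverse_map(t)
        xs, ys = inv(out_x, out_y)
        frames[i] = ndimage.map_coordinates(
            template, [ys, xs], order=3, mode="nearest"
        )
    if waveform.noise_sd > 0:
        noise = rng.normal(0.0, waveform.noise_sd, frames.shape)
        noise[0] = 0.0  # frame 0 stays bit-identical to the template
        frames = frames + noise

    seq = ImageSequence(
        frames=frames,
        frame_rate=waveform.frame_rate,
        pixel_size=pixel_size,
        id=video_id,
        metadata={
            "synthetic": True,
            "motion_model": motion_model,
            "warp": "backward-bicubic",
            "rate_bpm": waveform.rate,
            "peak_strain": waveform.peak_strain,
        },
    )
    truth = GroundTruth(
        displacement_fn=disp_fn,
        strain_fn=strain_fn,
        true_rate=waveform.rate,
        true_peak_mean_contractile_strain=true_peak,
        motion_model=motion_model,
        pattern_mask=mask,
        waveform=waveform,
        params=motion_params,
    )
    return seq, truth


def synthesize_trace(
    waveform: ContractionWaveformSpec,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sampled mean-contractile-strain trace implied by a waveform.

    Returns (times_s, mean_eps2) where mean_eps2 = -a(t): the trace the
    pipeline would produce from a noiseless uniaxial video.
    """
    waveform.validate()
    n = int(round(waveform.duration * waveform.frame_rate))
    times = np.arange(n) / waveform.frame_rate
    return times, -waveform.amplitude(times)


def save_video(seq: ImageSequence, truth: GroundTruth, path) -> None:
    """Write the video as multi-page TIFF (16-bit) plus a sidecar JSON."""
    import tifffile

    path = Path(path)
    lo, hi = seq.frames.min(), seq.frames.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    u16 = np.clip((seq.frames - lo) * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, u16, photometric="minisblack")
    wf = truth.waveform
    side = {
        "frame_rate": seq.frame_rate,
        "pixel_size": seq.pixel_size,
        "id": seq.id,
        "motion_model": truth.motion_model,
        "true_rate_bpm": truth.true_rate,
        "true_peak_mean_contractile_strain": truth.true_peak_mean_contractile_strain,
        "warp": "backward-bicubic",
        "intensity_scale": {"lo": float(lo), "hi": float(hi)},
    }
    if wf is not None:
        side["waveform"] = {
            "rate": wf.rate,
            "peak_strain": wf.peak_strain,
            "pulse_width": wf.effective_pulse_width,
            "duration": wf.duration,
            "frame_rate": wf.frame_rate,
            "noise_sd": wf.noise_sd,
            "rng_seed": wf.rng_seed,
        }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(side, fh, indent=2)
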