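# Methods

This note documents the measurement model behind `cardiostrain`, the
defaults and why they were chosen, what the synthetic validation data do and
do not emulate, and the numerical decisions a maintainer should know about.

## Measurement model

A contracting cardiomyocyte monolayer on a compliant substrate is imaged in
brightfield at a fixed frame rate. The cells' own phase texture acts as the
tracking pattern. We model the image sequence as a reference (relaxed)
texture advected by a smooth, in-plane displacement field `U(x, t)`; the
observable of interest is the infinitesimal strain tensor
`ε = ½(∇U + ∇Uᵀ)` and specifically its smaller eigenvalue ε₂, the most
compressive principal strain. In an aligned monolayer contraction is
predominantly along the lane axis, but the cells in the angled bridge
regions contract off-axis; using the principal decomposition rather than
ε_yy makes the metric orientation-free.

Per video the pipeline reports:

* `|ε₂_max|` — maximum over frames of |masked spatial mean of ε₂|. The mean
  is taken over valid, cell-occupied subset-grid points; the maximum over
  frames picks out systole.
* spontaneous rate (BPM) — from the trace of the masked mean against time.

### Digital image correlation

Displacements are estimated per square subset against **frame 0** (every
frame vs. the reference, never incremental chaining, so errors do not
accumulate over the video and frame 0 is exactly zero by construction).

* Subset size 48 px, spacing 12 px — at 0.65 µm/px this is a
  31.2 µm interrogation window, several myofibril widths, stepped finely
  enough that the strain kernel resolves the lane-scale strain pattern.
* Integer stage: exhaustive zero-normalized cross-correlation (ZNCC) over a
  ± `search_radius` window (default 12 px). ZNCC is invariant to intensity
  offset and gain, which covers slow illumination drift. Identical subsets
  give exactly zero displacement — there is no sub-pixel jitter on static
  regions, because the sub-pixel stage only runs when the aligned subsets
  differ.
* Sub-pixel stage: upsampled cross-correlation (matrix-multiply DFT) to
  1/50 px on the integer-aligned, mean-subtracted, Hann-windowed subset
  pair. The window suppresses periodic-boundary leakage, which otherwise
  dominates sub-pixel error (~0.05 px without, ~0.01 px with, on smooth
  speckle). This is a deliberate simplification relative to full iterative
  warping DIC: it estimates translation only per subset, which is accurate
  while the within-subset strain `ε·(subset/2) ≲ 1 px` — satisfied up to
  ~5 % strain at 48 px subsets, and degrading gracefully (toward the subset
  mean) beyond.
* Quality and validity: the ZNCC peak is kept as a per-subset quality score;
  subsets with reference-texture standard deviation below a floor, or peak
  quality below `quality_floor` (default 0.3), are flagged invalid and
  **excluded** from spatial averages. Zeroing them instead would bias the
  mean strain toward zero.

### Strain kernels

Gradients are computed on the subset grid by separable convolution: a 5-tap
derivative kernel `[1, −8, 0, 8, −1]/12` along the derivative axis and a
binomial smoother `[1, 4, 6, 4, 1]/16` transverse. The derivative kernel
has zero mean and exact unit first moment, so **linear displacement fields
(uniform strain) are differentiated exactly**; its frequency response
`(8 sin ω − sin 2ω)/6` is fourth-order accurate and is exposed as
`derivative_response` so tests can bound the error on sinusoidal fields
analytically. A plain central-difference kernel is available
(`kernel="central3"`) for cross-validation. Derivatives per grid step are
divided by the subset spacing (px), making strain dimensionless — the
classic off-by-spacing bug is guarded by a dedicated test.

Grid points whose 5×5 kernel support overruns the grid border or touches an
invalid displacement point are flagged invalid (binary erosion of the
validity mask), so invalidity propagates rather than leaking smoothed
garbage into averages.

The small-strain tensor is used without finite-strain (Green–Lagrange)
terms: at the ≤ 15 % strains seen in these monolayers the quadratic
correction is second-order (≤ ~1 % of the strain itself) and omitting it
matches the convention of gradient-of-displacement analysis.

### Cell mask

Substrate deformation extends beyond the cells, so unpopulated regions carry
small spurious strains. The mask chain on the reference frame: Sobel
gradient magnitude → threshold (user-set; default Otsu's threshold on the
gradient image) → dilation by a disk (default radius 5 px, enough to bridge
the speckle-scale gaps between detected edges) → fill enclosed areas →
erosion by the same radius. The final erosion restores the boundary to the
detected edge position; without it the mask overhangs the cells by the
dilation radius. The mask is resampled to the subset grid by majority vote
over each subset footprint (≥ 50 % of pixels; `rule="any"` available).

The mask is built once from frame 0 and reused: frame-to-frame cell motion
(≲ 10 px) is small against the 48 px footprint, and per-frame masking would
couple mask noise into the trace. A per-frame mode exists behind
`per_frame_mask=True`.

### Beat detection and rate

The trace is |masked mean ε₂| per frame. The detection threshold is 60 % of
the **global** trace peak (one line for the whole video, not per beat —
per-beat thresholds would move midpoints on unequal beats). For each maximal
run of frames strictly above the line, the two crossings are interpolated
linearly between bracketing frames and their frame-axis midpoint is the
beat time. Runs shorter than 2 frames (noise spikes) and runs cut by the
video boundary (biased midpoints) are discarded. Rate = 60 / (mean
successive midpoint spacing / frame rate). With fewer than 2 complete beats
the rate is explicitly undefined (None + reason), never silently zero.

The frame rate is per-video metadata; 11.02 fps is only the default.
(Acquisition hardware in this class of experiment reports nominal rates of
11.02–11.05 fps; the difference is a 0.3 % scale factor on BPM, far below
between-video variability, but the parameter is explicit so either can be
used.)

### Statistics

Two groups: unpaired two-sample t-test, pooled variance by default (the
classical test), Welch's correction behind `welch=True`. Three or more:
one-way ANOVA, then Tukey HSD adjusted pairwise p-values from the
studentized-range distribution. Rate-vs-strain confounding is screened with
Pearson correlation. The unit of analysis is the video (one |ε₂_max| and
one rate each); there is no mixed-effects nesting by biological replicate —
an acknowledged simplification that overstates effective n when videos from
one differentiation batch are correlated.

## Synthetic validation data

The generator builds what the pipeline expects to see and nothing more:

* **Geometry**: vertical lanes (30 µm wide, 60 µm pitch) unioned with
  bridge stripes at 15° from vertical (perpendicular pitch 180 µm), at
  0.65 µm/px. An exact vector-geometry area fraction (shapely polygon
  union clipped to the field) serves as the oracle for the rasterized mask.
* **Texture**: seeded random impulses at 10 % density, Gaussian-blurred to
  ~2 px grains — high contrast, short autocorrelation, every 48 px window
  trackable.
* **Motion**: rigid translation (zero strain), uniaxial contraction toward
  a horizontal centerline (`U_y = −a(t)(y−y₀)`, so ε_yy = −a(t) uniformly),
  and biaxial contraction adding a transverse component at ratio 0.5. All
  are affine, so backward warping uses the exact inverse map with bicubic
  interpolation; frame 0 is bit-identical to the template. Ground-truth
  displacement and strain closures are attached to every video.
* **Twitch**: raised-cosine pulses peaking at the prescribed strain, beat
  centers at (k+½)·period so no pulse is truncated. Default pulse width is
  0.7 of the beat period: spontaneous stem-cell-derived cardiomyocyte
  twitches are long relative to the cycle, and this width keeps the
  supra-60 % region ≥ 2 frames at 11 fps for all rates below ~100 BPM, the
  regime these cultures beat in. Camera noise (Gaussian, `noise_sd`) is
  added after warping.

What this does **not** emulate: phase-contrast optics, cell-shape change and
sarcomere-level texture evolution during contraction, out-of-plane motion,
mask/texture decorrelation over long videos, and irregular (arrhythmic)
beat trains. Passing recovery tests therefore demonstrates the correctness
of the measurement chain on its idealized observable, not robustness to
every imaging pathology of real recordings.

## Problem sizes

Validation runs use the standard subset geometry (48/12) on 480 px fields
for strain recovery (14 frames bracketing one systole) and 288 px fields
for multi-beat rate recovery (2.7 s, two complete beats), with the
four-rate sweep (20/42/60/90 BPM, ≥ 3 beats each) run on generator traces
through the same beat-detection code path. These sizes give the recovery
checks sub-percent accuracy headroom while keeping a full validation pass
in the minutes range on one CPU.

## Numerical notes and edge cases

* Integer DIC on identical images returns exactly 0; sub-pixel refinement
  is skipped when the aligned subsets are bit-identical.
* Sub-pixel residuals are trusted only within ±1.5 px of the integer peak;
  larger values indicate a secondary-peak lock and are discarded.
* `seeding_density` truncates toward zero (120 000 / 35.6 → 3 370), the
  convention used when such densities are reported.
* A Sobel threshold above the maximum gradient yields an empty mask with a
  warning; an empty mask at trace computation raises (`EmptyMaskError`)
  rather than producing NaN metrics.
* Degenerate t-test input: identical constant groups return t = 0, p = 1;
  constant groups with different means raise.
* Metadata precedence: explicit arguments > sidecar JSON > defaults.

## Known limitations

* Translation-only subsets (no affine shape functions): systematic
  underestimation grows once within-subset displacement gradients approach
  a pixel; adequate at ≤ 5–10 % strain with 48 px subsets.
* Single-level search (no pyramid): peak displacement must stay within the
  search radius (default 12 px); the generator warns when a prescribed
  motion exceeds half the subset.
* The 60 %-crossing rate estimator assumes unimodal, reasonably regular
  twitches; strongly arrhythmic trains (e.g. DAD-like events) need a
  different detector and are out of scope.
* Group statistics treat videos as independent; hierarchical designs need
  external mixed-model tooling.
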