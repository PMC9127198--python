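# cardiostrain

Quantitative mechanical-function analysis of spontaneously contracting
cardiomyocyte monolayers from brightfield video.

Human iPSC-derived cardiomyocytes cultured on micropatterned soft substrates
(chevron geometry: 30 µm lanes joined by 15° bridges) form aligned,
electrically coupled syncytia whose contractions can be measured optically —
no fluorescent reporters, no force transducers. `cardiostrain` turns such
videos into two per-video metrics and their group statistics:

* **maximum contractile strain** |ε₂‚max| — the peak over frames of the
  magnitude of the cell-masked spatial mean of the second principal strain
  ε₂ (the most compressive eigenvalue of the 2-D strain tensor);
* **spontaneous contraction rate** (beats/min) — from midpoints of the
  crossings of the contractile-strain trace with a line at 60 % of its peak.

It is aimed at disease-modelling labs comparing patient vs. control lines
(e.g. inherited arrhythmia syndromes such as CPVT) across substrate
stiffnesses, where contractile strain serves as the functional readout.

## Method

1. **Digital image correlation (DIC).** Each frame is correlated against
   frame 0 (the relaxed state) on a grid of 48 × 48 px subsets spaced 12 px
   apart (31.2 × 31.2 µm at 0.65 µm/px). Integer displacements maximize
   zero-normalized cross-correlation over an exhaustive search window;
   sub-pixel refinement uses upsampled (matrix-DFT) cross-correlation on
   Hann-windowed subsets. Untrackable subsets are flagged, never zeroed.
2. **Strain.** Displacement gradients by separable 5-tap
   derivative/smoother convolution on the subset grid, divided by the grid
   spacing; infinitesimal strain tensor
   ε_xx = ∂U_x/∂x, ε_yy = ∂U_y/∂y, ε_xy = ½(∂U_x/∂y + ∂U_y/∂x); principal
   strains ε₁,₂ = (ε_xx+ε_yy)/2 ± √(((ε_xx−ε_yy)/2)² + ε_xy²).
3. **Masking.** Cell-occupied regions from the reference frame: Sobel edges
   at a user-defined (default Otsu) threshold, dilated into enclosed areas,
   filled, eroded back; resampled to the subset grid by footprint majority.
4. **Trace & metrics.** Per-frame masked mean ε₂ → |ε₂‚max| and the
   60 %-crossing midpoint beat rate.
5. **Statistics.** Unpaired two-sample t-test (two groups), one-way ANOVA +
   Tukey HSD (three or more), Pearson correlation for rate-vs-strain
   confounding; α = 0.05.

Because raw lab videos are rarely shareable, the package ships a synthetic
video generator (chevron pattern × speckle texture, warped by analytically
known displacement fields with raised-cosine twitches) so the entire chain
is validated by parameter recovery against exact ground truth.

## Worked example

```python
import cardiostrain as cs

pattern = cs.PatternSpec(field_size=(288, 288))
chevron = cs.generate_chevron_mask(pattern)
speckle = cs.generate_speckle(chevron.shape, density=0.1, rng_seed=7)
waveform = cs.ContractionWaveformSpec(
    rate=42.0, peak_strain=0.05, duration=2.7, frame_rate=11.02, rng_seed=7
)
video, truth = cs.synthesize_video(chevron, speckle, waveform, "uniaxial_contraction")
result = cs.analyze_sequence(video)
m = result.metrics
print(f"max contractile strain |eps2_max| = {m.max_contractile_strain:.4f}")
print(f"spontaneous rate = {m.rate:.2f} BPM from {m.n_beats_used} beats")
```

prints

```
max contractile strain |eps2_max| = 0.0500
spontaneous rate = 42.00 BPM from 2 beats
```

i.e. the pipeline recovers the prescribed 5 % peak contractile strain to
three decimals and the prescribed 42 BPM to 0.01 % on a video it has never
seen the parameters of — DIC, strain kernels, masking and beat detection all
working in concert.

The same flow from the shell:

```bash
cardiostrain simulate --rate 42 --peak-strain 0.05 --duration 2.7 --seed 7 --out vid.tif
cardiostrain analyze vid.tif --out run   # writes trace.csv, metrics.json, fields
cardiostrain report run --out report.png
cardiostrain compare metrics.csv --metric max_contractile_strain --by cell_line
```

## Layout

| module | contents |
| --- | --- |
| `cardiostrain.synthetic` | pattern/speckle/waveform generators, video synthesis, ground truth |
| `cardiostrain.io` | TIFF / frame-directory reading, metadata, output writers |
| `cardiostrain.dic` | subset grid, per-frame and per-sequence correlation |
| `cardiostrain.strain` | gradient kernels, strain tensor, principal strains |
| `cardiostrain.mask` | cell-region detection, grid resampling, application |
| `cardiostrain.beatrate` | contraction trace, |ε₂‚max|, beat detection, BPM |
| `cardiostrain.stats` | t-test, ANOVA + Tukey HSD, correlation, metrics table |
| `cardiostrain.pipeline` / `cli` | end-to-end orchestration and the `cardiostrain` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
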