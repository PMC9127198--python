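"""Generator correctness: pattern geometry, speckle, waveform, warping."""

import numpy as np
import pytest

import cardiostrain as cs
from cardiostrain.synthetic import analytic_foreground_fraction


def run_lengths(row):
    """Lengths of foreground runs in a boolean row."""
    padded = np.concatenate([[0], row.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


class TestChevronMask:
    def test_lane_width_in_pixels(self, chevron_mask):
        """30 um lanes at 0.65 um/px appear ~46 px wide (mode of row runs)."""
        lengths = np.concatenate([run_lengths(r) for r in chevron_mask])
        vals, counts = np.unique(lengths, return_counts=True)
        mode = vals[np.argmax(counts)]
        assert abs(mode - 30 / 0.65) <= 1.5

    def test_zero_bridge_angle_gives_plain_lanes(self):
        spec = cs.PatternSpec(bridge_angle=0.0)
        m = cs.generate_chevron_mask(spec)
        # every row identical: no bridges break the vertical translation symmetry
        assert (m == m[0]).all()
        frac = m.mean()
        assert frac == pytest.approx(spec.lane_width / spec.lane_pitch, rel=0.05)

    def test_foreground_fraction_matches_analytic(self, chevron_spec, chevron_mask):
        frac = chevron_mask.mean()
        expected = analytic_foreground_fraction(chevron_spec)
        assert 0 < frac < 1
        assert frac == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(lane_width=-1),
            dict(bridge_angle=95),
            dict(lane_pitch=20.0),  # <= lane_width
            dict(field_size=(100, 100)),  # < 3 pitches
        ],
    )
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            cs.generate_chevron_mask(cs.PatternSpec(**bad))


class TestSpeckle:
    def test_deterministic_for_fixed_seed(self):
        a = cs.generate_speckle((128, 128), 0.1, rng_seed=5)
        b = cs.generate_speckle((128, 128), 0.1, rng_seed=5)
        assert np.array_equal(a, b)
        c = cs.generate_speckle((128, 128), 0.1, rng_seed=6)
        assert not np.array_equal(a, c)

    def test_zero_density_is_uniform(self):
        img = cs.generate_speckle((64, 64), 0.0)
        assert img.std() == 0.0

    def test_every_subset_window_has_texture(self):
        img = cs.generate_speckle((480, 480), 0.1, rng_seed=1)
        floor = 0.02
        for y in range(0, 480 - 48 + 1, 48):
            for x in range(0, 480 - 48 + 1, 48):
                assert img[y : y + 48, x : x + 48].std() > floor

    def test_bad_density_rejected(self):
        with pytest.raises(ValueError):
            cs.generate_speckle((32, 32), 1.5)


class TestWaveform:
    def test_peak_spacing_is_beat_period(self):
        wf = cs.ContractionWaveformSpec(rate=42.0, duration=10.0)
        centers = wf.beat_centers()
        assert len(centers) >= 2
        assert np.allclose(np.diff(centers), 60.0 / 42.0)

    def test_systolic_peak_count_example(self):
        """42 BPM over 10 s at 11.02 fps gives floor(10*42/60) = 7 peaks."""
        wf = cs.ContractionWaveformSpec(rate=42.0, duration=10.0, frame_rate=11.02)
        assert len(wf.beat_centers()) == 7

    def test_amplitude_peaks_at_peak_strain(self):
        wf = cs.ContractionWaveformSpec(rate=60.0, peak_strain=0.07, duration=4.0)
        t = np.linspace(0, 4.0, 20001)
        a = wf.amplitude(t)
        assert a.max() == pytest.approx(0.07, abs=1e-6)
        assert a.min() == 0.0

    def test_invalid_waveform_rejected(self):
        with pytest.raises(ValueError):
            cs.ContractionWaveformSpec(peak_strain=0.7).validate()
        with pytest.raises(ValueError):
            cs.ContractionWaveformSpec(rate=-5).validate()


class TestSynthesizeVideo:
    def test_frame0_identical_to_template(self, uniaxial_video):
        seq, truth = uniaxial_video
        # frame 0 is the relaxed state: re-synthesize the template
        chevron = truth.pattern_mask
        speckle = cs.generate_speckle(chevron.shape, 0.1, rng_seed=3)
        template = np.where(chevron, 0.15 + 0.85 * speckle, 0.15 * 0.6)
        assert np.array_equal(seq.frames[0], template)

    def test_rigid_translation_has_zero_strain(self):
        wf = cs.ContractionWaveformSpec(rate=42, duration=1.0, frame_rate=11.02)
        speckle = cs.generate_speckle((200, 200), 0.1, rng_seed=1)
        seq, truth = cs.synthesize_video(
            None, speckle, wf, "rigid_translation", {"shift": (3.0, -2.0)}
        )
        x = np.linspace(10, 190, 7)
        exx, eyy, exy = truth.strain_fn(x, x, 0.5)
        assert np.all(exx == 0) and np.all(eyy == 0) and np.all(exy == 0)

    @pytest.mark.parametrize(
        "model", ["rigid_translation", "uniaxial_contraction", "biaxial_contraction"]
    )
    def test_strain_fn_is_gradient_of_displacement_fn(self, model):
        """Finite differences of U reproduce the analytic strain to 1e-6."""
        wf = cs.ContractionWaveformSpec(rate=42, peak_strain=0.05, duration=1.0)
        speckle = cs.generate_speckle((200, 200), 0.1, rng_seed=1)
        _, truth = cs.synthesize_video(None, speckle, wf, model)
        rng = np.random.default_rng(0)
        x = rng.uniform(20, 180, 50)
        y = rng.uniform(20, 180, 50)
        t = 0.7  # mid-twitch
        h = 1e-3
        ux_px, _ = truth.displacement_fn(x + h, y, t)
        ux_mx, _ = truth.displacement_fn(x - h, y, t)
        ux_py, uy_py = truth.displacement_fn(x, y + h, t)
        ux_my, uy_my = truth.displacement_fn(x, y - h, t)
        _, uy_px = truth.displacement_fn(x + h, y, t)
        _, uy_mx = truth.displacement_fn(x - h, y, t)
        dux_dx = (ux_px - ux_mx) / (2 * h)
        duy_dy = (uy_py - uy_my) / (2 * h)
        dux_dy = (ux_py - ux_my) / (2 * h)
        duy_dx = (uy_px - uy_mx) / (2 * h)
        exx, eyy, exy = truth.strain_fn(x, y, t)
        assert np.allclose(dux_dx, exx, atol=1e-6)
        assert np.allclose(duy_dy, eyy, atol=1e-6)
        assert np.allclose(0.5 * (dux_dy + duy_dx), exy, atol=1e-6)

    def test_uniaxial_peak_strain_value(self):
        wf = cs.ContractionWaveformSpec(rate=42, peak_strain=0.05, duration=2.0)
        speckle = cs.generate_speckle((200, 200), 0.1, rng_seed=1)
        _, truth = cs.synthesize_video(None, speckle, wf, "uniaxial_contraction")
        tc = wf.beat_centers()[0]
        _, eyy, _ = truth.strain_fn(np.array([100.0]), np.array([50.0]), tc)
        assert eyy[0] == pytest.approx(-0.05, abs=1e-12)
        assert truth.true_peak_mean_contractile_strain == 0.05

    def test_large_displacement_warns(self):
        wf = cs.ContractionWaveformSpec(rate=42, peak_strain=0.3, duration=2.0)
        speckle = cs.generate_speckle((400, 400), 0.1, rng_seed=1)
        with pytest.warns(UserWarning, match="search range"):
            cs.synthesize_video(None, speckle, wf, "uniaxial_contraction")

    def test_unknown_motion_model_rejected(self):
        wf = cs.ContractionWaveformSpec(duration=1.0)
        speckle = cs.generate_speckle((200, 200), 0.1, rng_seed=1)
        with pytest.raises(ValueError, match="motion_model"):
            cs.synthesize_video(None, speckle, wf, "swirl")


class TestSynthesizeTrace:
    def test_trace_matches_amplitude(self):
        wf = cs.ContractionWaveformSpec(rate=60, peak_strain=0.04, duration=5.0)
        t, tr = cs.synthesize_trace(wf)
        assert np.allclose(tr, -wf.amplitude(t))
        # sampled minimum sits within half a frame of the continuous peak
        assert -0.04 <= tr.min() <= -0.036
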