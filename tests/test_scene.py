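"""Synthetic acquisition generator: geometry, noise, release dynamics."""

import numpy as np
import pytest

from sfdiscope.demod import demodulate
from sfdiscope.optics import rd_forward
from sfdiscope.scene import (
    FiberSpec,
    NoiseModel,
    ReleaseModel,
    make_phantom_scene,
    render_fluorescence_frame,
    render_frameset,
    render_reflectance_frame,
    scene_x1d_map,
    simulate_calibration_stacks,
    simulate_release_series,
)

NOISE_OFF = NoiseModel(0.0, 0.0, 0.0)


def scene(**kw):
    kw.setdefault("shape", (32, 32))
    kw.setdefault("noise", NOISE_OFF)
    return make_phantom_scene(1.0, 15.0, 0.8, 12.5, **kw)


class TestSceneConstruction:
    def test_homogeneous_maps_constant(self):
        s = scene(dox_conc=10.0)
        for m in (s.mu_a_ex, s.mu_s_ex, s.dox, s.height_mm):
            assert np.ptp(m) == 0.0
        assert s.dox[0, 0] == 10.0

    def test_phantom_grid_has_distinct_dc_reflectance(self):
        combos = [(1.0, 15.0), (1.0, 25.0), (2.5, 15.0), (2.5, 25.0)]
        rds = [rd_forward(a, s, 0.0) for a, s in combos]
        assert len(set(np.round(rds, 6))) == 4

    def test_tumor_inclusion(self):
        s = scene(tumor={"center": (16, 16), "radius": 6, "mu_a_ex": 2.5, "dox": 5.0})
        assert s.tumor_mask.any() and not s.tumor_mask.all()
        assert s.mu_a_ex[16, 16] == 2.5 and s.mu_a_ex[0, 0] == 1.0
        assert s.dox[16, 16] == 5.0

    def test_invalid_scenes_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_scene(1.0, -1.0, 0.8, 12.5)
        with pytest.raises(ValueError):
            make_phantom_scene(1.0, 15.0, 0.8, 12.5, dox_conc=-2.0)
        with pytest.raises(ValueError):
            scene(height_mm=9.5)


class TestReflectanceRender:
    def test_dc_frames_identical_across_phases(self):
        s = scene()
        frames = [render_reflectance_frame(s, 490.0, 0.0, p) for p in range(3)]
        np.testing.assert_array_equal(frames[0], frames[1])
        np.testing.assert_array_equal(frames[1], frames[2])

    def test_demodulation_returns_rd_exactly(self):
        # Noise/artifact-free flat render at h=0: M_AC/(gain/2) == R_d(f).
        s = scene()
        f = 2.0
        i1, i2, i3 = (
            render_reflectance_frame(s, 490.0, f, p) - s.dark_level for p in range(3)
        )
        m_ac, m_dc = demodulate(i1, i2, i3)
        expected = rd_forward(1.0, 15.0, f)
        np.testing.assert_allclose(m_ac / (s.gain / 2), expected, rtol=1e-6)
        np.testing.assert_allclose(m_dc / (s.gain / 2), rd_forward(1.0, 15.0, 0.0), rtol=1e-6)

    def test_height_shrinks_pattern_period(self):
        # At h the local frequency is f (1 + h/d0): count phase cycles.
        f = 2.0
        s0 = scene(shape=(8, 256))
        s8 = scene(shape=(8, 256), height_mm=8.0)
        row0 = render_reflectance_frame(s0, 490.0, f, 0)[4]
        row8 = render_reflectance_frame(s8, 490.0, f, 0)[4]
        # cycles ~ zero crossings of the mean-removed signal / 2
        cyc0 = (np.diff(np.sign(row0 - row0.mean())) != 0).sum() / 2
        cyc8 = (np.diff(np.sign(row8 - row8.mean())) != 0).sum() / 2
        assert cyc8 / cyc0 == pytest.approx(1.0 + 8.0 / s8.d0_mm, rel=0.06)

    def test_unknown_frequency_rejected(self):
        with pytest.raises(ValueError):
            render_reflectance_frame(scene(), 490.0, 1.11, 0)

    def test_noise_requires_rng_and_is_reproducible(self):
        s = scene(noise=NoiseModel(1.25, 2.0, 0.0))
        with pytest.raises(ValueError):
            render_reflectance_frame(s, 490.0, 0.0, 0)
        a = render_reflectance_frame(s, 490.0, 0.0, 0, np.random.default_rng(5))
        b = render_reflectance_frame(s, 490.0, 0.0, 0, np.random.default_rng(5))
        c = render_reflectance_frame(s, 490.0, 0.0, 0, np.random.default_rng(6))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestFluorescenceRender:
    def test_no_drug_gives_dark_level_only(self):
        s = scene(dox_conc=0.0)
        img = render_fluorescence_frame(s, 1.0)
        np.testing.assert_allclose(img, s.dark_level)

    def test_fully_quenched_unreleased_gives_dark_level(self):
        s = scene(dox_conc=10.0)
        model = ReleaseModel(loaded_fraction_quenched=1.0)
        img = render_fluorescence_frame(s, 0.0, model)
        np.testing.assert_allclose(img, s.dark_level)

    def test_signal_ratio_tracks_x1d_between_media(self):
        lo = make_phantom_scene(0.5, 20.0, 0.4, 17.0, dox_conc=10.0, shape=(8, 8), noise=NOISE_OFF)
        hi = make_phantom_scene(1.0, 20.0, 0.8, 17.0, dox_conc=10.0, shape=(8, 8), noise=NOISE_OFF)
        a = render_fluorescence_frame(lo, 1.0) - lo.dark_level
        b = render_fluorescence_frame(hi, 1.0) - hi.dark_level
        ratio = a[4, 4] / b[4, 4]
        expected = scene_x1d_map(lo)[4, 4] / scene_x1d_map(hi)[4, 4]
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert a[4, 4] > b[4, 4]  # more absorption -> dimmer raw signal

    def test_release_fraction_bounds_checked(self):
        with pytest.raises(ValueError):
            render_fluorescence_frame(scene(dox_conc=1.0), 1.5)


class TestReleaseSeries:
    def test_closed_form_time_to_95(self):
        # k = 0.01 /s -> t95 = ln(20)/k ~ 299.6 s in the ground truth.
        s = scene(dox_conc=10.0)
        model = ReleaseModel(k0=1.0, fluence_rate=10.0, attenuation_coupling=0.0)
        k = model.rate_map(s.mu_a_treat)[0, 0]
        assert k == pytest.approx(0.01)
        series = simulate_release_series(s, model, 400.0, 10.0, seed=0)
        rel = np.array([r[0, 0] for r in series.released])
        t95_truth = np.log(20.0) / k
        crossed = series.times_s[rel >= 0.95][0]
        assert abs(crossed - t95_truth) <= 10.0

    def test_higher_absorption_releases_slower(self):
        model = ReleaseModel()
        lo = scene()
        hi = make_phantom_scene(1.0, 15.0, 1.6, 12.5, shape=(32, 32), noise=NOISE_OFF)
        k_lo = model.rate_map(lo.mu_a_treat)[0, 0]
        k_hi = model.rate_map(hi.mu_a_treat)[0, 0]
        assert k_hi < k_lo  # strictly longer t95 for the absorber

    def test_first_frame_equals_unreleased_render(self):
        s = scene(dox_conc=10.0)
        model = ReleaseModel()
        series = simulate_release_series(s, model, 100.0, 10.0, seed=0)
        np.testing.assert_allclose(
            series.frames[0], render_fluorescence_frame(s, 0.0, model)
        )

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_release_series(scene(), ReleaseModel(), 10.0, 20.0)


class TestCalibrationStacks:
    def test_single_height_matches_plain_render(self, ref_ops):
        stacks = simulate_calibration_stacks(ref_ops, [0.0], shape=(16, 16))
        fs = stacks[0.0]
        s = scene(shape=(16, 16))
        expected = render_reflectance_frame(s, 490.0, 2.0, 1)
        np.testing.assert_allclose(fs.frames[(490.0, 2.0, 1)], expected)

    def test_amplitude_and_phase_monotone_in_height(self, ref_ops):
        stacks = simulate_calibration_stacks(ref_ops, [0.0, 2.0, 4.0, 6.0, 8.0], shape=(16, 16))
        amps, phases = [], []
        from sfdiscope.demod import extract_phase, unwrap_phase

        for h in (0.0, 2.0, 4.0, 6.0, 8.0):
            i1, i2, i3 = stacks[h].phase_triplet(490.0, 2.0)
            ac, _ = demodulate(i1, i2, i3)
            amps.append(ac[8, 8])
            phases.append(unwrap_phase(extract_phase(i1, i2, i3)).phase[8, 8])
        assert np.all(np.diff(amps) < 0)  # divergence dims the pattern
        assert np.all(np.diff(phases) > 0)  # phase advances with height

    def test_empty_heights_rejected(self, ref_ops):
        with pytest.raises(ValueError):
            simulate_calibration_stacks(ref_ops, [])


class TestArtifactsAndNoise:
    def test_honeycomb_has_strong_spectral_peak(self):
        pitch = 8.0
        s = scene(shape=(64, 64), fiber=FiberSpec(pitch_px=pitch, artifact_depth=0.3))
        img = render_reflectance_frame(s, 490.0, 0.0, 0)
        F = np.abs(np.fft.fft2(img - img.mean()))
        fy = np.fft.fftfreq(64)[:, None]
        fx = np.fft.fftfreq(64)[None, :]
        r = np.hypot(fy, fx)
        ring = (r > 0.8 / pitch) & (r < 1.2 / pitch)
        background = (r > 0.3) & (r < 0.45)
        assert F[ring].max() >= 10.0 * F[background].mean()

    def test_seeded_renders_bit_identical(self):
        s = scene(noise=NoiseModel(1.25, 2.0, 0.01))
        a = render_frameset(s, np.random.default_rng(42))
        b = render_frameset(s, np.random.default_rng(42))
        for k in a.frames:
            np.testing.assert_array_equal(a.frames[k], b.frames[k])
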