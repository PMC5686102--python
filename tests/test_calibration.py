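"""Reference calibration, profilometry height correction, reflectance."""

import numpy as np
import pytest

from sfdiscope.calibration import (
    calibrate_reference,
    calibrated_reflectance,
    fit_height_calibration,
    height_map,
)
from sfdiscope.demod import demodulate_frameset, extract_phase
from sfdiscope.optics import rd_forward
from sfdiscope.preprocess import subtract_dark
from sfdiscope.scene import (
    NoiseModel,
    make_phantom_scene,
    render_frameset,
    simulate_calibration_stacks,
)

NOISE_OFF = NoiseModel(0.0, 0.0, 0.0)
SHAPE = (24, 24)


@pytest.fixture(scope="module")
def stacks(ref_ops):
    return simulate_calibration_stacks(
        ref_ops, [0.0, 2.0, 4.0, 6.0, 8.0], shape=SHAPE, seed=0
    )


@pytest.fixture(scope="module")
def hcal(stacks, ref_ops):
    return fit_height_calibration(stacks, ref_ops)


@pytest.fixture(scope="module")
def reference(stacks, ref_ops):
    return calibrate_reference(stacks[0.0], ref_ops)


def sample_phase(fs, wl=490.0, f=2.0):
    i1, i2, i3 = (subtract_dark(i, fs.dark) for i in fs.phase_triplet(wl, f))
    return extract_phase(i1, i2, i3, frequency=f)


class TestHeightCalibrationFit:
    def test_two_heights_insufficient(self, stacks, ref_ops):
        with pytest.raises(ValueError):
            fit_height_calibration({h: stacks[h] for h in (0.0, 4.0)}, ref_ops)

    def test_phase_slope_recovered_within_one_percent(self, hcal, stacks):
        # Generator fringe phase is exactly linear in h with slope
        # dphi/dh = 2 pi f x/d0 + kappa f at each pixel.
        fs0 = stacks[0.0]
        scene = make_phantom_scene(1.0, 15.0, 0.8, 12.5, shape=SHAPE, noise=NOISE_OFF)
        x = (np.arange(SHAPE[1]) + 0.5) * scene.acquisition.fov_cm / SHAPE[1]
        truth = 2 * np.pi * 2.0 * x / scene.d0_mm + scene.kappa * 2.0
        slope, _ = hcal.phase_fit[490.0]
        recovered = 1.0 / slope  # fit stores dh/dphi
        np.testing.assert_allclose(recovered[12], truth, rtol=0.01)

    def test_calibration_reproduces_training_amplitudes(self, hcal):
        # Interpolation passes through the nodes exactly.
        for h_idx, h in enumerate(hcal.heights_mm):
            ref = hcal.ref_amp[(490.0, 2.0)][h_idx]
            got = hcal.reference_amplitude_at(490.0, 2.0, np.full(SHAPE, h))
            np.testing.assert_allclose(got, ref, rtol=1e-12)

    def test_degenerate_phase_rejected(self, ref_ops):
        # Flat stacks all at the same effective geometry -> constant phase.
        base = simulate_calibration_stacks(ref_ops, [0.0], shape=(12, 12))[0.0]
        fake = {0.0: base, 2.0: base, 4.0: base}
        with pytest.raises(ValueError):
            fit_height_calibration(fake, ref_ops)


class TestHeightMap:
    def test_reference_plane_maps_to_zero(self, hcal, stacks):
        hm = height_map(sample_phase(stacks[0.0]), hcal, 490.0)
        assert np.abs(hm.heights_mm).max() < 0.05

    def test_midpoint_between_nodes_interpolates(self, hcal, ref_ops):
        fs = simulate_calibration_stacks(ref_ops, [3.0], shape=SHAPE)[3.0]
        hm = height_map(sample_phase(fs), hcal, 490.0)
        assert np.abs(hm.heights_mm - 3.0).max() < 0.1

    def test_flat_scene_at_6mm_recovered(self, hcal, ref_ops):
        fs = simulate_calibration_stacks(
            ref_ops, [6.0], shape=SHAPE, noise=NoiseModel(0, 0, 0.01), seed=4
        )[6.0]
        hm = height_map(sample_phase(fs), hcal, 490.0)
        assert float(hm.heights_mm.mean()) == pytest.approx(6.0, abs=0.3)

    def test_out_of_calibration_wavelength_rejected(self, hcal, stacks):
        with pytest.raises(ValueError):
            height_map(sample_phase(stacks[0.0]), hcal, 650.0)


class TestCalibratedReflectance:
    def test_self_calibration_returns_model_prediction(self, reference, stacks, ref_ops):
        maps = demodulate_frameset(stacks[0.0], 490.0)
        rd = calibrated_reflectance(maps, reference)
        op = ref_ops[490.0]
        for f in rd.frequencies():
            np.testing.assert_allclose(
                rd.r_d[f], rd_forward(op.mu_a, op.mu_s_prime, f), rtol=1e-9
            )

    def test_linearity_in_sample_amplitude(self, reference, stacks):
        maps = demodulate_frameset(stacks[0.0], 490.0)
        rd1 = calibrated_reflectance(maps, reference)
        maps.m_dc = 0.5 * maps.m_dc
        maps.m_ac = {f: 0.5 * a for f, a in maps.m_ac.items()}
        rd2 = calibrated_reflectance(maps, reference)
        for f in rd1.frequencies():
            np.testing.assert_allclose(rd2.r_d[f], 0.5 * rd1.r_d[f], rtol=1e-9)

    def test_round_trip_reflectance_identity(self, reference):
        # Noise-free render of a different medium, calibrated at h=0,
        # returns its true R_d(f) to high accuracy.
        scene = make_phantom_scene(2.0, 22.0, 1.5, 18.0, shape=SHAPE, noise=NOISE_OFF)
        fs = render_frameset(scene)
        rd = calibrated_reflectance(demodulate_frameset(fs, 490.0), reference)
        for f in rd.frequencies():
            np.testing.assert_allclose(rd.r_d[f], rd_forward(2.0, 22.0, f), rtol=1e-3)

    def test_height_correction_restores_displaced_sample(self, reference, hcal):
        # Flat phantom at 8 mm: corrected R_d within 5% of the h=0
        # answer, uncorrected off by far more than 20%.
        kw = dict(shape=SHAPE, noise=NOISE_OFF)
        s0 = make_phantom_scene(1.0, 15.0, 0.8, 12.5, **kw)
        s8 = make_phantom_scene(1.0, 15.0, 0.8, 12.5, height_mm=8.0, **kw)
        rd0 = calibrated_reflectance(demodulate_frameset(render_frameset(s0), 490.0), reference)
        fs8 = render_frameset(s8)
        maps8 = demodulate_frameset(fs8, 490.0)
        hm = height_map(sample_phase(fs8), hcal, 490.0)
        corrected = calibrated_reflectance(maps8, reference, heights=hm, hcal=hcal)
        uncorrected = calibrated_reflectance(maps8, reference)
        inner = (slice(4, -4), slice(4, -4))
        for f in rd0.frequencies():
            rel_corr = np.abs(corrected.r_d[f] - rd0.r_d[f])[inner] / rd0.r_d[f][inner]
            rel_unc = np.abs(uncorrected.r_d[f] - rd0.r_d[f])[inner] / rd0.r_d[f][inner]
            assert rel_corr.max() < 0.05
            assert rel_unc.mean() > 0.20

    def test_height_correction_transfer_to_different_medium(self, reference, hcal):
        # A medium unlike the calibration phantom, displaced 8 mm: the
        # correction removes the dominant divergence bias; a chromatic
        # second-order residual remains because the stretched pattern
        # frequency probes the sample and reference differently.
        kw = dict(shape=SHAPE, noise=NOISE_OFF)
        s0 = make_phantom_scene(2.0, 22.0, 1.5, 18.0, **kw)
        s8 = make_phantom_scene(2.0, 22.0, 1.5, 18.0, height_mm=8.0, **kw)
        rd0 = calibrated_reflectance(demodulate_frameset(render_frameset(s0), 490.0), reference)
        fs8 = render_frameset(s8)
        maps8 = demodulate_frameset(fs8, 490.0)
        hm = height_map(sample_phase(fs8), hcal, 490.0)
        corrected = calibrated_reflectance(maps8, reference, heights=hm, hcal=hcal)
        uncorrected = calibrated_reflectance(maps8, reference)
        f = 2.0
        inner = (slice(4, -4), slice(4, -4))
        rel_corr = np.abs(corrected.r_d[f] - rd0.r_d[f])[inner] / rd0.r_d[f][inner]
        rel_unc = np.abs(uncorrected.r_d[f] - rd0.r_d[f])[inner] / rd0.r_d[f][inner]
        # DC channel has no frequency shift and is corrected exactly.
        np.testing.assert_allclose(corrected.r_d[0.0][inner], rd0.r_d[0.0][inner], rtol=1e-6)
        assert rel_corr.mean() < 0.5 * rel_unc.mean()

    def test_error_independent_of_height_after_correction(self, reference, hcal, ref_ops):
        # Regression slope of mean |R_d error| against height ~ 0.
        heights = [0.0, 2.0, 4.0, 6.0, 8.0]
        errs = []
        for h in heights:
            s = make_phantom_scene(1.0, 15.0, 0.8, 12.5, height_mm=h, shape=SHAPE, noise=NOISE_OFF)
            fs = render_frameset(s)
            maps = demodulate_frameset(fs, 490.0)
            hm = height_map(sample_phase(fs), hcal, 490.0)
            rd = calibrated_reflectance(maps, reference, heights=hm, hcal=hcal)
            truth = rd_forward(1.0, 15.0, 2.0)
            errs.append(float(np.abs(rd.r_d[2.0] - truth).mean() / truth))
        slope = np.polyfit(heights, errs, 1)[0]
        assert abs(slope) < 0.005  # per mm

    def test_missing_calibration_rejected(self, stacks):
        maps = demodulate_frameset(stacks[0.0], 490.0)
        with pytest.raises(ValueError):
            calibrated_reflectance(maps, None)
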