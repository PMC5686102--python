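"""Per-pixel inversion: fit accuracy, LUT equivalence, correction maps."""

import numpy as np
import pytest

from sfdiscope.inversion import (
    build_correction_map,
    build_lut,
    fit_optical_properties,
)
from sfdiscope.optics import rd_forward, x1d_factor

FREQS = np.array([0.0, 2.0 / 3.0, 4.0 / 3.0, 2.0])


def rd_maps(mu_a, mu_s, shape=(6, 6), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for f in FREQS:
        img = np.full(shape, rd_forward(mu_a, mu_s, f))
        if noise:
            img = img * (1.0 + noise * rng.standard_normal(shape))
        out[float(f)] = img
    return out


class TestFitOpticalProperties:
    def test_noise_free_identity_recovery(self):
        fit = fit_optical_properties(rd_maps(1.0, 15.0), 490.0)
        np.testing.assert_allclose(fit.mu_a, 1.0, rtol=1e-3)
        np.testing.assert_allclose(fit.mu_s_prime, 15.0, rtol=1e-3)
        assert fit.valid.all()

    @pytest.mark.parametrize(
        "mu_a,mu_s", [(1.0, 15.0), (1.0, 25.0), (2.5, 15.0), (2.5, 25.0)]
    )
    def test_one_percent_noise_recovery_under_ten_percent(self, mu_a, mu_s):
        fit = fit_optical_properties(rd_maps(mu_a, mu_s, (8, 8), noise=0.01, seed=3), 490.0)
        assert np.nanmean(np.abs(fit.mu_a - mu_a)) / mu_a < 0.10
        assert np.nanmean(np.abs(fit.mu_s_prime - mu_s)) / mu_s < 0.10

    def test_both_starts_converge_to_same_solution_on_clean_data(self):
        fit = fit_optical_properties(rd_maps(1.7, 18.0), 490.0)
        assert np.all(fit.start_disagreement < 0.05)
        assert fit.valid.all()

    def test_matches_scipy_trust_region_fit(self):
        # Cross-check the batched optimizer against scipy's reference
        # solver on a single pixel.
        from scipy.optimize import least_squares

        obs = np.array([rd_forward(1.3, 19.0, f) for f in FREQS]) * (
            1.0 + 0.01 * np.random.default_rng(1).standard_normal(len(FREQS))
        )
        res = least_squares(
            lambda p: rd_forward(p[0], p[1], FREQS) - obs,
            x0=[0.5, 10.0],
            bounds=([0.01, 1.0], [10.0, 50.0]),
        )
        maps = {float(f): np.full((2, 2), o) for f, o in zip(FREQS, obs)}
        fit = fit_optical_properties(maps, 490.0)
        assert fit.mu_a[0, 0] == pytest.approx(res.x[0], rel=1e-3)
        assert fit.mu_s_prime[0, 0] == pytest.approx(res.x[1], rel=1e-3)

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            fit_optical_properties({0.0: np.ones((4, 4)) * 0.3}, 490.0)


@pytest.fixture(scope="module")
def lut():
    return build_lut(frequencies=FREQS)


class TestLookupTable:
    def test_grid_nodes_recovered_exactly(self, lut):
        ia, is_ = 20, 30
        mu_a = lut.mu_a_grid[ia]
        mu_s = lut.mu_s_grid[is_]
        fit = lut.invert(rd_maps(mu_a, mu_s, (3, 3)))
        np.testing.assert_allclose(fit.mu_a, mu_a, rtol=1e-6)
        np.testing.assert_allclose(fit.mu_s_prime, mu_s, rtol=1e-6)

    def test_off_node_agrees_with_nonlinear_fit_within_two_percent(self, lut):
        maps = rd_maps(1.7, 18.0, (4, 4), noise=0.005, seed=9)
        lut_fit = lut.invert(maps)
        gn_fit = fit_optical_properties(maps, 490.0)
        np.testing.assert_allclose(lut_fit.mu_a, gn_fit.mu_a, rtol=0.02)
        np.testing.assert_allclose(lut_fit.mu_s_prime, gn_fit.mu_s_prime, rtol=0.02)

    def test_lut_equivalence_across_calibration_grid(self, lut):
        # Oracle equivalence over the phantom property range.
        for mu_a in (0.6, 1.2, 2.4):
            for mu_s in (12.5, 19.0, 25.0):
                maps = rd_maps(mu_a, mu_s, (2, 2))
                a = lut.invert(maps)
                b = fit_optical_properties(maps, 490.0)
                np.testing.assert_allclose(a.mu_a, b.mu_a, rtol=0.02)
                np.testing.assert_allclose(a.mu_s_prime, b.mu_s_prime, rtol=0.02)

    def test_out_of_grid_query_flagged(self, lut):
        maps = rd_maps(9.0, 45.0, (2, 2))  # far outside the table
        fit = lut.invert(maps)
        assert not fit.valid.any()

    def test_frequency_mismatch_rejected(self, lut):
        with pytest.raises(ValueError):
            lut.invert({0.0: np.ones((2, 2)), 1.0: np.ones((2, 2))})


class TestCorrectionMap:
    def make_ops(self, mu_a, mu_s, shape=(4, 4), wavelength=490.0):
        from sfdiscope.inversion import OpticalPropertyMaps

        return OpticalPropertyMaps(
            mu_a=np.full(shape, mu_a),
            mu_s_prime=np.full(shape, mu_s),
            wavelength=wavelength,
            residual_norm=np.zeros(shape),
            valid=np.ones(shape, bool),
            start_disagreement=np.zeros(shape),
        )

    def test_homogeneous_maps_give_constant_factor(self):
        cm = build_correction_map(self.make_ops(1.0, 15.0), self.make_ops(0.8, 12.5, wavelength=590.0))
        assert np.ptp(cm) == 0.0
        assert cm[0, 0] == pytest.approx(x1d_factor((1.0, 15.0), (0.8, 12.5)), rel=1e-6)

    def test_absorbing_inclusion_lowers_factor(self):
        ex = self.make_ops(1.0, 15.0, (8, 8))
        ex.mu_a[3:5, 3:5] = 2.5
        cm = build_correction_map(ex, self.make_ops(0.8, 12.5, (8, 8), 590.0))
        assert cm[4, 4] < cm[0, 0]

    def test_pointwise_consistency_with_scalar_factor(self):
        ex = self.make_ops(1.0, 15.0, (3, 3))
        em = self.make_ops(0.8, 12.5, (3, 3), 590.0)
        ex.mu_a[1, 1] = 1.9
        cm = build_correction_map(ex, em)
        assert cm[1, 1] == pytest.approx(x1d_factor((1.9, 15.0), (0.8, 12.5)), rel=1e-3)

    def test_invalid_pixels_propagate(self):
        ex = self.make_ops(1.0, 15.0)
        ex.valid[0, 0] = False
        cm = build_correction_map(ex, self.make_ops(0.8, 12.5, wavelength=590.0))
        assert np.isnan(cm[0, 0]) and np.isfinite(cm[1, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_correction_map(self.make_ops(1.0, 15.0, (4, 4)), self.make_ops(0.8, 12.5, (5, 5)))
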