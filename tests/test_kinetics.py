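"""Release curves, time-to-fraction, unmixing, target arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfdiscope.concentration import ConcentrationMap
from sfdiscope.kinetics import (
    ReleaseCurve,
    SpectrumSample,
    release_curve,
    time_to_fraction,
    unmix_spectrum,
    usaf_resolution,
)
from sfdiscope.preprocess import RoiMask


def conc_maps(values, shape=(6, 6)):
    return [
        ConcentrationMap(dox=np.full(shape, v), clipped=np.zeros(shape, bool))
        for v in values
    ]


def full_roi(shape=(6, 6)):
    return RoiMask(np.ones(shape, bool), 0.5)


class TestReleaseCurve:
    def test_constant_maps_give_flat_curve(self):
        curve = release_curve(conc_maps([4.0, 4.0, 4.0]), [0, 10, 20], full_roi())
        np.testing.assert_allclose(curve.mean, 4.0)
        np.testing.assert_allclose(curve.sd, 0.0)

    def test_simulated_exponential_recovered(self):
        times = np.arange(0, 400, 10.0)
        k, plateau = 0.01, 8.0
        truth = plateau * (1 - np.exp(-k * times))
        curve = release_curve(conc_maps(truth), times, full_roi())
        np.testing.assert_allclose(curve.mean, truth, rtol=1e-12)

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError):
            release_curve(conc_maps([1.0]), [0.0], full_roi())

    def test_empty_roi_rejected(self):
        roi = RoiMask(np.zeros((6, 6), bool), 0.5)
        with pytest.raises(ValueError):
            release_curve(conc_maps([1.0, 2.0]), [0, 10], roi)


class TestTimeToFraction:
    def test_step_curve(self):
        curve = ReleaseCurve([0, 10, 20, 30], [0, 0, 5.0, 5.0], [0] * 4)
        ft = time_to_fraction(curve, 0.95)
        assert ft.reached and 10.0 < ft.time_s <= 20.0

    def test_exponential_closed_form_within_sampling_interval(self):
        k = 0.01
        times = np.arange(0, 600, 10.0)
        curve = ReleaseCurve(times, 10 * (1 - np.exp(-k * times)), np.zeros_like(times))
        ft = time_to_fraction(curve, 0.95)
        # plateau estimate biases slightly low; within one 10 s interval
        assert abs(ft.time_s - np.log(20.0) / k) <= 10.0

    def test_fraction_one_on_increasing_curve_is_last_time(self):
        times = np.array([0.0, 10.0, 20.0])
        curve = ReleaseCurve(times, [0.0, 1.0, 2.0], [0, 0, 0])
        ft = time_to_fraction(curve, 1.0, plateau_points=1)
        assert ft.time_s == 20.0 and ft.reached

    def test_result_carries_plateau_and_flag(self):
        # The result is a flagged record, never a silent scalar: it
        # carries the plateau estimate (mean of the final 3 samples)
        # and whether the fraction was attained.
        times = np.arange(0, 60, 10.0)
        mean = np.array([0.0, 2.0, 6.0, 7.9, 8.0, 8.1])
        ft = time_to_fraction(ReleaseCurve(times, mean, np.zeros(6)), 0.95)
        assert ft.reached
        assert ft.plateau == pytest.approx(8.0)
        assert float(ft) == ft.time_s

    def test_t95_recovery_over_known_rate_range(self):
        # 20 first-order curves, k in [0.005, 0.02] /s sampled every 10 s:
        # |t95_est - ln(20)/k| <= 10 s for each.
        times = np.arange(0.0, 1400.0, 10.0)
        for k in np.linspace(0.005, 0.02, 20):
            mean = 8.0 * (1 - np.exp(-k * times))
            curve = ReleaseCurve(times, mean, np.zeros_like(times))
            ft = time_to_fraction(curve, 0.95)
            assert ft.reached
            assert abs(ft.time_s - np.log(20.0) / k) <= 10.0


class TestUnmixing:
    def grid(self):
        return np.arange(530.0, 701.0, 10.0)

    def bases(self):
        wl = self.grid()
        dox = np.exp(-0.5 * ((wl - 590) / 25.0) ** 2)
        auto = np.exp(-(wl - 530) / 60.0)
        return SpectrumSample(wl, dox), SpectrumSample(wl, auto)

    def test_pure_basis_recovered(self):
        dox, auto = self.bases()
        c_dox, c_auto, resid = unmix_spectrum(dox, dox, auto)
        assert c_dox == pytest.approx(1.0, rel=1e-9)
        assert c_auto == pytest.approx(0.0, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_noisy_mixture_within_five_percent(self):
        dox, auto = self.bases()
        rng = np.random.default_rng(8)
        mix = 0.3 * dox.counts + 0.7 * auto.counts
        mix = mix + 0.002 * rng.standard_normal(mix.size)
        c_dox, c_auto, _ = unmix_spectrum(SpectrumSample(self.grid(), mix), dox, auto)
        assert c_dox == pytest.approx(0.3, rel=0.05)
        assert c_auto == pytest.approx(0.7, rel=0.05)

    def test_zero_spectrum_gives_zero_coefficients(self):
        dox, auto = self.bases()
        c_dox, c_auto, _ = unmix_spectrum(
            SpectrumSample(self.grid(), np.zeros(18)), dox, auto
        )
        assert c_dox == 0.0 and c_auto == 0.0

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, scale):
        dox, auto = self.bases()
        mix = SpectrumSample(self.grid(), 0.4 * dox.counts + 0.6 * auto.counts)
        scaled = SpectrumSample(self.grid(), scale * mix.counts)
        a = unmix_spectrum(mix, dox, auto)
        b = unmix_spectrum(scaled, dox, auto)
        assert b[0] == pytest.approx(scale * a[0], rel=1e-6)
        assert b[1] == pytest.approx(scale * a[1], rel=1e-6)

    def test_grid_mismatch_rejected(self):
        dox, auto = self.bases()
        other = SpectrumSample(np.arange(540.0, 711.0, 10.0), dox.counts)
        with pytest.raises(ValueError):
            unmix_spectrum(other, dox, auto)

    def test_dependent_bases_rejected(self):
        dox, _ = self.bases()
        twin = SpectrumSample(self.grid(), 2.0 * dox.counts)
        with pytest.raises(ValueError):
            unmix_spectrum(dox, dox, twin)


class TestUsafResolution:
    @pytest.mark.parametrize(
        "group,element,lp_mm,width_um",
        [(2, 5, 6.35, 78.75), (3, 5, 12.7, 39.37), (0, 1, 1.0, 500.0)],
    )
    def test_printed_values(self, group, element, lp_mm, width_um):
        res, width = usaf_resolution(group, element)
        assert round(res, 2) == lp_mm
        assert round(width, 2) == width_um

    def test_element_range_enforced(self):
        with pytest.raises(ValueError):
            usaf_resolution(2, 0)
        with pytest.raises(ValueError):
            usaf_resolution(2, 7)
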