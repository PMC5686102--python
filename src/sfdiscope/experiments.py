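"""Desk-scale replication experiments on synthetic acquisitions.

Each routine builds its scenes, runs the full measurement chain
(render -> demodulate -> calibrate -> invert -> correct), and reports
summary statistics: the linearity of attenuation-corrected fluorescence
against drug concentration pooled over phantoms of very different
optical properties, the residual optical-property error after
profilometry height correction, and the four-phantom quantification
accuracy under 1% measurement noise.

Problem sizes default to 32x32-pixel scenes, which keeps every
experiment in the seconds-to-a-minute range while leaving hundreds of
independent noisy pixels per ROI.
"""

from __future__ import annotations

import numpy as np

from .calibration import (
    PROFILOMETRY_FREQUENCY,
    calibrate_reference,
    calibrated_reflectance,
    fit_height_calibration,
    height_map,
)
from .concentration import fit_concentration_calibration
from .demod import demodulate_frameset, extract_phase
from .inversion import build_correction_map, fit_optical_properties
from .optics import OpticalProperties
from .preprocess import subtract_dark
from .scene import (
    WAVELENGTH_EM,
    WAVELENGTH_EX,
    NoiseModel,
    make_phantom_scene,
    render_fluorescence_frame,
    render_frameset,
    scene_x1d_map,
    simulate_calibration_stacks,
)

__all__ = [
    "PHANTOM_GRID",
    "corrected_fluorescence_linearity",
    "height_correction_errors",
    "four_phantom_recovery",
]

#: The four calibration phantoms: (mu_a, mu_s') at 490 nm and at 590 nm.
#: Ink level sets absorption, scatterer level sets scattering; the two
#: wavelengths see correspondingly scaled coefficients.
PHANTOM_GRID = (
    {"ex": (1.0, 15.0), "em": (0.8, 12.5)},
    {"ex": (1.0, 25.0), "em": (0.8, 21.0)},
    {"ex": (2.5, 15.0), "em": (1.9, 12.5)},
    {"ex": (2.5, 25.0), "em": (1.9, 21.0)},
)

#: Reference phantom used to calibrate the simulated measurements.
REFERENCE_PROPS = {"ex": (1.0, 20.0), "em": (0.8, 17.0)}

#: 1% multiplicative measurement noise.
NOISE_1PCT = NoiseModel(shot_scale=0.0, read_sigma=0.0, multiplicative_sigma=0.01)


def _reference_ops() -> dict[float, OpticalProperties]:
    return {
        WAVELENGTH_EX: OpticalProperties(*REFERENCE_PROPS["ex"], WAVELENGTH_EX),
        WAVELENGTH_EM: OpticalProperties(*REFERENCE_PROPS["em"], WAVELENGTH_EM),
    }


def _central_mask(shape: tuple[int, int], frac: float = 0.5) -> np.ndarray:
    """Central box ROI covering ``frac`` of each dimension."""
    mask = np.zeros(shape, dtype=bool)
    r0 = int(shape[0] * (1 - frac) / 2)
    c0 = int(shape[1] * (1 - frac) / 2)
    mask[r0 : shape[0] - r0, c0 : shape[1] - c0] = True
    return mask


def _ols_r2(x, y) -> float:
    from scipy import stats

    return float(stats.linregress(np.asarray(x), np.asarray(y)).rvalue ** 2)


def corrected_fluorescence_linearity(
    seed: int = 0,
    shape: tuple[int, int] = (32, 32),
    dox_levels=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    noise: NoiseModel = NOISE_1PCT,
) -> dict:
    """Pooled corrected-vs-raw fluorescence linearity over the phantom grid.

    Simulates each of the four phantoms at every drug level, recovers
    optical properties from the structured reflectance data, applies the
    X_1D correction and pools ROI means over all phantoms.  Returns the
    pooled coefficients of determination ``r2_corrected`` / ``r2_raw``
    and the fitted concentration calibration.
    """
    rng = np.random.default_rng(seed)
    ref_ops = _reference_ops()
    ref_scene = make_phantom_scene(
        *REFERENCE_PROPS["ex"], *REFERENCE_PROPS["em"], shape=shape, noise=noise
    )
    reference = calibrate_reference(render_frameset(ref_scene, rng), ref_ops)
    roi = _central_mask(shape)
    conc, corrected, raw = [], [], []
    for phantom in PHANTOM_GRID:
        scene = make_phantom_scene(
            *phantom["ex"], *phantom["em"], shape=shape, noise=noise
        )
        fs = render_frameset(scene, rng)
        ops = {}
        for wl in (WAVELENGTH_EX, WAVELENGTH_EM):
            rd = calibrated_reflectance(demodulate_frameset(fs, wl), reference)
            ops[wl] = fit_optical_properties(rd, wl)
        x1d_est = build_correction_map(ops[WAVELENGTH_EX], ops[WAVELENGTH_EM])
        x1d_true = scene_x1d_map(scene)
        for level in dox_levels:
            lv_scene = make_phantom_scene(
                *phantom["ex"], *phantom["em"], dox_conc=level, shape=shape, noise=noise
            )
            frame = render_fluorescence_frame(lv_scene, 1.0, None, rng, x1d_true)
            net = subtract_dark(frame, np.full(shape, lv_scene.dark_level))
            corr = net / x1d_est
            conc.append(level)
            raw.append(float(net[roi].mean()))
            corrected.append(float(np.nanmean(corr[roi])))
    cal = fit_concentration_calibration(conc, corrected)
    return {
        "r2_corrected": _ols_r2(conc, corrected),
        "r2_raw": _ols_r2(conc, raw),
        "concentration_calibration": cal,
        "pooled": (np.array(conc), np.array(corrected), np.array(raw)),
    }


def height_correction_errors(
    seed: int = 0,
    shape: tuple[int, int] = (32, 32),
    sample_heights=(0.0, 2.0, 4.0, 6.0, 8.0),
    cal_heights=(0.0, 2.0, 4.0, 6.0, 8.0),
    sample_props=None,
    noise: NoiseModel = NOISE_1PCT,
    wavelength: float = WAVELENGTH_EX,
) -> dict:
    """Optical-property error versus height, with and without correction.

    A flat reference phantom is imaged at the calibration heights to fit
    the profilometry calibration; a flat sample is then re-imaged at each
    test height (fresh noise realizations) with the pattern divergence
    model and 1% noise, and inverted with the flat h=0 reference
    (uncorrected) and with the height-adjusted reference (corrected).
    By default the sample is the calibration phantom itself, mirroring
    the original distance-variation experiment; pass ``sample_props``
    ``((mu_a_ex, mu_s_ex), (mu_a_em, mu_s_em))`` to test calibration
    transfer to a different medium.  Errors are ROI means of the
    per-pixel relative error, in percent.
    """
    rng = np.random.default_rng(seed)
    ref_ops = _reference_ops()
    if sample_props is None:
        sample_props = (REFERENCE_PROPS["ex"], REFERENCE_PROPS["em"])
    stacks = simulate_calibration_stacks(
        ref_ops, cal_heights, seed=seed + 1, shape=shape, noise=noise
    )
    hcal = fit_height_calibration(stacks, ref_ops)
    reference = calibrate_reference(stacks[0.0], ref_ops)
    (mua_ex, mus_ex), (mua_em, mus_em) = sample_props
    truth = {WAVELENGTH_EX: (mua_ex, mus_ex), WAVELENGTH_EM: (mua_em, mus_em)}[wavelength]
    roi = _central_mask(shape)
    out = {"heights_mm": list(sample_heights), "corrected": [], "uncorrected": [],
           "height_error_mm": []}
    for h in sample_heights:
        scene = make_phantom_scene(
            mua_ex, mus_ex, mua_em, mus_em, shape=shape, height_mm=h, noise=noise
        )
        fs = render_frameset(scene, rng)
        maps = demodulate_frameset(fs, wavelength)
        i1, i2, i3 = fs.phase_triplet(wavelength, PROFILOMETRY_FREQUENCY)
        i1, i2, i3 = (subtract_dark(i, fs.dark) for i in (i1, i2, i3))
        pm = extract_phase(i1, i2, i3, frequency=PROFILOMETRY_FREQUENCY)
        hm = height_map(pm, hcal, wavelength)
        out["height_error_mm"].append(float(np.abs(hm.heights_mm - h)[roi].mean()))
        results = {}
        for label, kwargs in (
            ("corrected", {"heights": hm, "hcal": hcal}),
            ("uncorrected", {}),
        ):
            rd = calibrated_reflectance(maps, reference, **kwargs)
            fit = fit_optical_properties(rd, wavelength)
            err_a = np.abs(fit.mu_a - truth[0]) / truth[0]
            err_s = np.abs(fit.mu_s_prime - truth[1]) / truth[1]
            results[label] = (
                float(np.nanmean(err_a[roi]) * 100),
                float(np.nanmean(err_s[roi]) * 100),
            )
        out["corrected"].append(results["corrected"])
        out["uncorrected"].append(results["uncorrected"])
    hs = list(sample_heights)
    i8 = hs.index(8.0) if 8.0 in hs else len(hs) - 1
    out["mu_a_error_8mm_pct"] = out["corrected"][i8][0]
    out["mu_s_error_8mm_pct"] = out["corrected"][i8][1]
    out["mu_a_error_avg_pct"] = float(np.mean([c[0] for c in out["corrected"]]))
    out["mu_s_error_avg_pct"] = float(np.mean([c[1] for c in out["corrected"]]))
    out["mu_a_error_8mm_uncorrected_pct"] = out["uncorrected"][i8][0]
    return out


def four_phantom_recovery(
    seed: int = 0,
    shape: tuple[int, int] = (32, 32),
    noise: NoiseModel = NOISE_1PCT,
) -> dict:
    """Quantification error over the four-phantom grid, both wavelengths.

    Each phantom is simulated with 1% multiplicative noise, calibrated
    against the reference phantom and inverted per pixel; the reported
    numbers are the ROI-mean relative errors averaged over all phantoms
    and wavelengths, in percent.
    """
    rng = np.random.default_rng(seed)
    ref_ops = _reference_ops()
    ref_scene = make_phantom_scene(
        *REFERENCE_PROPS["ex"], *REFERENCE_PROPS["em"], shape=shape, noise=noise
    )
    reference = calibrate_reference(render_frameset(ref_scene, rng), ref_ops)
    roi = _central_mask(shape)
    errs_a, errs_s, details = [], [], []
    for phantom in PHANTOM_GRID:
        scene = make_phantom_scene(*phantom["ex"], *phantom["em"], shape=shape, noise=noise)
        fs = render_frameset(scene, rng)
        for wl, key in ((WAVELENGTH_EX, "ex"), (WAVELENGTH_EM, "em")):
            truth = phantom[key]
            rd = calibrated_reflectance(demodulate_frameset(fs, wl), reference)
            fit = fit_optical_properties(rd, wl)
            ea = float(np.nanmean(np.abs(fit.mu_a - truth[0])[roi]) / truth[0] * 100)
            es = float(np.nanmean(np.abs(fit.mu_s_prime - truth[1])[roi]) / truth[1] * 100)
            errs_a.append(ea)
            errs_s.append(es)
            details.append({"wavelength": wl, "truth": truth, "err_mu_a_pct": ea, "err_mu_s_pct": es})
    return {
        "avg_mu_a_error_pct": float(np.mean(errs_a)),
        "avg_mu_s_error_pct": float(np.mean(errs_s)),
        "details": details,
    }
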