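"""End-to-end processing: reflectance -> optical properties -> corrected
fluorescence -> concentration maps -> release kinetics.

The pipeline mirrors the instrument's dual-mode workflow: structured
reflectance acquisitions at two wavelengths give per-pixel absorption
and scattering; those feed the X_1D correction that turns raw
fluorescence into a signal proportional to drug concentration; a
calibration line converts it to absolute ug/mL; and the time series of
corrected maps yields the release curve and the time to 95% of full
release.  Since no instrument is attached, acquisitions come from the
synthetic scene generator, driven by the same configuration.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    PROFILOMETRY_FREQUENCY,
    HeightCalibration,
    ReferenceCalibration,
    calibrate_reference,
    calibrated_reflectance,
    fit_height_calibration,
    height_map,
)
from .concentration import (
    ConcCalibration,
    concentration_map,
    fit_concentration_calibration,
)
from .demod import demodulate_frameset, extract_phase
from .inversion import build_correction_map, fit_optical_properties
from .kinetics import FractionTime, ReleaseCurve, release_curve, time_to_fraction
from .optics import OpticalProperties
from .preprocess import subtract_dark, threshold_roi
from .scene import (
    WAVELENGTH_EM,
    WAVELENGTH_EX,
    NoiseModel,
    ReleaseModel,
    make_phantom_scene,
    render_fluorescence_frame,
    render_frameset,
    scene_x1d_map,
    simulate_calibration_stacks,
    simulate_release_series,
)

__all__ = ["default_config", "run_pipeline", "PipelineResult"]


def default_config() -> dict:
    """Baseline configuration; every run_pipeline key with its default."""
    return {
        "seed": 0,
        "shape": [48, 48],
        "noise": {"shot_scale": 1.25, "read_sigma": 2.0, "multiplicative_sigma": 0.0},
        "reference": {
            "mu_a_ex": 1.0,
            "mu_s_ex": 15.0,
            "mu_a_em": 0.8,
            "mu_s_em": 12.5,
        },
        "sample": {
            "mu_a_ex": 2.5,
            "mu_s_ex": 25.0,
            "mu_a_em": 1.9,
            "mu_s_em": 21.0,
            "dox": 10.0,
            "height_mm": 0.0,
            "tumor": None,
        },
        "height_correction": {"enabled": False, "heights_mm": [0, 2, 4, 6, 8]},
        "release": {
            "k0": 0.032,
            "fluence_rate": 350.0,
            "attenuation_coupling": 0.58,
            "loaded_fraction_quenched": 0.88,
            "duration_s": 600.0,
            "dt_s": 10.0,
        },
        "concentration_calibration_ug_mL": [0, 2, 4, 6, 8, 10],
        "roi_threshold_fraction": 0.5,
        "mc_photons": 100_000,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(config) -> dict:
    """Accept a dict, a JSON/YAML path, or None (defaults)."""
    if config is None:
        return default_config()
    if isinstance(config, (str, pathlib.Path)):
        text = pathlib.Path(config).read_text()
        if str(config).endswith((".yml", ".yaml")):
            import yaml

            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    if not isinstance(config, dict):
        raise TypeError("config must be a dict or a path to JSON/YAML")
    return _merge(default_config(), config)


@dataclass
class PipelineResult:
    """Everything one processed acquisition produces."""

    config: dict
    reference: ReferenceCalibration
    height_cal: HeightCalibration | None
    optical_maps: dict  # wavelength -> OpticalPropertyMaps
    height: object | None
    correction_map: np.ndarray
    conc_cal: ConcCalibration
    concentration_maps: list
    curve: ReleaseCurve
    t95: FractionTime
    log: dict = field(default_factory=dict)

    def save(self, output_dir) -> pathlib.Path:
        from .io import save_map

        out = pathlib.Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for wl, maps in self.optical_maps.items():
            save_map(maps.mu_a, out / f"mu_a_{int(wl)}nm.tif")
            save_map(maps.mu_s_prime, out / f"mu_s_prime_{int(wl)}nm.tif")
        if self.height is not None:
            save_map(self.height.heights_mm, out / "height_mm.tif")
        save_map(self.correction_map, out / "x1d_correction.tif")
        for i, cm in enumerate(self.concentration_maps):
            save_map(cm.dox, out / f"dox_t{i:03d}.tif")
        lines = ["time_s,mean_ug_mL,sd_ug_mL"]
        for t, m, s in zip(self.curve.times_s, self.curve.mean, self.curve.sd):
            lines.append(f"{t:.1f},{m:.6f},{s:.6f}")
        (out / "release_curve.csv").write_text("\n".join(lines) + "\n")
        (out / "run_log.json").write_text(json.dumps(self.log, indent=1, sort_keys=True))
        return out


def _reference_ops(cfg_ref: dict) -> dict[float, OpticalProperties]:
    return {
        WAVELENGTH_EX: OpticalProperties(cfg_ref["mu_a_ex"], cfg_ref["mu_s_ex"], WAVELENGTH_EX),
        WAVELENGTH_EM: OpticalProperties(cfg_ref["mu_a_em"], cfg_ref["mu_s_em"], WAVELENGTH_EM),
    }


def run_pipeline(config=None, output_dir=None) -> PipelineResult:
    """Run the full simulated acquisition + quantification workflow.

    Deterministic for a fixed config (all randomness flows from
    ``config["seed"]``).  Writes maps/CSV/log when ``output_dir`` given.
    """
    cfg = load_config(config)
    if "reference" not in cfg or cfg["reference"] is None:
        raise ValueError("pipeline requires a reference-phantom calibration block")
    seed = int(cfg["seed"])
    shape = tuple(cfg["shape"])
    noise = NoiseModel(**cfg["noise"])
    ref_ops = _reference_ops(cfg["reference"])
    rng = np.random.default_rng(seed)

    # --- reference acquisition (flat, h = 0)
    ref_scene = make_phantom_scene(
        cfg["reference"]["mu_a_ex"],
        cfg["reference"]["mu_s_ex"],
        cfg["reference"]["mu_a_em"],
        cfg["reference"]["mu_s_em"],
        shape=shape,
        noise=noise,
    )
    reference = calibrate_reference(
        render_frameset(ref_scene, rng if noise.enabled else None), ref_ops
    )

    # --- optional height calibration
    hcal = None
    if cfg["height_correction"]["enabled"]:
        stacks = simulate_calibration_stacks(
            ref_ops,
            cfg["height_correction"]["heights_mm"],
            seed=seed + 1,
            shape=shape,
            noise=noise,
        )
        hcal = fit_height_calibration(stacks, ref_ops)

    # --- sample acquisition
    scfg = cfg["sample"]
    sample_scene = make_phantom_scene(
        scfg["mu_a_ex"],
        scfg["mu_s_ex"],
        scfg["mu_a_em"],
        scfg["mu_s_em"],
        dox_conc=scfg["dox"],
        shape=shape,
        height_mm=scfg["height_mm"],
        tumor=scfg.get("tumor"),
        noise=noise,
    )
    sample_fs = render_frameset(sample_scene, rng if noise.enabled else None)

    # --- demodulation, optional profilometry, reflectance, inversion
    optical_maps = {}
    hmap = None
    for wl in (WAVELENGTH_EX, WAVELENGTH_EM):
        maps = demodulate_frameset(sample_fs, wl)
        if hcal is not None:
            if hmap is None:
                i1, i2, i3 = sample_fs.phase_triplet(wl, PROFILOMETRY_FREQUENCY)
                i1, i2, i3 = (subtract_dark(i, sample_fs.dark) for i in (i1, i2, i3))
                pm = extract_phase(i1, i2, i3, frequency=PROFILOMETRY_FREQUENCY)
                hmap = height_map(pm, hcal, wl)
            rd = calibrated_reflectance(maps, reference, heights=hmap, hcal=hcal)
        else:
            rd = calibrated_reflectance(maps, reference)
        optical_maps[wl] = fit_optical_properties(rd, wl)

    correction = build_correction_map(optical_maps[WAVELENGTH_EX], optical_maps[WAVELENGTH_EM])
    corr_safe = np.where(np.isfinite(correction) & (correction > 0), correction, np.nan)

    # --- concentration calibration: known additions, fully released
    model = ReleaseModel(
        k0=cfg["release"]["k0"],
        fluence_rate=cfg["release"]["fluence_rate"],
        attenuation_coupling=cfg["release"]["attenuation_coupling"],
        loaded_fraction_quenched=cfg["release"]["loaded_fraction_quenched"],
    )
    cal_levels = list(cfg["concentration_calibration_ug_mL"])
    x1d_true = scene_x1d_map(sample_scene)
    cal_conc, cal_signal = [], []
    for level in cal_levels:
        cal_scene = make_phantom_scene(
            scfg["mu_a_ex"],
            scfg["mu_s_ex"],
            scfg["mu_a_em"],
            scfg["mu_s_em"],
            dox_conc=level,
            shape=shape,
            height_mm=scfg["height_mm"],
            noise=noise,
        )
        frame = render_fluorescence_frame(
            cal_scene, 1.0, model, rng if noise.enabled else None, x1d_true
        )
        corrected = subtract_dark(frame, np.full(shape, cal_scene.dark_level)) / corr_safe
        cal_conc.append(level)
        cal_signal.append(float(np.nanmean(corrected)))
    conc_cal = fit_concentration_calibration(cal_conc, cal_signal)

    # --- triggered-release series
    series = simulate_release_series(
        sample_scene, model, cfg["release"]["duration_s"], cfg["release"]["dt_s"], seed=seed + 2
    )
    conc_maps = []
    for frame in series.frames:
        corrected = subtract_dark(frame, series.dark) / corr_safe
        conc_maps.append(concentration_map(np.nan_to_num(corrected), conc_cal))
    roi = threshold_roi(
        conc_maps[-1].dox, cfg["roi_threshold_fraction"], source="final release map"
    )
    curve = release_curve(conc_maps, series.times_s, roi)
    t95 = time_to_fraction(curve, 0.95)

    log = {
        "seed": seed,
        "shape": list(shape),
        "t95_s": t95.time_s,
        "t95_reached": t95.reached,
        "conc_cal_slope": conc_cal.slope,
        "conc_cal_r2": conc_cal.r_squared,
        "final_mean_ug_mL": float(curve.mean[-1]),
        "height_corrected": hcal is not None,
    }
    result = PipelineResult(
        config=cfg,
        reference=reference,
        height_cal=hcal,
        optical_maps=optical_maps,
        height=hmap,
        correction_map=correction,
        conc_cal=conc_cal,
        concentration_maps=conc_maps,
        curve=curve,
        t95=t95,
        log=log,
    )
    if output_dir is not None:
        result.save(output_dir)
    return result
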