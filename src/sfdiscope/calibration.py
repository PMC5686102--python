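"""Reference-phantom calibration and profilometry height correction.

Measured modulation amplitudes are converted to absolute diffuse
reflectance by ratioing against a phantom of known optical properties
and multiplying by the forward-model prediction for that phantom:

    R_d(f) = M_AC,sample(f) / M_AC,ref(f) * R_d,model(ref, f)

The f = 0 channel uses the DC images.  When the surface sits below the
focal plane the projected pattern diverges (higher local frequency,
lower intensity), which biases this ratio; the height correction
replaces the flat reference amplitude by the amplitude the reference
phantom shows at the same height, looked up from a once-acquired stack
of calibration measurements at known offsets and a per-pixel
phase-to-height linear fit at the highest frequency (2.0 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demod import ModulationMaps, PhaseMap, demodulate_frameset, extract_phase, unwrap_phase
from .optics import OpticalProperties, rd_forward
from .scene import FrameSet

__all__ = [
    "ReferenceCalibration",
    "HeightCalibration",
    "HeightMap",
    "ReflectanceMaps",
    "calibrate_reference",
    "fit_height_calibration",
    "height_map",
    "calibrated_reflectance",
]

#: Frequency whose fringes drive the profilometry (highest projected).
PROFILOMETRY_FREQUENCY = 2.0


@dataclass
class ReferenceCalibration:
    """Reference phantom: known properties + measured amplitudes at h=0."""

    reference_ops: dict[float, OpticalProperties]
    measured: dict[float, ModulationMaps]  # wavelength -> maps

    def model_rd(self, wavelength: float, f: float) -> float:
        op = self.reference_ops[wavelength]
        return rd_forward(op.mu_a, op.mu_s_prime, f)


@dataclass
class HeightMap:
    """Per-pixel surface offset below the focal plane, mm."""

    heights_mm: np.ndarray
    in_range: np.ndarray  # False where clamped to the calibrated range

    def __post_init__(self) -> None:
        self.in_range = np.asarray(self.in_range, dtype=bool)


@dataclass
class ReflectanceMaps:
    """Calibrated diffuse reflectance images per spatial frequency."""

    r_d: dict[float, np.ndarray]
    wavelength: float
    height_corrected: bool = False
    invalid: np.ndarray | None = None

    def frequencies(self) -> list[float]:
        return sorted(self.r_d)

    def stack(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies, (n_f, H, W) array) in frequency order."""
        fs = self.frequencies()
        return np.array(fs), np.stack([self.r_d[f] for f in fs])


@dataclass
class HeightCalibration:
    """Phase->height and height->reference-amplitude calibration.

    Built from flat-phantom stacks at known heights.  ``phase_fit``
    holds per-pixel (slope, intercept) of the linear map h = s*phi + b
    per wavelength; ``ref_amp`` holds the height-resolved reference
    amplitude stack per (wavelength, frequency), interpolated piecewise
    linearly in h at correction time.
    """

    heights_mm: np.ndarray
    reference_ops: dict[float, OpticalProperties]
    phase_fit: dict[float, tuple[np.ndarray, np.ndarray]]
    ref_amp: dict[tuple[float, float], np.ndarray]  # (wl, f) -> (n_h, H, W)
    phase_stacks: dict[float, np.ndarray] = field(default_factory=dict)
    fit_rms_mm: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def h_range(self) -> tuple[float, float]:
        return float(self.heights_mm[0]), float(self.heights_mm[-1])

    def reference_amplitude_at(
        self, wavelength: float, f: float, heights: np.ndarray
    ) -> np.ndarray:
        """Height-adjusted reference amplitude, per pixel.

        Piecewise-linear interpolation through the calibration nodes
        along the height axis, independently at each pixel; heights are
        clamped to the calibrated range.
        """
        stack = self.ref_amp[(wavelength, f)]
        hs = self.heights_mm
        h = np.clip(heights, hs[0], hs[-1])
        idx = np.clip(np.searchsorted(hs, h) - 1, 0, len(hs) - 2)
        h0 = hs[idx]
        h1 = hs[idx + 1]
        w = np.where(h1 > h0, (h - h0) / np.where(h1 > h0, h1 - h0, 1.0), 0.0)
        pix = np.indices(h.shape)
        lo = stack[idx, pix[0], pix[1]]
        hi = stack[idx + 1, pix[0], pix[1]]
        return (1.0 - w) * lo + w * hi


def calibrate_reference(
    fs: FrameSet, reference_ops: dict[float, OpticalProperties]
) -> ReferenceCalibration:
    """Build a reference calibration from a flat measurement at h = 0."""
    measured = {wl: demodulate_frameset(fs, wl) for wl in fs.wavelengths()}
    missing = set(fs.wavelengths()) - set(reference_ops)
    if missing:
        raise ValueError(f"no known optical properties for wavelengths {missing}")
    return ReferenceCalibration(reference_ops=dict(reference_ops), measured=measured)


def fit_height_calibration(
    stacks: dict[float, FrameSet],
    reference_ops: dict[float, OpticalProperties],
    f_phase: float = PROFILOMETRY_FREQUENCY,
) -> HeightCalibration:
    """Fit the profilometry calibration from flat stacks at known heights.

    Requires at least three distinct heights.  Per pixel and wavelength,
    the unwrapped fringe phase at the profilometry frequency is fit
    linearly against height (h = s*phi + b); the demodulated amplitude
    maps at every frequency are stored per height for the
    height-adjusted reference lookup.
    """
    heights = np.array(sorted(stacks), dtype=float)
    if len(heights) < 3:
        raise ValueError("need at least 3 distinct calibration heights")
    wavelengths = stacks[heights[0]].wavelengths()
    phase_fit, ref_amp, phase_stacks, fit_rms = {}, {}, {}, {}
    for wl in wavelengths:
        phases = []
        amp_stacks: dict[float, list[np.ndarray]] = {}
        for h in heights:
            fs = stacks[h]
            maps = demodulate_frameset(fs, wl)
            for f in [0.0] + maps.frequencies():
                amp_stacks.setdefault(f, []).append(maps.amplitude(f))
            i1, i2, i3 = fs.phase_triplet(wl, f_phase)
            pm = extract_phase(i1, i2, i3, frequency=f_phase)
            phases.append(unwrap_phase(pm).phase)
        phi = np.stack(phases)  # (n_h, H, W)
        var = phi.var(axis=0)
        if np.any(var <= 1e-18):
            raise ValueError("degenerate (constant) phase across heights")
        hvec = heights[:, None, None]
        phi_mean = phi.mean(axis=0)
        h_mean = heights.mean()
        cov = ((phi - phi_mean) * (hvec - h_mean)).mean(axis=0)
        slope = cov / var
        intercept = h_mean - slope * phi_mean
        pred = slope * phi + intercept
        fit_rms[wl] = np.sqrt(((pred - hvec) ** 2).mean(axis=0))
        phase_fit[wl] = (slope, intercept)
        phase_stacks[wl] = phi
        for f, imgs in amp_stacks.items():
            ref_amp[(wl, f)] = np.stack(imgs)
    return HeightCalibration(
        heights_mm=heights,
        reference_ops=dict(reference_ops),
        phase_fit=phase_fit,
        ref_amp=ref_amp,
        phase_stacks=phase_stacks,
        fit_rms_mm=fit_rms,
    )


def height_map(
    phase: PhaseMap, calib: HeightCalibration, wavelength: float
) -> HeightMap:
    """Per-pixel height from an (unwrapped) profilometry phase map.

    Wrapped input is unwrapped first.  Heights outside the calibrated
    range are clamped and flagged out-of-range rather than extrapolated.
    """
    if wavelength not in calib.phase_fit:
        raise ValueError(f"calibration has no phase fit at {wavelength} nm")
    if phase.wrapped:
        phase = unwrap_phase(phase)
    slope, intercept = calib.phase_fit[wavelength]
    h = slope * phase.phase + intercept
    lo, hi = calib.h_range
    in_range = (h >= lo) & (h <= hi) & phase.valid
    return HeightMap(heights_mm=np.clip(h, lo, hi), in_range=in_range)


def calibrated_reflectance(
    sample: ModulationMaps,
    ref: ReferenceCalibration | None = None,
    heights: HeightMap | None = None,
    hcal: HeightCalibration | None = None,
) -> ReflectanceMaps:
    """Diffuse reflectance maps from demodulated sample amplitudes.

    Without heights the flat (h = 0) reference amplitudes are used.
    With ``heights`` and ``hcal`` the reference amplitude at each pixel
    is the height-adjusted value interpolated from the calibration
    stacks, which removes the divergence bias of surfaces below the
    focal plane.  At least one of ``ref``/``hcal`` must be given.
    """
    wl = sample.wavelength
    use_hcal = heights is not None
    if use_hcal and hcal is None:
        raise ValueError("height correction requested but no HeightCalibration given")
    if not use_hcal and ref is None:
        raise ValueError("no reference calibration given")
    source_ops = hcal.reference_ops if use_hcal else ref.reference_ops
    if wl not in source_ops:
        raise ValueError(f"reference optical properties missing at {wl} nm")
    op = source_ops[wl]
    out: dict[float, np.ndarray] = {}
    invalid = np.zeros(sample.m_dc.shape, dtype=bool)
    for f in [0.0] + sample.frequencies():
        amp_sample = sample.amplitude(f)
        if use_hcal:
            amp_ref = hcal.reference_amplitude_at(wl, f, heights.heights_mm)
        else:
            if wl not in ref.measured:
                raise ValueError(f"reference has no measurement at {wl} nm")
            amp_ref = ref.measured[wl].amplitude(f)
        bad = ~(amp_ref > 0)
        invalid |= bad
        safe_ref = np.where(bad, 1.0, amp_ref)
        rd_model = rd_forward(op.mu_a, op.mu_s_prime, f)
        rd = amp_sample / safe_ref * rd_model
        rd[bad] = np.nan
        out[f] = np.clip(rd, 0.0, 1.0)
    return ReflectanceMaps(
        r_d=out, wavelength=wl, height_corrected=use_hcal, invalid=invalid
    )
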