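"""Release-kinetics curves, spectral unmixing, and resolution arithmetic."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .concentration import ConcentrationMap
from .preprocess import RoiMask

__all__ = [
    "ReleaseCurve",
    "FractionTime",
    "SpectrumSample",
    "release_curve",
    "time_to_fraction",
    "unmix_spectrum",
    "usaf_resolution",
]


@dataclass
class ReleaseCurve:
    """ROI-mean drug concentration versus treatment time."""

    times_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    roi: RoiMask | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.times_s) == len(self.mean) == len(self.sd)):
            raise ValueError("times, mean and sd must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class FractionTime:
    """Time to reach a release fraction; ``reached`` is False when the
    curve never attains it (the time is then the last sample, flagged)."""

    time_s: float
    reached: bool
    fraction: float
    plateau: float

    def __float__(self) -> float:  # convenient in arithmetic
        return self.time_s


@dataclass
class SpectrumSample:
    """Emission spectrum on a uniform wavelength grid (nm)."""

    wavelengths_nm: np.ndarray
    counts: np.ndarray
    background_subtracted: bool = True

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavelengths_nm.shape != self.counts.shape:
            raise ValueError("wavelengths and counts must have equal length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be increasing")


def release_curve(
    conc_maps: list[ConcentrationMap], times_s, roi: RoiMask
) -> ReleaseCurve:
    """ROI mean +- sd of concentration at each time point."""
    times = np.asarray(times_s, dtype=float)
    if len(conc_maps) != len(times):
        raise ValueError("one concentration map per time point required")
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    if roi.count == 0:
        raise ValueError("ROI is empty")
    means, sds = [], []
    for cm in conc_maps:
        m, s = roi.mean_sd(cm.dox)
        means.append(m)
        sds.append(s)
    return ReleaseCurve(times, np.array(means), np.array(sds), roi)


def time_to_fraction(
    curve: ReleaseCurve, fraction: float = 0.95, plateau_points: int = 3
) -> FractionTime:
    """First time the ROI mean reaches ``fraction`` of the full release.

    "Full release" is estimated as the mean of the final
    ``plateau_points`` samples; the crossing time is linearly
    interpolated between the bracketing samples.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    plateau = float(curve.mean[-plateau_points:].mean())
    if plateau <= 0:
        raise ValueError("release curve has no positive final plateau")
    target = fraction * plateau
    above = curve.mean >= target
    if not above.any():
        return FractionTime(float(curve.times_s[-1]), False, fraction, plateau)
    i = int(np.argmax(above))
    if i == 0:
        return FractionTime(float(curve.times_s[0]), True, fraction, plateau)
    t0, t1 = curve.times_s[i - 1], curve.times_s[i]
    y0, y1 = curve.mean[i - 1], curve.mean[i]
    t = t0 + (target - y0) / (y1 - y0) * (t1 - t0) if y1 > y0 else t1
    return FractionTime(float(t), True, fraction, plateau)


def unmix_spectrum(
    sample: SpectrumSample,
    dox_basis: SpectrumSample,
    autofluor_basis: SpectrumSample,
) -> tuple[float, float, float]:
    """Nonnegative least-squares unmixing into drug + autofluorescence.

    Returns ``(dox_coeff, autofluor_coeff, residual_norm)``.  The drug
    coefficient converts to concentration through a standard-curve slope
    measured on the same plate.  Bases must share the sample's
    wavelength grid and be linearly independent.
    """
    for basis in (dox_basis, autofluor_basis):
        if not np.array_equal(basis.wavelengths_nm, sample.wavelengths_nm):
            raise ValueError("basis and sample wavelength grids differ")
    A = np.column_stack([dox_basis.counts, autofluor_basis.counts])
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("basis spectra are linearly dependent")
    coeffs, rnorm = nnls(A, sample.counts)
    return float(coeffs[0]), float(coeffs[1]), float(rnorm)


def usaf_resolution(group: int, element: int) -> tuple[float, float]:
    """USAF-1951 target arithmetic.

    Resolution of group g, element e is ``2**(g + (e-1)/6)`` line pairs
    per mm; the bar (line) width is ``500/resolution`` um.  Returns
    ``(resolution_lp_per_mm, bar_width_um)``.
    """
    if int(element) != element or not 1 <= element <= 6:
        raise ValueError("element must be an integer in [1, 6]")
    if int(group) != group:
        raise ValueError("group must be an integer")
    resolution = 2.0 ** (group + (element - 1) / 6.0)
    return resolution, 500.0 / resolution
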