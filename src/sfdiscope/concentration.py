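"""Conversion of attenuation-corrected fluorescence to drug concentration.

A calibration line (ordinary least squares of corrected signal against
known doxorubicin concentrations) converts corrected fluorescence
images to absolute concentration maps in ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import RoiMask

__all__ = [
    "ConcCalibration",
    "ConcentrationMap",
    "fit_concentration_calibration",
    "concentration_map",
    "dilution_concentration",
    "percent_error",
]


@dataclass
class ConcCalibration:
    """OLS line: corrected-fluorescence counts per (ug/mL)."""

    slope: float
    intercept: float
    r_squared: float
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


@dataclass
class ConcentrationMap:
    """Drug concentration image, ug/mL, with ROI summary."""

    dox: np.ndarray
    clipped: np.ndarray  # True where a negative fit output was clipped to 0
    roi_mean: float = np.nan
    roi_sd: float = np.nan

    def summarize(self, roi: RoiMask) -> "ConcentrationMap":
        mean, sd = roi.mean_sd(self.dox)
        self.roi_mean, self.roi_sd = mean, sd
        return self


def fit_concentration_calibration(
    concentrations, corrected_signals
) -> ConcCalibration:
    """Fit the concentration calibration line by OLS.

    ``concentrations`` (ug/mL) and ``corrected_signals`` may contain
    repeated concentration levels (e.g. several phantoms per level);
    at least three distinct levels, including 0, are required.
    """
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(corrected_signals, dtype=float)
    if conc.shape != sig.shape:
        raise ValueError("concentrations and signals must have equal length")
    levels = np.unique(conc)
    if len(levels) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    if not np.any(levels == 0.0):
        raise ValueError("calibration requires a zero-concentration baseline")
    res = stats.linregress(conc, sig)
    return ConcCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentrations=tuple(np.sort(levels)),
    )


def concentration_map(f_corrected: np.ndarray, cal: ConcCalibration) -> ConcentrationMap:
    """Invert the calibration line: dox = (F_corr - intercept)/slope.

    Negative outputs (signal below the calibration baseline) are clipped
    to 0 and flagged.
    """
    if cal.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    raw = (np.asarray(f_corrected, dtype=float) - cal.intercept) / cal.slope
    clipped = raw < 0
    return ConcentrationMap(dox=np.maximum(raw, 0.0), clipped=clipped)


def dilution_concentration(
    added_volume_uL: float, stock_mg_per_mL: float, phantom_volume_mL: float
) -> float:
    """Concentration (ug/mL) after spiking a phantom with stock drug.

    ``added * stock / phantom_volume`` -- the added volume's own dilution
    of the total is neglected, matching the instrument's calibration
    arithmetic (1000 uL of 1 mg/mL into 100 mL -> 10.0 ug/mL).
    """
    if phantom_volume_mL <= 0:
        raise ValueError("phantom volume must be > 0")
    if added_volume_uL < 0 or stock_mg_per_mL < 0:
        raise ValueError("volumes and stock concentration must be >= 0")
    return added_volume_uL * stock_mg_per_mL / phantom_volume_mL


def percent_error(measured: float, expected: float) -> float:
    """|measured - expected| / expected, in percent."""
    if expected == 0:
        raise ValueError("expected value must be nonzero")
    return abs(measured - expected) / abs(expected) * 100.0
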