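"""Three-phase demodulation and fringe-phase extraction.

The instrument projects sine patterns at phase offsets (0, 2pi/3,
4pi/3).  For frames ``i_k = DC + AC cos(phi + psi_k)`` the standard
three-phase identities recover amplitude and phase exactly:

    M_AC = (sqrt(2)/3) sqrt[(i1-i2)^2 + (i2-i3)^2 + (i3-i1)^2]
    M_DC = (i1 + i2 + i3)/3
    phi  = atan2(sqrt(3) (i3 - i2), 2 i1 - i2 - i3)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import FrameSet
from .preprocess import subtract_dark

__all__ = [
    "ModulationMaps",
    "PhaseMap",
    "demodulate",
    "extract_phase",
    "unwrap_phase",
    "demodulate_frameset",
]


@dataclass
class ModulationMaps:
    """Demodulated amplitude maps per spatial frequency (one wavelength).

    ``m_ac[f]`` is the AC modulation amplitude at frequency f (counts);
    ``m_dc`` is the mean (DC) image.  The f = 0 channel of a measurement
    is represented by ``m_dc``, not by an AC amplitude.
    """

    m_ac: dict[float, np.ndarray]
    m_dc: np.ndarray
    wavelength: float = 0.0

    def frequencies(self) -> list[float]:
        return sorted(self.m_ac)

    def amplitude(self, f: float) -> np.ndarray:
        """Calibration amplitude at f: M_AC, or M_DC for the f=0 channel."""
        return self.m_dc if f == 0.0 else self.m_ac[f]


@dataclass
class PhaseMap:
    """Wrapped or unwrapped fringe phase with a validity mask."""

    phase: np.ndarray
    valid: np.ndarray
    wrapped: bool = True
    frequency: float = 0.0

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def invalid_fraction(self) -> float:
        return float(1.0 - self.valid.mean())


def _check_triplet(i1, i2, i3):
    i1, i2, i3 = (np.asarray(a, dtype=float) for a in (i1, i2, i3))
    if not (i1.shape == i2.shape == i3.shape):
        raise ValueError("phase-shifted images must share one shape")
    return i1, i2, i3


def demodulate(i1, i2, i3) -> tuple[np.ndarray, np.ndarray]:
    """AC and DC amplitude from three phase-shifted frames."""
    i1, i2, i3 = _check_triplet(i1, i2, i3)
    m_ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    m_dc = (i1 + i2 + i3) / 3.0
    return m_ac, m_dc


def extract_phase(i1, i2, i3, frequency: float = 0.0, rel_tol: float = 1e-9) -> PhaseMap:
    """Wrapped fringe phase in (-pi, pi].

    Pixels with vanishing modulation amplitude (relative to the local DC
    level) have undefined phase and are flagged invalid.
    """
    i1, i2, i3 = _check_triplet(i1, i2, i3)
    num = np.sqrt(3.0) * (i3 - i2)
    den = 2.0 * i1 - i2 - i3
    phi = np.arctan2(num, den)
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract.
    phi = np.where(phi <= -np.pi, np.pi, phi)
    m_ac, m_dc = demodulate(i1, i2, i3)
    valid = m_ac > rel_tol * np.maximum(np.abs(m_dc), 1.0)
    return PhaseMap(phase=phi, valid=valid, wrapped=True, frequency=frequency)


def unwrap_phase(wrapped: PhaseMap, max_invalid_fraction: float = 0.5) -> PhaseMap:
    """Two-dimensional phase unwrapping.

    Uses the reliability-sorted unwrapper from scikit-image, honouring
    the validity mask, then re-anchors the result so the first valid
    pixel keeps its wrapped value (the generator guarantees |phase| < pi
    there, making the unwrapped surface absolute rather than relative).
    """
    if not wrapped.wrapped:
        return wrapped
    if wrapped.invalid_fraction > max_invalid_fraction:
        raise ValueError(
            f"{wrapped.invalid_fraction:.0%} of pixels are invalid; cannot unwrap"
        )
    from skimage.restoration import unwrap_phase as _sk_unwrap

    if wrapped.valid.all():
        out = np.asarray(_sk_unwrap(wrapped.phase))
    else:
        marr = np.ma.array(wrapped.phase, mask=~wrapped.valid)
        out = np.asarray(_sk_unwrap(marr).filled(0.0))
    anchor = tuple(np.argwhere(wrapped.valid)[0])
    shift = wrapped.phase[anchor] - out[anchor]
    out = out + 2.0 * np.pi * np.round(shift / (2.0 * np.pi))
    return PhaseMap(out, wrapped.valid.copy(), wrapped=False, frequency=wrapped.frequency)


def demodulate_frameset(
    fs: FrameSet, wavelength: float, dark_subtract: bool = True
) -> ModulationMaps:
    """Demodulate every frequency of one wavelength channel.

    The f = 0 channel (unmodulated illumination) contributes the DC
    image; nonzero frequencies contribute AC amplitude maps.  When no
    f = 0 channel was acquired, M_DC falls back to the mean DC of the
    modulated channels.
    """
    m_ac: dict[float, np.ndarray] = {}
    dc_images = []
    dc0 = None
    for f in fs.frequencies(wavelength):
        i1, i2, i3 = fs.phase_triplet(wavelength, f)
        if dark_subtract:
            i1, i2, i3 = (subtract_dark(i, fs.dark) for i in (i1, i2, i3))
        ac, dc = demodulate(i1, i2, i3)
        if f == 0.0:
            dc0 = dc
        else:
            m_ac[f] = ac
            dc_images.append(dc)
    if dc0 is None:
        if not dc_images:
            raise ValueError("frameset has no frequencies for this wavelength")
        dc0 = np.mean(dc_images, axis=0)
    return ModulationMaps(m_ac=m_ac, m_dc=dc0, wavelength=wavelength)
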