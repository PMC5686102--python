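"""Frame conditioning: dark subtraction, honeycomb removal, distortion
correction, binning and ROI selection.

The fixed pipeline order is dark -> honeycomb -> distortion -> bin.
All operations preserve nonnegativity; only :func:`bin_pixels` changes
shape.  Image coordinates are 0-based row-major with pixel (0, 0) at the
top left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import warp

__all__ = [
    "RoiMask",
    "subtract_dark",
    "remove_honeycomb",
    "apply_distortion",
    "correct_distortion",
    "bin_pixels",
    "threshold_roi",
]


@dataclass
class RoiMask:
    """Boolean region of interest from an intensity threshold."""

    mask: np.ndarray
    threshold_fraction: float
    source: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def mean_sd(self, img: np.ndarray) -> tuple[float, float]:
        """Mean and standard deviation of ``img`` over the mask."""
        vals = np.asarray(img)[self.mask]
        return float(vals.mean()), float(vals.std())


def subtract_dark(img: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Dark-frame subtraction, clipped at zero."""
    img = np.asarray(img, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if img.shape != dark.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {dark.shape}")
    return np.maximum(img - dark, 0.0)


def remove_honeycomb(img: np.ndarray, fiber_pitch_px: float, width_frac: float = 0.18) -> np.ndarray:
    """Suppress the fiber-bundle honeycomb lattice by Fourier notching.

    A Gaussian annular notch is applied at the lattice's fundamental
    radial frequency 1/pitch (cycles/px) and its first harmonic; DC and
    low-frequency image content pass untouched.  ``width_frac`` sets the
    notch width as a fraction of the fundamental radius.
    """
    img = np.asarray(img, dtype=float)
    if fiber_pitch_px <= 2:
        raise ValueError("fiber pitch must exceed 2 px (Nyquist)")
    if fiber_pitch_px >= min(img.shape):
        raise ValueError("fiber pitch must be smaller than the image")
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    r = np.hypot(fy, fx)
    r0 = 1.0 / fiber_pitch_px
    sigma = width_frac * r0
    mask = np.ones_like(r)
    for harmonic in (1.0, 2.0):
        rc = harmonic * r0
        if rc >= 0.5 * np.sqrt(2):
            break
        mask *= 1.0 - np.exp(-0.5 * ((r - rc) / sigma) ** 2)
    # Never touch the low-pass band that carries the scene.
    mask[r < 0.5 * r0] = 1.0
    out = np.fft.ifft2(np.fft.fft2(img) * mask).real
    return np.maximum(out, 0.0)


def _radial_maps(shape: tuple[int, int]):
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    norm = np.hypot(cy, cx)  # half-diagonal normalizes the radius
    return cy, cx, norm


def apply_distortion(img: np.ndarray, coefficient: float, order: int = 1) -> np.ndarray:
    """Forward radial (barrel/pincushion) warp of an ideal image.

    The observed position of a true point at normalized radius ``rn`` is
    ``rn (1 + coefficient * rn^2)``.  Sampling the ideal image therefore
    requires the inverse mapping, solved per pixel by Newton iteration.
    Used by the virtual camera; :func:`correct_distortion` undoes it.
    """
    img = np.asarray(img, dtype=float)
    if coefficient == 0.0:
        return img.copy()
    cy, cx, norm = _radial_maps(img.shape)
    _check_invertible(coefficient)

    def inverse_map(coords):
        y = (coords[:, 0] - cy) / norm
        x = (coords[:, 1] - cx) / norm
        r_obs = np.hypot(y, x)
        r_true = _invert_radial(r_obs, coefficient)
        scale = np.where(r_obs > 0, r_true / np.maximum(r_obs, 1e-12), 1.0)
        return np.column_stack([y * scale * norm + cy, x * scale * norm + cx])

    return warp(img, inverse_map, order=order, mode="edge", preserve_range=True)


def correct_distortion(img: np.ndarray, coefficient: float, order: int = 1) -> np.ndarray:
    """Inverse radial remap undoing :func:`apply_distortion`.

    For each corrected (true) pixel, sample the observed image at
    ``rn (1 + coefficient * rn^2)``.
    """
    img = np.asarray(img, dtype=float)
    if coefficient == 0.0:
        return img.copy()
    if not np.isfinite(coefficient):
        raise ValueError("distortion coefficient must be finite")
    cy, cx, norm = _radial_maps(img.shape)
    _check_invertible(coefficient)

    def inverse_map(coords):
        y = (coords[:, 0] - cy) / norm
        x = (coords[:, 1] - cx) / norm
        rn2 = y * y + x * x
        scale = 1.0 + coefficient * rn2
        return np.column_stack([y * scale * norm + cy, x * scale * norm + cx])

    out = warp(img, inverse_map, order=order, mode="edge", preserve_range=True)
    return np.maximum(out, 0.0)


def _check_invertible(coefficient: float) -> None:
    # r_obs(r_true) must be strictly increasing over the image extent
    # (normalized radius <= 1): d/dr [r + k r^3] = 1 + 3 k r^2 > 0.
    if not np.isfinite(coefficient):
        raise ValueError("distortion coefficient must be finite")
    if 1.0 + 3.0 * coefficient > 0:
        return
    raise ValueError(
        f"radial coefficient {coefficient} is not invertible over the image extent"
    )


def _invert_radial(r_obs: np.ndarray, k: float, iters: int = 8) -> np.ndarray:
    r = r_obs.copy()
    for _ in range(iters):
        fr = r * (1.0 + k * r * r) - r_obs
        dfr = 1.0 + 3.0 * k * r * r
        r = r - fr / dfr
    return np.maximum(r, 0.0)


def bin_pixels(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean binning over ``factor x factor`` tiles.

    Mean (not sum) so that gains stay comparable across binning factors.
    Trailing rows/columns that do not fill a tile are dropped.
    """
    img = np.asarray(img, dtype=float)
    if int(factor) != factor or factor < 1:
        raise ValueError("binning factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return img.copy()
    ny = img.shape[0] // factor
    nx = img.shape[1] // factor
    if ny == 0 or nx == 0:
        raise ValueError("binning factor exceeds image size")
    trimmed = img[: ny * factor, : nx * factor]
    return trimmed.reshape(ny, factor, nx, factor).mean(axis=(1, 3))


def threshold_roi(img: np.ndarray, fraction: float = 0.5, source: str = "") -> RoiMask:
    """Pixels at or above ``fraction`` of the peak intensity.

    The instrument convention for target ROIs is the 50%-of-peak
    threshold; the mask is true where ``img >= fraction * max(img)``.
    """
    img = np.asarray(img, dtype=float)
    peak = float(np.nanmax(img))
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("image has no positive peak to threshold against")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return RoiMask(mask=img >= fraction * peak, threshold_fraction=fraction, source=source)
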