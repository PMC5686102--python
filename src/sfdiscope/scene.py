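"""Synthetic scenes and a virtual structured-illumination camera.

Every test and desk-scale experiment in this package runs on frames
produced here: a scene holds per-pixel optical-property, drug and height
maps plus an instrument description (gain, dark level, noise, fiber
honeycomb, lens distortion, pattern divergence), and the render
functions turn it into the phase-shifted intensity stacks the real
instrument would record.

Geometry of the projected fringes
---------------------------------
Patterns are defined at the focal (reference) plane.  Because the
projection diverges, a surface ``h`` mm below that plane sees a pattern
whose local frequency grows as ``f_eff = f (1 + h/d0)`` while the
collected intensity falls as ``(1 + h/d0)^-2``; the fringe phase at a
fixed pixel also shifts linearly with height (small-angle triangulation),
``dpsi = kappa f h``.  ``d0`` is the nominal working distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import OpticalProperties, rd_forward, x1d_factor

__all__ = [
    "AcquisitionSpec",
    "NoiseModel",
    "FiberSpec",
    "SceneSpec",
    "ReleaseModel",
    "FrameSet",
    "ReleaseSeries",
    "make_phantom_scene",
    "render_reflectance_frame",
    "render_fluorescence_frame",
    "render_frameset",
    "simulate_release_series",
    "simulate_calibration_stacks",
    "scene_x1d_map",
]

PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

#: Acquisition wavelengths, nm (drug excitation / emission).
WAVELENGTH_EX = 490.0
WAVELENGTH_EM = 590.0

#: The four projected spatial frequencies, cm^-1 (evenly spanning 0-2).
DEFAULT_FREQUENCIES = (0.0, 2.0 / 3.0, 4.0 / 3.0, 2.0)


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise, Gaussian read noise, and an
    optional purely multiplicative term.

    ``shot_scale`` is the photoelectron count per digital count; the
    default puts ~1% relative shot noise on a 10^4-count signal.  Set
    everything to 0 for noise-free renders.
    """

    shot_scale: float = 1.25
    read_sigma: float = 2.0
    multiplicative_sigma: float = 0.0

    @property
    def enabled(self) -> bool:
        return self.shot_scale > 0 or self.read_sigma > 0 or self.multiplicative_sigma > 0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img
        if self.shot_scale > 0:
            out = rng.poisson(np.maximum(out, 0.0) * self.shot_scale) / self.shot_scale
        if self.multiplicative_sigma > 0:
            out = out * (1.0 + self.multiplicative_sigma * rng.standard_normal(img.shape))
        if self.read_sigma > 0:
            out = out + self.read_sigma * rng.standard_normal(img.shape)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class FiberSpec:
    """Imaging fiber bundle: honeycomb lattice pitch and artifact depth."""

    element_count: int = 30_000
    pitch_px: float = 8.0
    artifact_depth: float = 0.0  # 0 disables, 1 = full modulation

    def pattern(self, shape: tuple[int, int]) -> np.ndarray:
        """Multiplicative honeycomb transmission pattern, mean ~1."""
        if self.artifact_depth <= 0:
            return np.ones(shape)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        k = 2.0 * np.pi / self.pitch_px
        pat = np.zeros(shape)
        for ang in (0.0, np.pi / 3.0, 2.0 * np.pi / 3.0):
            pat += np.cos(k * (np.cos(ang) * xx + np.sin(ang) * yy))
        return 1.0 + self.artifact_depth * pat / 3.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """What the virtual instrument acquires and how."""

    wavelengths: tuple[float, ...] = (WAVELENGTH_EX, WAVELENGTH_EM)
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    fov_cm: float = 1.6
    exposure_s: float = 0.1


@dataclass
class SceneSpec:
    """Per-pixel ground truth plus the instrument description.

    All maps share one shape.  Optical-property maps are stored per
    wavelength channel (490 nm excitation, 590 nm emission); heights in
    mm below the focal plane; drug concentration in ug/mL.
    """

    mu_a_ex: np.ndarray
    mu_s_ex: np.ndarray
    mu_a_em: np.ndarray
    mu_s_em: np.ndarray
    dox: np.ndarray
    height_mm: np.ndarray
    tumor_mask: np.ndarray
    fiber: FiberSpec = field(default_factory=FiberSpec)
    distortion: float = 0.0  # radial coefficient, normalized radius
    gain: float = 30_000.0  # counts per unit reflectance
    gain_f: float = 500.0  # fluorescence counts per (ug/mL x X_1D)
    dark_level: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    d0_mm: float = 10.0  # nominal working distance for divergence
    # Fringe phase shift per height, rad per (mm x cm^-1).  Small enough
    # that the first-pixel absolute phase stays inside (-pi, pi] over the
    # whole 0-8 mm range, which keeps unwrapped phase maps absolute.
    kappa: float = 0.1
    mu_a_treatment: np.ndarray | None = None  # defaults to 590 nm map

    def __post_init__(self) -> None:
        maps = [
            self.mu_a_ex,
            self.mu_s_ex,
            self.mu_a_em,
            self.mu_s_em,
            self.dox,
            self.height_mm,
            self.tumor_mask,
        ]
        shapes = {np.shape(m) for m in maps}
        if len(shapes) != 1:
            raise ValueError(f"all scene maps must share one shape, got {shapes}")
        if np.any(self.dox < 0):
            raise ValueError("dox map must be >= 0")
        if np.any((self.height_mm < 0) | (self.height_mm > 8.0)):
            raise ValueError("height map must lie in [0, 8] mm")
        if np.any(self.mu_s_ex <= 0) or np.any(self.mu_s_em <= 0):
            raise ValueError("scattering maps must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu_a_ex.shape

    def props(self, wavelength: float) -> tuple[np.ndarray, np.ndarray]:
        """(mu_a, mu_s') maps for the requested wavelength channel."""
        if np.isclose(wavelength, WAVELENGTH_EX):
            return self.mu_a_ex, self.mu_s_ex
        if np.isclose(wavelength, WAVELENGTH_EM):
            return self.mu_a_em, self.mu_s_em
        raise KeyError(f"scene has no optical properties at {wavelength} nm")

    @property
    def mu_a_treat(self) -> np.ndarray:
        return self.mu_a_treatment if self.mu_a_treatment is not None else self.mu_a_em


@dataclass(frozen=True)
class ReleaseModel:
    """First-order photo-triggered release kinetics.

    Local rate ``k = k0 * fluence_rate * exp(-attenuation_coupling * mu_a)``
    (fluence_rate converted to J s^-1 cm^-2), so higher background
    absorption at the treatment wavelength slows release.  Encapsulated
    drug fluoresces at ``1 - loaded_fraction_quenched`` of the free-drug
    brightness (self-quenching in the intact liposome).
    """

    k0: float = 0.032  # cm^2 / J
    fluence_rate: float = 350.0  # mW / cm^2
    treatment_wavelength: float = 657.0  # nm
    attenuation_coupling: float = 0.58  # per cm^-1 of mu_a
    loaded_fraction_quenched: float = 0.88

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.fluence_rate <= 0:
            raise ValueError("k0 and fluence_rate must be > 0")
        if not 0.0 <= self.loaded_fraction_quenched <= 1.0:
            raise ValueError("loaded_fraction_quenched must lie in [0, 1]")

    def rate_map(self, mu_a_treatment: np.ndarray) -> np.ndarray:
        """Per-pixel release rate, s^-1."""
        fluence_J = self.fluence_rate * 1e-3
        return self.k0 * fluence_J * np.exp(-self.attenuation_coupling * mu_a_treatment)


@dataclass
class FrameSet:
    """Raw frames indexed by (wavelength nm, frequency cm^-1, phase 0-2)."""

    frames: dict[tuple[float, float, int], np.ndarray]
    exposure_s: float
    dark: np.ndarray

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.frames.values()} | {self.dark.shape}
        if len(shapes) != 1:
            raise ValueError("all frames must share one shape")
        for (wl, f, _p) in self.frames:
            for p in range(3):
                if (wl, f, p) not in self.frames:
                    raise ValueError(f"incomplete phase set for ({wl} nm, {f} cm^-1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dark.shape

    def wavelengths(self) -> list[float]:
        return sorted({k[0] for k in self.frames})

    def frequencies(self, wavelength: float | None = None) -> list[float]:
        keys = self.frames if wavelength is None else [k for k in self.frames if k[0] == wavelength]
        return sorted({k[1] for k in keys})

    def phase_triplet(self, wavelength: float, f: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.frames[(wavelength, f, p)] for p in range(3))


@dataclass
class ReleaseSeries:
    """Fluorescence time series with ground truth released fractions."""

    times_s: np.ndarray
    frames: list[np.ndarray]
    released: list[np.ndarray]  # ground-truth fraction per pixel
    dark: np.ndarray
    scene: SceneSpec
    model: ReleaseModel


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def make_phantom_scene(
    mu_a_ex: float,
    mu_s_ex: float,
    mu_a_em: float,
    mu_s_em: float,
    dox_conc: float = 0.0,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    height_mm: float = 0.0,
    tumor: dict | None = None,
    **scene_kwargs,
) -> SceneSpec:
    """Homogeneous phantom scene, optionally with a circular inclusion.

    ``tumor`` may give ``{"center": (r, c), "radius": px, "mu_a_ex": ...,
    "mu_a_em": ..., "dox": ..., "height_mm": ...}``; unspecified inclusion
    values inherit the background.  Deterministic for a given seed (the
    seed is carried into the scene only through derived renders; the maps
    themselves are analytic).
    """
    if mu_s_ex <= 0 or mu_s_em <= 0:
        raise ValueError("scattering must be > 0")
    if dox_conc < 0:
        raise ValueError("dox_conc must be >= 0")
    full = lambda v: np.full(shape, float(v))
    maps = {
        "mu_a_ex": full(mu_a_ex),
        "mu_s_ex": full(mu_s_ex),
        "mu_a_em": full(mu_a_em),
        "mu_s_em": full(mu_s_em),
        "dox": full(dox_conc),
        "height_mm": full(height_mm),
    }
    mask = np.zeros(shape, dtype=bool)
    if tumor is not None:
        r0, c0 = tumor.get("center", (shape[0] / 2, shape[1] / 2))
        radius = tumor.get("radius", min(shape) / 5)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius**2
        for key in ("mu_a_ex", "mu_s_ex", "mu_a_em", "mu_s_em", "dox", "height_mm"):
            if key in tumor:
                maps[key] = maps[key].copy()
                maps[key][mask] = float(tumor[key])
    return SceneSpec(tumor_mask=mask, **maps, **scene_kwargs)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _x_coords_cm(scene: SceneSpec) -> np.ndarray:
    ncol = scene.shape[1]
    return (np.arange(ncol) + 0.5) * (scene.acquisition.fov_cm / ncol)


def _apply_camera(
    ideal: np.ndarray, scene: SceneSpec, rng: np.random.Generator | None
) -> np.ndarray:
    from .preprocess import apply_distortion

    img = ideal
    if scene.distortion != 0.0:
        img = apply_distortion(img, scene.distortion)
    img = img * scene.fiber.pattern(scene.shape)
    img = img + scene.dark_level
    if scene.noise.enabled:
        if rng is None:
            raise ValueError("noise enabled but no rng given; pass a seeded Generator")
        img = scene.noise.apply(img, rng)
    return img


def render_reflectance_frame(
    scene: SceneSpec,
    wavelength: float,
    f: float,
    phase_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One phase-shifted structured-illumination frame, in counts.

    ``I = gain * s(h)/2 * [R_d(0) + R_d(f_eff) cos(2 pi f_eff x + psi_k
    + kappa f h)] + dark + noise`` with ``f_eff = f (1 + h/d0)`` and
    ``s(h) = (1 + h/d0)^-2``.  ``f = 0`` renders unmodulated full-field
    illumination (``I = gain * s(h) * R_d(0)``), identical across the
    three phase indices.
    """
    if phase_index not in (0, 1, 2):
        raise ValueError("phase_index must be 0, 1 or 2")
    if f not in scene.acquisition.frequencies:
        raise ValueError(f"frequency {f} not in configured set {scene.acquisition.frequencies}")
    mu_a, mu_s = scene.props(wavelength)
    h = scene.height_mm
    stretch = 1.0 + h / scene.d0_mm
    scale = stretch**-2
    if f == 0.0:
        ideal = scene.gain * scale * rd_forward(mu_a, mu_s, 0.0)
    else:
        f_eff = f * stretch
        rd0 = rd_forward(mu_a, mu_s, 0.0)
        rdf = rd_forward(mu_a, mu_s, f_eff)
        x = _x_coords_cm(scene)[None, :]
        arg = 2.0 * np.pi * f_eff * x + PHASES[phase_index] + scene.kappa * f * h
        ideal = scene.gain * 0.5 * scale * (rd0 + rdf * np.cos(arg))
    return _apply_camera(ideal, scene, rng)


def scene_x1d_map(scene: SceneSpec) -> np.ndarray:
    """Ground-truth X_1D map of a scene (cached over unique pixels)."""
    stacked = np.stack([scene.mu_a_ex, scene.mu_s_ex, scene.mu_a_em, scene.mu_s_em])
    flat = stacked.reshape(4, -1)
    uniq, inverse = np.unique(flat.T, axis=0, return_inverse=True)
    vals = np.array(
        [x1d_factor((row[0], row[1]), (row[2], row[3])) for row in uniq]
    )
    return vals[inverse].reshape(scene.shape)


def render_fluorescence_frame(
    scene: SceneSpec,
    release_state: np.ndarray | float,
    model: ReleaseModel | None = None,
    rng: np.random.Generator | None = None,
    x1d_map: np.ndarray | None = None,
) -> np.ndarray:
    """Raw drug-fluorescence frame under full-field excitation.

    ``I = gain_f * dox * [rel + (1 - rel)(1 - q)] * X_1D(local) * s(h)
    + dark + noise`` where ``rel`` is the released fraction per pixel and
    ``q`` the encapsulated-quenching fraction of the release model.
    """
    model = model or ReleaseModel()
    rel = np.asarray(release_state, dtype=float)
    if np.any((rel < 0) | (rel > 1)):
        raise ValueError("release fractions must lie in [0, 1]")
    if x1d_map is None:
        x1d_map = scene_x1d_map(scene)
    q = model.loaded_fraction_quenched
    brightness = rel + (1.0 - rel) * (1.0 - q)
    scale = (1.0 + scene.height_mm / scene.d0_mm) ** -2
    ideal = scene.gain_f * scene.dox * brightness * x1d_map * scale
    return _apply_camera(ideal, scene, rng)


def render_frameset(
    scene: SceneSpec, rng: np.random.Generator | None = None
) -> FrameSet:
    """Full reflectance acquisition: all wavelengths, frequencies, phases."""
    acq = scene.acquisition
    frames = {}
    for wl in acq.wavelengths:
        for f in acq.frequencies:
            for p in range(3):
                frames[(wl, f, p)] = render_reflectance_frame(scene, wl, f, p, rng)
    dark = np.full(scene.shape, scene.dark_level)
    return FrameSet(frames=frames, exposure_s=acq.exposure_s, dark=dark)


# ---------------------------------------------------------------------------
# Release kinetics and calibration stacks
# ---------------------------------------------------------------------------

def simulate_release_series(
    scene: SceneSpec,
    model: ReleaseModel,
    duration_s: float,
    dt_s: float,
    seed: int = 0,
) -> ReleaseSeries:
    """Triggered-release fluorescence time series.

    Released fraction follows ``1 - exp(-k t)`` with the model's
    absorption-coupled local rate.  Frames at t = 0, dt, 2dt, ...
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be > 0")
    if dt_s > duration_s:
        raise ValueError("dt must not exceed duration")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    k = model.rate_map(scene.mu_a_treat)
    x1d = scene_x1d_map(scene)
    frames, released = [], []
    for t in times:
        rel = 1.0 - np.exp(-k * t)
        released.append(rel)
        frames.append(
            render_fluorescence_frame(scene, rel, model, rng if scene.noise.enabled else None, x1d)
        )
    dark = np.full(scene.shape, scene.dark_level)
    return ReleaseSeries(times, frames, released, dark, scene, model)


def simulate_calibration_stacks(
    reference_ops: dict[float, OpticalProperties],
    heights_mm,
    acquisition: AcquisitionSpec | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    noise: NoiseModel | None = None,
    **scene_kwargs,
) -> dict[float, FrameSet]:
    """Flat reference phantom imaged from each height below the frame.

    ``reference_ops`` maps wavelength (nm) to the phantom's known
    properties.  Returns ``{height_mm: FrameSet}`` with the
    height-dependent frequency, amplitude, and phase effects applied.
    """
    heights = list(heights_mm)
    if not heights:
        raise ValueError("heights list must not be empty")
    if any(h < 0 or h > 8.0 for h in heights):
        raise ValueError("heights must lie within [0, 8] mm")
    acquisition = acquisition or AcquisitionSpec()
    noise = noise or NoiseModel(0.0, 0.0, 0.0)
    op_ex = reference_ops[WAVELENGTH_EX]
    op_em = reference_ops[WAVELENGTH_EM]
    rng = np.random.default_rng(seed)
    out = {}
    for h in heights:
        scene = make_phantom_scene(
            op_ex.mu_a,
            op_ex.mu_s_prime,
            op_em.mu_a,
            op_em.mu_s_prime,
            shape=shape,
            height_mm=h,
            noise=noise,
            acquisition=acquisition,
            **scene_kwargs,
        )
        out[h] = render_frameset(scene, rng if noise.enabled else None)
    return out
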