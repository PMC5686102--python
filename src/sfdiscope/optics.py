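"""Forward optics of a homogeneous semi-infinite turbid medium.

This module holds the physics the rest of the package inverts:

* :func:`sfd_reflectance` — spatial-frequency-domain diffuse reflectance
  ``R_d(f)`` in the diffusion approximation with a partial-current
  (Robin) boundary condition.  This is the forward model used both to
  calibrate measured modulation amplitudes against a reference phantom
  and to fit per-pixel absorption/scattering maps.
* :func:`x1d_factor` — the one-dimensional attenuation-correction factor
  ``X_1D(lambda_ex, lambda_em)`` that couples penetration of excitation
  light with escape of emitted fluorescence.  Dividing a raw
  fluorescence image by ``X_1D`` yields a signal proportional to
  fluorophore concentration regardless of the background absorption and
  scattering.
* :func:`correct_fluorescence` — that division.

Units are fixed package-wide: optical coefficients and spatial
frequencies in cm^-1, wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalProperties",
    "REFRACTIVE_INDEX",
    "sfd_reflectance",
    "rd_diffusion",
    "x1d_factor",
    "correct_fluorescence",
]

#: Tissue refractive index assumed throughout (soft-tissue standard).
REFRACTIVE_INDEX = 1.4


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a medium at one wavelength.

    Parameters
    ----------
    mu_a:
        Absorption coefficient, cm^-1.  Must be >= 0.
    mu_s_prime:
        Reduced scattering coefficient mu_s' = mu_s (1 - g), cm^-1.
        Must be > 0.
    wavelength:
        Wavelength in nm, > 0.  Carried for bookkeeping (excitation vs
        emission channels); the forward model itself is monochromatic.
    """

    mu_a: float
    mu_s_prime: float
    wavelength: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise ValueError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )
        if not np.isfinite(self.wavelength) or self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0 nm, got {self.wavelength}")


def _effective_reflection_coefficient(n: float) -> float:
    # Groenhuis/Egan-Hilgeman polynomial fit for the internal diffuse
    # reflection at a tissue/air boundary with relative index n.
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def _boundary_A(n: float) -> float:
    r_eff = _effective_reflection_coefficient(n)
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def rd_diffusion(mu_a, mu_s_prime, f, n: float = REFRACTIVE_INDEX):
    """Diffuse reflectance R_d(f), vectorized over arrays.

    Diffusion approximation for a spatially modulated planar source on a
    semi-infinite homogeneous medium::

        mu_tr     = mu_a + mu_s'
        a'        = mu_s' / mu_tr
        mu_eff    = sqrt(3 mu_a mu_tr)
        mu_eff'   = sqrt(mu_eff^2 + (2 pi f)^2)
        R_d(f)    = 3 A a' / [(mu_eff'/mu_tr + 1)(mu_eff'/mu_tr + 3A)]

    with ``A`` the proportionality constant of the partial-current
    boundary condition for refractive index ``n``.

    Parameters broadcast against each other; scalars return a float.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(mu_a)) or np.any(mu_a < 0):
        raise ValueError("mu_a must be finite and >= 0")
    if np.any(~np.isfinite(mu_s_prime)) or np.any(mu_s_prime <= 0):
        raise ValueError("mu_s_prime must be finite and > 0")
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise ValueError("spatial frequency must be finite and >= 0")

    mu_tr = mu_a + mu_s_prime
    a_prime = mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr)
    mu_eff_p = np.sqrt(mu_eff**2 + (2.0 * np.pi * f) ** 2)
    A = _boundary_A(n)
    x = mu_eff_p / mu_tr
    rd = 3.0 * A * a_prime / ((x + 1.0) * (x + 3.0 * A))
    if rd.ndim == 0:
        return float(rd)
    return rd


# ---------------------------------------------------------------------------
# Monte Carlo-corrected forward model
# ---------------------------------------------------------------------------
#
# R_d of a semi-infinite medium obeys an exact similarity scaling: it is a
# function of the transport albedo a' = mu_s'/mu_tr and the reduced
# frequency v = f/mu_tr alone (fixed g, n).  The shipped table
# data/rd_mc_table.json holds C(a', v) = R_MC/R_diffusion computed by the
# in-repo Monte Carlo (scripts/build_forward_table.py); multiplying the
# diffusion expression by C keeps the forward model transport-accurate at
# low albedo and high frequency, where plain diffusion is 15-30% high.

_MC_TABLE_CACHE: dict = {}


def _mc_correction_interp():
    if "interp" in _MC_TABLE_CACHE:
        return _MC_TABLE_CACHE["interp"]
    import json
    from importlib import resources

    from scipy.interpolate import RegularGridInterpolator

    try:
        with resources.files("sfdiscope").joinpath("data/rd_mc_table.json").open() as fh:
            raw = json.load(fh)
    except FileNotFoundError:
        _MC_TABLE_CACHE["interp"] = None
        return None
    a_nodes = np.asarray(raw["albedo_nodes"], float)
    v_nodes = np.asarray(raw["v_nodes"], float)
    table = np.asarray(raw["correction"], float)
    interp = RegularGridInterpolator((a_nodes, v_nodes), table, method="linear")
    _MC_TABLE_CACHE["interp"] = (interp, a_nodes, v_nodes)
    return _MC_TABLE_CACHE["interp"]


def has_mc_correction() -> bool:
    """True when the Monte Carlo correction table shipped and loaded."""
    return _mc_correction_interp() is not None


def mc_correction_factor(mu_a, mu_s_prime, f):
    """Interpolated C(a', v) = R_MC/R_diffusion; 1.0 without a table.

    Queries outside the tabulated (albedo, reduced-frequency) hull are
    clamped to the nearest edge -- the table spans the whole fitting
    range, so clamping only touches pathological optimizer iterates.
    """
    got = _mc_correction_interp()
    if got is None:
        return np.ones(np.broadcast(mu_a, mu_s_prime, f).shape) if np.ndim(mu_a) or np.ndim(f) else 1.0
    interp, a_nodes, v_nodes = got
    mu_a = np.asarray(mu_a, float)
    mu_s_prime = np.asarray(mu_s_prime, float)
    f = np.asarray(f, float)
    mu_tr = mu_a + mu_s_prime
    a_p = np.clip(mu_s_prime / mu_tr, a_nodes[0], a_nodes[-1])
    v = np.clip(f / mu_tr, v_nodes[0], v_nodes[-1])
    a_p, v = np.broadcast_arrays(a_p, v)
    out = interp(np.stack([a_p.ravel(), v.ravel()], axis=-1)).reshape(a_p.shape)
    if out.ndim == 0:
        return float(out)
    return out


def rd_forward(mu_a, mu_s_prime, f, n: float = REFRACTIVE_INDEX):
    """Forward model R_d(f): diffusion expression x MC correction."""
    return rd_diffusion(mu_a, mu_s_prime, f, n) * mc_correction_factor(
        mu_a, mu_s_prime, f
    )


def sfd_reflectance(op: OpticalProperties, f) -> float:
    """Model diffuse reflectance R_d(f) for one medium.

    Monte Carlo-corrected forward model (see :func:`rd_forward`); ``f``
    may be a scalar or array of spatial frequencies (cm^-1, >= 0).
    """
    return rd_forward(op.mu_a, op.mu_s_prime, f)


# ---------------------------------------------------------------------------
# X_1D attenuation-correction factor
# ---------------------------------------------------------------------------

def _planar_fluence_terms(mu_a, mu_s_prime, n: float):
    """Coefficients of the planar-illumination diffusion fluence.

    A collimated planar beam of unit irradiance is represented as an
    isotropic plane source of strength a' buried at one transport mean
    free path z0 = 1/mu_tr, with an image sink across the extrapolated
    boundary at z = -2 zb.  The fluence at depth z >= 0 is::

        phi(z) = amp * [exp(-mu_eff |z - z0|) - exp(-mu_eff (z + z0 + 2 zb))]

    with ``amp = a' / (2 D mu_eff)`` and ``zb = D / A``.
    Returns (amp, mu_eff, z0, zb) broadcast over the inputs.
    """
    mu_tr = mu_a + mu_s_prime
    a_prime = mu_s_prime / mu_tr
    D = 1.0 / (3.0 * mu_tr)
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr)
    A = _boundary_A(n)
    zb = D / A
    z0 = 1.0 / mu_tr
    amp = a_prime / (2.0 * D * mu_eff)
    return amp, mu_eff, z0, zb


def _planar_fluence(z, mu_a, mu_s_prime, n: float):
    amp, mu_eff, z0, zb = _planar_fluence_terms(mu_a, mu_s_prime, n)
    return amp * (
        np.exp(-mu_eff * np.abs(z - z0)) - np.exp(-mu_eff * (z + z0 + 2.0 * zb))
    )


def x1d_factor(
    op_ex: OpticalProperties | tuple,
    op_em: OpticalProperties | tuple,
    n: float = REFRACTIVE_INDEX,
    n_depth: int = 600,
) -> float:
    """Attenuation-correction factor X_1D(lambda_ex, lambda_em).

    One-dimensional coupling of excitation penetration and emission
    escape: the depth integral of the planar-illumination fluence
    ``phi_ex(z)`` at the excitation properties times the escape profile
    at the emission properties.  By optical reciprocity the escape
    profile of an isotropic emitter at depth z shares the functional
    form of the planar fluence, so

        X_1D = integral_0^inf  phi_ex(z) * phi_em(z) dz

    up to a fixed normalization that cancels in every use (the factor
    only ever divides a signal that was calibrated in the same
    convention).  Strictly decreasing in mu_a at either wavelength.

    Parameters accept :class:`OpticalProperties` or ``(mu_a, mu_s')``
    tuples/arrays (broadcastable), enabling per-pixel maps.

    Raises
    ------
    ValueError
        If either scattering coefficient is zero/negative (model
        undefined) or absorption is negative.
    """
    mu_a_x, mu_s_x = _as_mu_pair(op_ex)
    mu_a_m, mu_s_m = _as_mu_pair(op_em)
    for mu_a, mu_s in ((mu_a_x, mu_s_x), (mu_a_m, mu_s_m)):
        if np.any(~np.isfinite(mu_a)) or np.any(mu_a < 0):
            raise ValueError("mu_a must be finite and >= 0")
        if np.any(~np.isfinite(mu_s)) or np.any(mu_s <= 0):
            raise ValueError("mu_s_prime must be finite and > 0 (model undefined)")

    # Depth grid spanning both media's penetration scales.  mu_eff can be
    # 0 when mu_a = 0; fall back to the transport length scale then.
    mu_eff_x = np.sqrt(3.0 * mu_a_x * (mu_a_x + mu_s_x))
    mu_eff_m = np.sqrt(3.0 * mu_a_m * (mu_a_m + mu_s_m))
    scale = np.minimum(
        np.where(mu_eff_x > 0, mu_eff_x, mu_a_x + mu_s_x),
        np.where(mu_eff_m > 0, mu_eff_m, mu_a_m + mu_s_m),
    )
    z_max = 12.0 / float(np.min(scale))
    # Dense near the surface where the kink at z0 lives, coarser at depth.
    z = np.concatenate(
        [
            np.linspace(0.0, 0.2 * z_max, int(0.7 * n_depth), endpoint=False),
            np.linspace(0.2 * z_max, z_max, n_depth - int(0.7 * n_depth)),
        ]
    )
    shape_extra = (1,) * np.ndim(mu_a_x)
    zg = z.reshape((-1,) + shape_extra)
    phi_x = _planar_fluence(zg, mu_a_x, mu_s_x, n)
    phi_m = _planar_fluence(zg, mu_a_m, mu_s_m, n)
    out = np.trapezoid(phi_x * phi_m, z, axis=0)
    if out.ndim == 0:
        return float(out)
    return out


def _as_mu_pair(op):
    if isinstance(op, OpticalProperties):
        return np.asarray(op.mu_a, float), np.asarray(op.mu_s_prime, float)
    mu_a, mu_s = op
    return np.asarray(mu_a, dtype=float), np.asarray(mu_s, dtype=float)


def correct_fluorescence(f_raw, x1d):
    """Attenuation-corrected fluorescence ``F_corr = F_raw / X_1D``.

    Elementwise over images; ``x1d`` may be a scalar or a map of the
    same shape.  Raises ``ValueError`` for non-positive ``x1d`` or
    negative raw signal.
    """
    f_raw = np.asarray(f_raw, dtype=float)
    x1d_arr = np.asarray(x1d, dtype=float)
    if np.any(f_raw < 0):
        raise ValueError("raw fluorescence must be >= 0")
    if np.any(~np.isfinite(x1d_arr)) or np.any(x1d_arr <= 0):
        raise ValueError("x1d must be finite and > 0")
    out = f_raw / x1d_arr
    if out.ndim == 0:
        return float(out)
    return out
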