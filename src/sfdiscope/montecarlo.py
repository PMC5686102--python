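"""Monte Carlo photon transport in a semi-infinite turbid medium.

Independent verification oracle for the diffusion forward model and the
X_1D correction factor.  Photons perform an MCML-style weighted random
walk (Henyey-Greenstein scattering, implicit absorption, Russian
roulette, Fresnel partial reflection at the surface).  The
spatial-frequency-domain reflectance is obtained from the spatially
resolved exit weights via the zero-order transform

    R_d(f) = E[ w_exit * J0(2 pi f rho_exit) ]

which reduces to total diffuse reflectance at f = 0.

These estimators are deliberately simple and slow relative to the
analytic model; they exist to guard its accuracy, not to be the
per-pixel inversion path.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .optics import REFRACTIVE_INDEX, OpticalProperties

__all__ = ["mc_sfd_reflectance", "mc_fluorescence_yield", "MCEstimate"]

#: Henyey-Greenstein anisotropy assumed for tissue-like media.
DEFAULT_G = 0.9

_W_ROULETTE = 1e-4
_P_SURVIVE = 0.1


@njit(cache=True)
def _j0(x):
    # Abramowitz & Stegun 9.4.1 / 9.4.3 rational approximations (|err| < 1e-7).
    ax = abs(x)
    if ax <= 3.0:
        t = (ax / 3.0) ** 2
        return (
            1.0
            + t
            * (
                -2.2499997
                + t
                * (
                    1.2656208
                    + t
                    * (-0.3163866 + t * (0.0444479 + t * (-0.0039444 + t * 0.0002100)))
                )
            )
        )
    t = 3.0 / ax
    f0 = (
        0.79788456
        + t
        * (
            -0.00000077
            + t
            * (
                -0.00552740
                + t
                * (-0.00009512 + t * (0.00137237 + t * (-0.00072805 + t * 0.00014476)))
            )
        )
    )
    th = (
        ax
        - 0.78539816
        + t
        * (
            -0.04166397
            + t
            * (
                -0.00003954
                + t
                * (0.00262573 + t * (-0.00054125 + t * (-0.00029333 + t * 0.00013558)))
            )
        )
    )
    return f0 * math.cos(th) / math.sqrt(ax)


@njit(cache=True)
def _fresnel_internal(cos_i, n_rel):
    """Unpolarized Fresnel reflectance, incidence from inside (n_rel = n_in/n_out)."""
    if n_rel == 1.0:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _scatter(ux, uy, uz, g):
    if g == 0.0:
        cost = 2.0 * np.random.random() - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
        cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
    sint = math.sqrt(1.0 - cost * cost)
    phi = 2.0 * math.pi * np.random.random()
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = sint * cosp
        nuy = sint * sinp
        nuz = cost if uz >= 0.0 else -cost
    else:
        den = math.sqrt(1.0 - uz * uz)
        nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nuz = -sint * cosp * den + uz * cost
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _walk_reflectance(mu_a, mu_s, g, n_rel, two_pi_f, n_photons, seed, max_depth):
    """Pencil-beam walk; per-photon J0-weighted exit contribution moments."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    sum_c = 0.0
    sum_c2 = 0.0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        c = 0.0
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300) / mu_t
            zn = z + uz * s
            if zn < 0.0:
                s1 = -z / uz
                x += ux * s1
                y += uy * s1
                z = 0.0
                r = _fresnel_internal(-uz, n_rel)
                rho = math.sqrt(x * x + y * y)
                c += w * (1.0 - r) * _j0(two_pi_f * rho)
                w *= r
                if w <= 0.0:
                    break
                uz = -uz
                srem = s - s1
                x += ux * srem
                y += uy * srem
                z += uz * srem
            else:
                x += ux * s
                y += uy * s
                z = zn
            if z > max_depth:
                break
            w *= albedo
            if w < _W_ROULETTE:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    break
            ux, uy, uz = _scatter(ux, uy, uz, g)
        sum_c += c
        sum_c2 += c * c
    return sum_c, sum_c2


@njit(cache=True)
def _walk_reflectance_multi(mu_a, mu_s, g, n_rel, two_pi_fs, n_photons, seed, max_depth):
    """Shared-walk estimate of R_d at several spatial frequencies at once."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    nf = two_pi_fs.shape[0]
    sum_c = np.zeros(nf)
    sum_c2 = np.zeros(nf)
    c = np.zeros(nf)
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        for k in range(nf):
            c[k] = 0.0
        while True:
            s = -math.log(np.random.random() + 1e-300) / mu_t
            zn = z + uz * s
            if zn < 0.0:
                s1 = -z / uz
                x += ux * s1
                y += uy * s1
                z = 0.0
                r = _fresnel_internal(-uz, n_rel)
                rho = math.sqrt(x * x + y * y)
                wesc = w * (1.0 - r)
                for k in range(nf):
                    c[k] += wesc * _j0(two_pi_fs[k] * rho)
                w *= r
                if w <= 0.0:
                    break
                uz = -uz
                srem = s - s1
                x += ux * srem
                y += uy * srem
                z += uz * srem
            else:
                x += ux * s
                y += uy * s
                z = zn
            if z > max_depth:
                break
            w *= albedo
            if w < _W_ROULETTE:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    break
            ux, uy, uz = _scatter(ux, uy, uz, g)
        for k in range(nf):
            sum_c[k] += c[k]
            sum_c2[k] += c[k] * c[k]
    return sum_c, sum_c2


def mc_sfd_reflectance_multi(
    op: OpticalProperties,
    freqs,
    n_photons: int = 100_000,
    seed: int = 0,
    g: float = DEFAULT_G,
    n: float = REFRACTIVE_INDEX,
    max_depth: float | None = None,
):
    """Vector of R_d(f) estimates sharing one photon ensemble.

    Returns ``(values, stderrs)`` arrays matching ``freqs``.  Estimates
    at different frequencies are correlated (same walks), which is
    exactly what a frequency-response table wants.
    """
    if n_photons < 10_000:
        raise ValueError("n_photons must be >= 10^4")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(~np.isfinite(freqs)):
        raise ValueError("spatial frequencies must be finite and >= 0")
    mu_s = op.mu_s_prime / (1.0 - g)
    mu_tr = op.mu_a + op.mu_s_prime
    if max_depth is None:
        max_depth = _depth_cutoff(op.mu_a, mu_tr)
    sum_c, sum_c2 = _walk_reflectance_multi(
        op.mu_a, mu_s, g, n, 2.0 * math.pi * freqs, int(n_photons), int(seed), max_depth
    )
    mean = sum_c / n_photons
    var = np.maximum(sum_c2 / n_photons - mean**2, 0.0) / n_photons
    return mean, np.sqrt(var)


@njit(cache=True)
def _walk_deposition(mu_a, mu_s, g, n_rel, n_photons, seed, z_max, hist):
    """Excitation walk depositing absorbed weight into a depth histogram."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    nbins = hist.shape[0]
    dz = z_max / nbins
    total = 0.0
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        while True:
            s = -math.log(np.random.random() + 1e-300) / mu_t
            zn = z + uz * s
            if zn < 0.0:
                s1 = -z / uz
                x += ux * s1
                y += uy * s1
                z = 0.0
                r = _fresnel_internal(-uz, n_rel)
                w *= r
                if w <= 0.0:
                    break
                uz = -uz
                srem = s - s1
                x += ux * srem
                y += uy * srem
                z += uz * srem
            else:
                x += ux * s
                y += uy * s
                z = zn
            if z > z_max:
                break
            dw = w * (mu_a / mu_t)
            ib = int(z / dz)
            if ib >= nbins:
                ib = nbins - 1
            hist[ib] += dw
            total += dw
            w -= dw
            if w < _W_ROULETTE:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    break
            ux, uy, uz = _scatter(ux, uy, uz, g)
    return total


@njit(cache=True)
def _walk_escape_from_depths(z0s, mu_a, mu_s, g, n_rel, seed, max_depth):
    """Isotropic emitters at given depths; returns total escaped weight."""
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    escaped = 0.0
    for i in range(z0s.shape[0]):
        x = 0.0
        y = 0.0
        z = z0s[i]
        cost = 2.0 * np.random.random() - 1.0
        sint = math.sqrt(1.0 - cost * cost)
        phi = 2.0 * math.pi * np.random.random()
        ux = sint * math.cos(phi)
        uy = sint * math.sin(phi)
        uz = cost
        w = 1.0
        while True:
            s = -math.log(np.random.random() + 1e-300) / mu_t
            zn = z + uz * s
            if uz < 0.0 and zn < 0.0:
                s1 = -z / uz
                x += ux * s1
                y += uy * s1
                z = 0.0
                r = _fresnel_internal(-uz, n_rel)
                escaped += w * (1.0 - r)
                w *= r
                if w <= 0.0:
                    break
                uz = -uz
                srem = s - s1
                x += ux * srem
                y += uy * srem
                z += uz * srem
            else:
                x += ux * s
                y += uy * s
                z = zn
            if z > max_depth:
                break
            w *= albedo
            if w < _W_ROULETTE:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    break
            ux, uy, uz = _scatter(ux, uy, uz, g)
    return escaped


class MCEstimate(float):
    """A float estimate carrying its Monte Carlo standard error."""

    stderr: float

    def __new__(cls, value: float, stderr: float):
        obj = super().__new__(cls, value)
        obj.stderr = float(stderr)
        return obj

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MCEstimate({float(self):.6g} +- {self.stderr:.2g})"


def _depth_cutoff(mu_a: float, mu_tr: float) -> float:
    if mu_a > 0:
        return 15.0 / math.sqrt(3.0 * mu_a * mu_tr)
    # Non-absorbing medium: the walk is transient, truncate deep enough
    # that the leaked fraction (~ z0 / cutoff) is far below typical SE.
    return 5000.0 / mu_tr


def mc_sfd_reflectance(
    op: OpticalProperties,
    f: float,
    n_photons: int = 100_000,
    seed: int = 0,
    g: float = DEFAULT_G,
    n: float = REFRACTIVE_INDEX,
    max_depth: float | None = None,
) -> MCEstimate:
    """Monte Carlo estimate of R_d(f) with standard error.

    Parameters
    ----------
    op:
        Medium optical properties (mu_s = mu_s' / (1 - g) internally).
    f:
        Spatial frequency, cm^-1.
    n_photons:
        Photon count, >= 10^4 (below that the standard error of the
        J0-weighted estimator is not reliably finite).
    seed:
        Seed for the (numba) RNG; same seed + inputs => identical output.
    g, n:
        Scattering anisotropy and relative refractive index; ``n = 1``
        gives an index-matched boundary.
    max_depth:
        Kill depth in cm.  Defaults to 15 diffusion penetration depths
        (or 5000 transport lengths when mu_a = 0).
    """
    if n_photons < 10_000:
        raise ValueError("n_photons must be >= 10^4 for a finite standard error")
    if f < 0 or not np.isfinite(f):
        raise ValueError("spatial frequency must be finite and >= 0")
    if not (0.0 <= g < 1.0):
        raise ValueError("anisotropy g must be in [0, 1)")
    mu_s = op.mu_s_prime / (1.0 - g)
    mu_tr = op.mu_a + op.mu_s_prime
    if max_depth is None:
        max_depth = _depth_cutoff(op.mu_a, mu_tr)
    sum_c, sum_c2 = _walk_reflectance(
        op.mu_a, mu_s, g, n, 2.0 * math.pi * f, int(n_photons), int(seed), max_depth
    )
    mean = sum_c / n_photons
    var = max(sum_c2 / n_photons - mean * mean, 0.0) / n_photons
    return MCEstimate(mean, math.sqrt(var))


def mc_fluorescence_yield(
    op_ex: OpticalProperties,
    op_em: OpticalProperties,
    n_photons: int = 100_000,
    seed: int = 0,
    g: float = DEFAULT_G,
    n: float = REFRACTIVE_INDEX,
) -> MCEstimate:
    """Detected fluorescence per unit fluorophore, by two-stage MC.

    Stage 1 simulates the excitation walk and records absorbed energy
    versus depth; in a homogeneous medium the deposition profile is
    proportional to the excitation fluence, so emission origins sampled
    from it are distributed per fluence.  Stage 2 launches isotropic
    emission photons from those depths in the emission-wavelength medium
    and scores the escaping weight.  The yield is

        (total fluence integral) * (escape probability per emitted photon)

    which is the Monte Carlo analogue of X_1D up to a fixed constant, so
    ratios between media are directly comparable to x1d_factor ratios.
    """
    if n_photons < 10_000:
        raise ValueError("n_photons must be >= 10^4")
    if op_ex.mu_a <= 0:
        raise ValueError("excitation mu_a must be > 0 to sample emission origins")
    mu_s_x = op_ex.mu_s_prime / (1.0 - g)
    mu_s_m = op_em.mu_s_prime / (1.0 - g)
    mu_tr_x = op_ex.mu_a + op_ex.mu_s_prime
    z_max = _depth_cutoff(op_ex.mu_a, mu_tr_x)
    nbins = 4096
    hist = np.zeros(nbins)
    total_absorbed = _walk_deposition(
        op_ex.mu_a, mu_s_x, g, n, int(n_photons), int(seed), z_max, hist
    )
    total_absorbed /= n_photons
    # Fluence integral: absorbed = mu_a * integral(phi) per unit area.
    fluence_integral = total_absorbed / op_ex.mu_a
    rng = np.random.default_rng(seed + 1)
    p = hist / hist.sum()
    dz = z_max / nbins
    idx = rng.choice(nbins, size=n_photons, p=p)
    z0s = (idx + rng.random(n_photons)) * dz
    mu_tr_m = op_em.mu_a + op_em.mu_s_prime
    max_depth_m = _depth_cutoff(op_em.mu_a, mu_tr_m) + z_max
    escaped = _walk_escape_from_depths(
        z0s, op_em.mu_a, mu_s_m, g, n, int(seed) + 2, max_depth_m
    )
    p_escape = escaped / n_photons
    value = fluence_integral * p_escape
    # Dominant uncertainty: binomial-ish spread of the escape stage.
    se = fluence_integral * math.sqrt(max(p_escape * (1 - p_escape), 0.0) / n_photons)
    return MCEstimate(value, se)
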