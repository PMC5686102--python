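"""Per-pixel recovery of absorption and reduced scattering from R_d(f).

The inverse problem minimizes, pixelwise,

    sum_f [ r_d(f) - R_model(mu_a, mu_s', f) ]^2

over (mu_a, mu_s') with the Monte Carlo-corrected diffusion forward
model.  Two independent starting points guard against local minima;
pixels where the two solutions disagree by more than 5% are flagged.
A lookup-table path offers the same answers faster for large maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ReflectanceMaps
from .optics import rd_forward, x1d_factor

__all__ = [
    "OpticalPropertyMaps",
    "FIT_BOUNDS",
    "INITIAL_CONDITIONS",
    "fit_optical_properties",
    "build_lut",
    "LookupTable",
    "build_correction_map",
]

#: Fit bounds, cm^-1: mu_a in [0.01, 10], mu_s' in [1, 50].
FIT_BOUNDS = ((0.01, 10.0), (1.0, 50.0))

#: The two starting conditions (mu_a, mu_s') used to detect local minima.
INITIAL_CONDITIONS = ((0.5, 10.0), (2.0, 25.0))


@dataclass
class OpticalPropertyMaps:
    """Fitted mu_a / mu_s' maps with diagnostics."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    wavelength: float
    residual_norm: np.ndarray
    valid: np.ndarray
    start_disagreement: np.ndarray = field(default=None)  # relative, max over params

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)


def _as_freq_stack(r_d) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(r_d, ReflectanceMaps):
        return r_d.stack()
    fs = np.array(sorted(r_d))
    return fs, np.stack([np.asarray(r_d[f], dtype=float) for f in fs])


def _gauss_newton(
    obs: np.ndarray, freqs: np.ndarray, start: tuple[float, float], forward,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton in log-parameter space, batched over pixels.

    ``obs`` is (n_px, n_f).  Returns (params (n_px, 2), cost (n_px,)).
    Log parameters keep the iterates positive; bounds are enforced by
    clipping at every step (active only for pathological pixels).
    """
    n_px, n_f = obs.shape
    lo = np.log([FIT_BOUNDS[0][0], FIT_BOUNDS[1][0]])
    hi = np.log([FIT_BOUNDS[0][1], FIT_BOUNDS[1][1]])
    theta = np.tile(np.log(np.asarray(start)), (n_px, 1))

    def model(th):
        mu = np.exp(th)
        return forward(mu[:, 0:1], mu[:, 1:2], freqs[None, :])

    def cost(th):
        return ((model(th) - obs) ** 2).sum(axis=1)

    c = cost(theta)
    eps = 1e-6
    lam = np.full(n_px, 1e-6)
    for _ in range(n_iter):
        r = model(theta) - obs  # (n_px, n_f)
        J = np.empty((n_px, n_f, 2))
        for j in range(2):
            tp = theta.copy()
            tp[:, j] += eps
            J[:, :, j] = (model(tp) - model(theta)) / eps
        JtJ = np.einsum("pfi,pfj->pij", J, J)
        Jtr = np.einsum("pfi,pf->pi", J, r)
        A = JtJ + lam[:, None, None] * np.eye(2)[None]
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.empty_like(theta)
        step[:, 0] = (A[:, 1, 1] * Jtr[:, 0] - A[:, 0, 1] * Jtr[:, 1]) / det
        step[:, 1] = (A[:, 0, 0] * Jtr[:, 1] - A[:, 1, 0] * Jtr[:, 0]) / det
        cand = np.clip(theta - step, lo, hi)
        c_new = cost(cand)
        better = c_new < c
        theta[better] = cand[better]
        c = np.where(better, c_new, c)
        lam = np.where(better, np.maximum(lam * 0.3, 1e-9), np.minimum(lam * 8.0, 1e4))
        if np.all(c < 1e-24):
            break
    return np.exp(theta), c


def fit_optical_properties(
    r_d,
    wavelength: float = 0.0,
    forward=rd_forward,
    starts=INITIAL_CONDITIONS,
    disagreement_tol: float = 0.05,
    mask: np.ndarray | None = None,
) -> OpticalPropertyMaps:
    """Nonlinear least-squares (mu_a, mu_s') maps from reflectance maps.

    ``r_d`` is a :class:`~sfdiscope.calibration.ReflectanceMaps` or a
    ``{f: image}`` dict with at least two distinct frequencies.  The fit
    runs from each starting condition in ``starts``; the per-pixel
    solution is the lower-cost one and pixels where the two solutions
    differ by more than ``disagreement_tol`` (relative, either
    parameter) are flagged invalid.
    """
    freqs, stack = _as_freq_stack(r_d)
    if len(freqs) < 2:
        raise ValueError("need at least 2 distinct frequencies to fit 2 unknowns")
    if isinstance(r_d, ReflectanceMaps):
        wavelength = wavelength or r_d.wavelength
    shape = stack.shape[1:]
    obs = stack.reshape(len(freqs), -1).T  # (n_px, n_f)
    finite = np.isfinite(obs).all(axis=1)
    if mask is not None:
        finite &= np.asarray(mask, bool).ravel()
    obs_fit = obs[finite]
    solutions, costs = [], []
    for start in starts:
        p, c = _gauss_newton(obs_fit, freqs, start, forward)
        solutions.append(p)
        costs.append(c)
    solutions = np.stack(solutions)  # (n_start, n_px, 2)
    costs = np.stack(costs)
    best = costs.argmin(axis=0)
    pick = solutions[best, np.arange(best.size)]
    cost_best = costs[best, np.arange(best.size)]
    if len(starts) >= 2:
        rel = np.abs(solutions[0] - solutions[1]) / np.maximum(
            np.minimum(solutions[0], solutions[1]), 1e-12
        )
        disagree = rel.max(axis=1)
    else:
        disagree = np.zeros(len(obs_fit))

    def unflatten(vals, fill=np.nan):
        out = np.full(obs.shape[0], fill)
        out[finite] = vals
        return out.reshape(shape)

    mu_a = unflatten(pick[:, 0])
    mu_s = unflatten(pick[:, 1])
    resid = unflatten(np.sqrt(cost_best))
    dis = unflatten(disagree, fill=np.inf)
    valid = finite.reshape(shape) & (dis <= disagreement_tol)
    return OpticalPropertyMaps(
        mu_a=mu_a,
        mu_s_prime=mu_s,
        wavelength=wavelength,
        residual_norm=resid,
        valid=valid,
        start_disagreement=dis,
    )


@dataclass
class LookupTable:
    """Forward-model table over a (mu_a, mu_s') grid for fast inversion."""

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    frequencies: np.ndarray
    table: np.ndarray  # (n_a, n_s, n_f)
    forward: object = rd_forward

    def invert(self, r_d, wavelength: float = 0.0, refine_iters: int = 3) -> OpticalPropertyMaps:
        """Nearest-node search plus local Gauss-Newton polish.

        Queries whose best node sits on the grid boundary (or whose
        refined solution leaves the grid hull) are flagged invalid
        rather than extrapolated.
        """
        freqs, stack = _as_freq_stack(r_d)
        if isinstance(r_d, ReflectanceMaps):
            wavelength = wavelength or r_d.wavelength
        if len(freqs) != len(self.frequencies) or not np.allclose(freqs, self.frequencies):
            raise ValueError("query frequencies do not match the table")
        shape = stack.shape[1:]
        obs = stack.reshape(len(freqs), -1).T
        finite = np.isfinite(obs).all(axis=1)
        nodes = self.table.reshape(-1, len(freqs))  # (n_a*n_s, n_f)
        n_px = obs.shape[0]
        idx = np.empty(n_px, dtype=int)
        chunk = 4096
        for i0 in range(0, n_px, chunk):
            sub = obs[i0 : i0 + chunk]
            d2 = ((sub[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
            idx[i0 : i0 + chunk] = d2.argmin(axis=1)
        ia, is_ = np.unravel_index(idx, self.table.shape[:2])
        on_edge = (
            (ia == 0)
            | (ia == len(self.mu_a_grid) - 1)
            | (is_ == 0)
            | (is_ == len(self.mu_s_grid) - 1)
        )
        start = np.column_stack([self.mu_a_grid[ia], self.mu_s_grid[is_]])
        theta = np.log(start)
        for _ in range(refine_iters):
            mu = np.exp(theta)
            pred = self.forward(mu[:, 0:1], mu[:, 1:2], freqs[None, :])
            r = pred - obs
            J = np.empty((n_px, len(freqs), 2))
            eps = 1e-6
            for j in range(2):
                tp = theta.copy()
                tp[:, j] += eps
                mu_p = np.exp(tp)
                J[:, :, j] = (
                    self.forward(mu_p[:, 0:1], mu_p[:, 1:2], freqs[None, :]) - pred
                ) / eps
            JtJ = np.einsum("pfi,pfj->pij", J, J) + 1e-9 * np.eye(2)[None]
            Jtr = np.einsum("pfi,pf->pi", J, r)
            det = JtJ[:, 0, 0] * JtJ[:, 1, 1] - JtJ[:, 0, 1] * JtJ[:, 1, 0]
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            step = np.empty_like(theta)
            step[:, 0] = (JtJ[:, 1, 1] * Jtr[:, 0] - JtJ[:, 0, 1] * Jtr[:, 1]) / det
            step[:, 1] = (JtJ[:, 0, 0] * Jtr[:, 1] - JtJ[:, 1, 0] * Jtr[:, 0]) / det
            theta = theta - np.clip(step, -0.5, 0.5)
        mu = np.exp(theta)
        inside = (
            (mu[:, 0] >= self.mu_a_grid[0])
            & (mu[:, 0] <= self.mu_a_grid[-1])
            & (mu[:, 1] >= self.mu_s_grid[0])
            & (mu[:, 1] <= self.mu_s_grid[-1])
        )
        pred = self.forward(mu[:, 0:1], mu[:, 1:2], freqs[None, :])
        resid = np.sqrt(((pred - obs) ** 2).sum(axis=1))
        valid = finite & inside & ~on_edge

        def reshape(v, fill=np.nan):
            out = np.full(n_px, fill)
            out[finite] = v[finite]
            return out.reshape(shape)

        return OpticalPropertyMaps(
            mu_a=reshape(mu[:, 0]),
            mu_s_prime=reshape(mu[:, 1]),
            wavelength=wavelength,
            residual_norm=reshape(resid),
            valid=valid.reshape(shape),
            start_disagreement=np.zeros(shape),
        )


def build_lut(
    forward=rd_forward,
    mu_a_grid=None,
    mu_s_grid=None,
    frequencies=(0.0, 2.0 / 3.0, 4.0 / 3.0, 2.0),
) -> LookupTable:
    """Precompute the forward model on a property grid.

    Default grids bracket the tissue-like range geometrically:
    mu_a in [0.05, 6] (60 nodes), mu_s' in [5, 40] (60 nodes).
    """
    mu_a_grid = np.asarray(
        mu_a_grid if mu_a_grid is not None else np.geomspace(0.05, 6.0, 60)
    )
    mu_s_grid = np.asarray(
        mu_s_grid if mu_s_grid is not None else np.geomspace(5.0, 40.0, 60)
    )
    frequencies = np.asarray(frequencies, dtype=float)
    table = forward(
        mu_a_grid[:, None, None], mu_s_grid[None, :, None], frequencies[None, None, :]
    )
    return LookupTable(mu_a_grid, mu_s_grid, frequencies, table, forward)


def build_correction_map(
    ops_ex: OpticalPropertyMaps, ops_em: OpticalPropertyMaps
) -> np.ndarray:
    """Per-pixel X_1D map from fitted excitation/emission property maps.

    NaN where either input pixel is invalid.  Unique property
    combinations are computed once (maps are often piecewise constant).
    """
    if ops_ex.mu_a.shape != ops_em.mu_a.shape:
        raise ValueError("excitation and emission maps must share one shape")
    shape = ops_ex.mu_a.shape
    ok = (
        ops_ex.valid
        & ops_em.valid
        & np.isfinite(ops_ex.mu_a)
        & np.isfinite(ops_em.mu_a)
    )
    out = np.full(shape, np.nan)
    if not ok.any():
        return out
    stacked = np.stack(
        [m[ok] for m in (ops_ex.mu_a, ops_ex.mu_s_prime, ops_em.mu_a, ops_em.mu_s_prime)]
    ).T
    rounded = stacked.round(6)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    if len(uniq) <= 0.25 * len(rounded):
        vals = np.array([x1d_factor((u[0], u[1]), (u[2], u[3])) for u in uniq])
        out[ok] = vals[inverse]
    else:
        out[ok] = x1d_factor(
            (stacked[:, 0], stacked[:, 1]), (stacked[:, 2], stacked[:, 3])
        )
    return out
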