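"""c(s) sedimentation-coefficient distribution analysis.

Sedimentation-velocity data are modeled as a regularized superposition of
Lamm-equation solutions on a grid of sedimentation coefficients, all
sharing one frictional ratio f/f0.  For each grid point s the diffusion
coefficient follows the hydrodynamic scaling

    D(s) = (sqrt(2)/(18 pi)) kT eta^{-3/2} (f/f0)^{-3/2}
           * ((1 - vbar rho) / (vbar s))^{1/2}

so that a single shape parameter closes the (s, D, M) relations via the
Svedberg equation.  The distribution is obtained by non-negative linear
least squares with a second-difference Tikhonov penalty (strength chosen
by the discrepancy principle unless given), a constant baseline co-fitted,
and f/f0 optimized in an outer one-dimensional search minimizing the rmsd.

Peak utilities convert fitted peaks to standard-condition s20,w values,
apparent molecular masses (via the fitted f/f0), and relative areas
normalized by the whole-distribution area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar, nnls

from .sedsim import R_GAS, SVEDBERG, Solvent, SVExperiment, WATER_20C, lamm_profiles

__all__ = [
    "CsDistribution",
    "PeakQuant",
    "diffusion_from_s_ffr",
    "fit_cs",
    "s20w",
    "apparent_mass",
    "quantify_peaks",
]

K_BOLTZMANN = 1.380649e-16  # erg/K


@dataclass
class CsDistribution:
    s_grid: np.ndarray  # Svedberg, increasing
    c: np.ndarray  # signal per Svedberg, >= 0
    ffr: float  # fitted frictional ratio
    lambda_reg: float
    baseline: float
    rmsd: float
    vbar: float = 0.73
    solvent: Solvent = WATER_20C
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if np.any(self.c < -1e-12):
            raise ValueError("c(s) must be non-negative")
        if self.ffr < 1.0:
            raise ValueError("frictional ratio must be >= 1")

    @property
    def total_area(self) -> float:
        return float(np.trapezoid(self.c, self.s_grid))


@dataclass
class PeakQuant:
    """Quantified peaks of a c(s) distribution.

    Each peak dict carries: s_peak, range (s_lo, s_hi), area,
    relative_area, s20w, apparent_mass.
    """

    peaks: list
    total_area: float
    degenerate: bool = False  # empty distribution: relative areas undefined


def diffusion_from_s_ffr(s: float, ffr: float, solvent: Solvent = WATER_20C,
                         vbar: float = 0.73) -> float:
    """D(s) in cm^2/s under the single-frictional-ratio scaling (s in S)."""
    if s <= 0 or ffr < 1.0:
        raise ValueError("s must be positive and ffr >= 1")
    buoy = 1.0 - vbar * solvent.density
    if buoy <= 0:
        raise ValueError("non-positive buoyancy")
    kT = K_BOLTZMANN * solvent.temperature
    eta = solvent.viscosity_poise
    return (np.sqrt(2.0) / (18.0 * np.pi)) * kT * eta ** -1.5 * ffr ** -1.5 \
        * np.sqrt(buoy / (vbar * s * SVEDBERG))


def s20w(s_obs: float, solvent: Solvent, vbar: float = 0.73) -> float:
    """Standardize an observed s to water at 20 C.

    s20,w = s_obs * (eta_solvent / eta_20,w) * ((1 - vbar rho_20,w) /
    (1 - vbar rho_solvent)).
    """
    b_w = 1.0 - vbar * WATER_20C.density
    b_s = 1.0 - vbar * solvent.density
    if b_w <= 0 or b_s <= 0:
        raise ValueError("non-positive buoyancy")
    return s_obs * (solvent.viscosity / WATER_20C.viscosity) * (b_w / b_s)


def apparent_mass(s_peak: float, ffr: float, solvent: Solvent = WATER_20C,
                  vbar: float = 0.73) -> float:
    """Apparent molar mass (kDa) of a peak via the Svedberg closure."""
    D = diffusion_from_s_ffr(s_peak, ffr, solvent, vbar)
    buoy = 1.0 - vbar * solvent.density
    M = (s_peak * SVEDBERG) * R_GAS * solvent.temperature / (D * buoy)  # g/mol
    return M / 1e3


# ---------------------------------------------------------------------------
# inversion


def _design_matrix(experiment: SVExperiment, s_grid: np.ndarray, ffr: float,
                   vbar: float, rmask: np.ndarray) -> np.ndarray:
    """Columns are full-cell Lamm solutions restricted to the fitting window."""
    cols = []
    for s in s_grid:
        D = diffusion_from_s_ffr(s, ffr, experiment.solvent, vbar)
        prof = lamm_profiles(s * SVEDBERG, D, experiment.radii, experiment.times,
                             experiment.omega)
        cols.append(prof[:, rmask].ravel())
    ds = np.gradient(s_grid)  # quadrature weights so that c has units 1/S
    return np.column_stack(cols) * ds[None, :]


def _solve_nnls(AtA, Aty, lam, L):
    """Min ||A c - y||^2 + lam^2 ||L c_s||^2 s.t. c >= 0, via Cholesky.

    The quadratic form is reduced by Cholesky so the active-set NNLS runs
    on a small square system.  A vanishing diagonal jitter keeps the
    factorization of the (nearly collinear) Lamm design positive definite;
    it is raised only as far as needed.
    """
    G0 = AtA + lam ** 2 * (L.T @ L)
    scale = np.trace(G0) / G0.shape[0]
    for jitter in (1e-14, 1e-11, 1e-8):
        G = G0 + jitter * scale * np.eye(G0.shape[0])
        try:
            cf = cho_factor(G, lower=False)
        except np.linalg.LinAlgError:
            continue
        R = np.triu(cf[0])
        z = solve_triangular(R.T, Aty, lower=True)
        coef, _ = nnls(R, z)
        return coef
    raise np.linalg.LinAlgError(
        "ill-conditioned c(s) design; increase the regularization strength")


def fit_cs(
    experiment: SVExperiment,
    s_grid: np.ndarray,
    ffr_bounds: tuple = (1.0, 2.5),
    lambda_reg="auto",
    vbar: float = 0.73,
    ffr: Optional[float] = None,
    ffr_xatol: float = 0.02,
    fit_window: Optional[tuple] = None,
) -> CsDistribution:
    """Fit a c(s) distribution with fitted (or fixed) frictional ratio.

    Parameters
    ----------
    experiment : SVExperiment
        Scan data (at least 10 scans).
    s_grid : array
        Sedimentation-coefficient grid in Svedberg, spanning the expected
        species; resolution should be 0.5 S or finer.
    ffr_bounds : (lo, hi)
        Search interval for the frictional ratio.
    lambda_reg : float or "auto"
        Tikhonov strength on the second differences of c; "auto" applies
        the discrepancy principle (chi^2 within 1 + 1/sqrt(n) of the
        unregularized fit).
    ffr : float, optional
        Fix the frictional ratio instead of searching.
    fit_window : (r_lo, r_hi), optional
        Radial window (cm) whose data enter the fit.  The Lamm solutions are
        always computed over the whole cell; by default the window excludes
        4% of the column at the meniscus and 8% at the base, where optical
        artifacts and the D-sensitive back-diffusion/pelleting pile-up would
        otherwise dominate the residuals.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if experiment.times.size < 10:
        raise ValueError("need at least 10 scans for a c(s) fit")
    if s_grid.size < 3 or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be increasing with >= 3 points")
    if np.max(np.diff(s_grid)) > 0.5 + 1e-12:
        raise ValueError("s_grid resolution must be 0.5 S or finer")
    radii = experiment.radii
    if fit_window is None:
        col = radii[-1] - radii[0]
        fit_window = (radii[0] + 0.04 * col, radii[-1] - 0.08 * col)
    rmask = (radii >= fit_window[0]) & (radii <= fit_window[1])
    if rmask.sum() < 10:
        raise ValueError("fitting window contains too few radial points")
    y = experiment.signal[:, rmask].ravel()
    n_data = y.size
    n_s = s_grid.size

    # second-difference penalty on the s-part; baseline columns unpenalized
    L = np.zeros((n_s - 2, n_s + 2))
    for k in range(n_s - 2):
        L[k, k: k + 3] = (1.0, -2.0, 1.0)

    cache: dict = {}

    def solve_for(ffr_val: float, lam: float):
        key = round(ffr_val, 6)
        if key not in cache:
            A_s = _design_matrix(experiment, s_grid, ffr_val, vbar, rmask)
            ones = np.ones((n_data, 1))
            A = np.hstack([A_s, ones, -ones])
            cache[key] = (A, A.T @ A, A.T @ y)
        A, AtA, Aty = cache[key]
        coef = _solve_nnls(AtA, Aty, lam, L)
        resid = A @ coef - y
        return coef, float(resid @ resid)

    def rss0(ffr_val: float) -> float:
        return solve_for(ffr_val, 0.0)[1]

    if ffr is None:
        lo, hi = ffr_bounds
        res = minimize_scalar(rss0, bounds=(lo, hi), method="bounded",
                              options={"xatol": ffr_xatol})
        ffr_fit = float(res.x)
        converged = bool(res.success)
    else:
        ffr_fit = float(ffr)
        converged = True

    chi2_0 = solve_for(ffr_fit, 0.0)[1]
    if lambda_reg == "auto":
        target = chi2_0 * (1.0 + 1.0 / np.sqrt(n_data))
        # largest lambda meeting the discrepancy target, by bisection in log10
        scale = np.sqrt(np.trace(cache[round(ffr_fit, 6)][1]) / (n_s + 2))
        lo_l, hi_l = -8.0, 2.0
        if solve_for(ffr_fit, scale * 10.0 ** hi_l)[1] <= target:
            lam = scale * 10.0 ** hi_l
        else:
            for _ in range(24):
                mid = 0.5 * (lo_l + hi_l)
                if solve_for(ffr_fit, scale * 10.0 ** mid)[1] <= target:
                    lo_l = mid
                else:
                    hi_l = mid
            lam = scale * 10.0 ** lo_l
    else:
        lam = float(lambda_reg)

    coef, chi2 = solve_for(ffr_fit, lam)
    ds = np.gradient(s_grid)
    c = coef[:n_s]  # signal per Svedberg (quadrature weights in the design)
    baseline = float(coef[n_s] - coef[n_s + 1])
    return CsDistribution(
        s_grid=s_grid, c=c, ffr=ffr_fit, lambda_reg=lam, baseline=baseline,
        rmsd=float(np.sqrt(chi2 / n_data)), vbar=vbar, solvent=experiment.solvent,
        meta={"chi2": chi2, "chi2_lambda0": chi2_0, "converged": converged,
              "n_data": n_data, "ds": ds, "fit_window": tuple(fit_window)},
    )


# ---------------------------------------------------------------------------
# peak quantification


def _refine_peak(s_grid: np.ndarray, c: np.ndarray, idx: int) -> float:
    """Parabolic sub-grid refinement of a local maximum position."""
    if idx == 0 or idx == len(c) - 1:
        return float(s_grid[idx])
    y0, y1, y2 = c[idx - 1], c[idx], c[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(s_grid[idx])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(s_grid[idx] + shift * (s_grid[1] - s_grid[0]))


def quantify_peaks(
    dist: CsDistribution,
    ranges: Optional[Sequence] = None,
    prominence_frac: float = 0.05,
    solvent: Optional[Solvent] = None,
) -> PeakQuant:
    """Integrate c(s) peaks and report relative areas, s20,w and masses.

    With ``ranges=None`` peaks are auto-detected as local maxima with
    prominence above ``prominence_frac * max(c)`` and integration ranges
    split at the minima between adjacent peaks (valley-to-valley), the
    outermost ranges extending to the grid edges.  Relative areas are
    normalized by the whole-distribution area.
    """
    s, c = dist.s_grid, dist.c
    solvent = solvent if solvent is not None else dist.solvent
    total = float(np.trapezoid(c, s))
    if total <= 0:
        return PeakQuant(peaks=[], total_area=0.0, degenerate=True)

    if ranges is None:
        if c.max() <= 0:
            return PeakQuant(peaks=[], total_area=total, degenerate=True)
        idx, _ = sps.find_peaks(c, prominence=prominence_frac * c.max())
        if idx.size == 0:
            idx = np.array([int(np.argmax(c))])
        bounds = [s[0]]
        for a, b in zip(idx, idx[1:]):
            valley = a + int(np.argmin(c[a: b + 1]))
            bounds.append(float(s[valley]))
        bounds.append(s[-1])
        ranges = list(zip(bounds[:-1], bounds[1:]))
        peak_idx = list(idx)
    else:
        ranges = [tuple(r) for r in ranges]
        for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
            if b0 < a1 - 1e-12:
                raise ValueError("ranges must be non-overlapping and ordered")
        peak_idx = []
        for lo, hi in ranges:
            mask = (s >= lo) & (s <= hi)
            if not np.any(mask):
                raise ValueError(f"range ({lo}, {hi}) outside the s grid")
            peak_idx.append(int(np.nonzero(mask)[0][np.argmax(c[mask])]))

    peaks = []
    for (lo, hi), pidx in zip(ranges, peak_idx):
        # include exact endpoints for a clean partition of the total area
        grid = s[(s >= lo) & (s <= hi)]
        gx = np.unique(np.concatenate([[lo], grid, [hi]]))
        area = float(np.trapezoid(np.interp(gx, s, c), gx))
        s_peak = _refine_peak(s, c, pidx)
        peaks.append({
            "s_peak": s_peak,
            "range": (float(lo), float(hi)),
            "area": area,
            "relative_area": area / total,
            "s20w": s20w(s_peak, solvent, dist.vbar),
            "apparent_mass": apparent_mass(s_peak, dist.ffr, solvent, dist.vbar),
        })
    return PeakQuant(peaks=peaks, total_area=total)
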