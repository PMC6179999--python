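"""Fitting the multi-component diffusion model to correlation curves.

The forward model (see :mod:`wntflux.models`) is fitted by bounded
nonlinear least squares on an internal parameterization that enforces the
physical constraints by construction:

* fractions live on the simplex via stick-breaking variables in [0, 1];
* diffusion times are ordered fast-to-slow via a base time and positive
  log-increments;
* the triplet fraction is bounded to [0, 0.5] and the triplet time is kept
  at least five-fold faster than the fastest diffusion time.

Weights are 1/sigma^2 when the curve carries per-lag uncertainties,
unweighted otherwise.  Several deterministic starting points (log-spaced
splits of the observed decay time) are tried and the best fit kept, so no
random initialization enters the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .correlate import CorrelationCurve
from .models import DetectionVolume, FcsModel, fcs_correlation

__all__ = [
    "FcsFitResult",
    "fit_fcs",
    "select_n_components",
    "diffusion_coefficient",
    "cpm",
    "size_ratio",
    "qc_photobleach",
]


@dataclass
class FcsFitResult:
    """Fitted model plus derived physical quantities."""

    model: FcsModel
    stderr: dict = field(default_factory=dict)
    chi2_reduced: float = np.nan
    D: tuple = ()  # um^2/s, ordered fast -> slow (decreasing)
    cpm: Optional[float] = None  # kHz per molecule
    converged: bool = True
    cost: float = np.nan
    n_points: int = 0

    @property
    def amplitude(self) -> float:
        """Fitted G(0+) - 1 with the triplet term excluded."""
        return self.model.amplitude


def diffusion_coefficient(tau_i: float, w0: float) -> float:
    """D = w0^2 / (4 tau_i), with w0 in um and tau in s -> um^2/s."""
    if tau_i <= 0 or w0 <= 0:
        raise ValueError("tau and w0 must be positive")
    return w0 ** 2 / (4.0 * tau_i)


def cpm(mean_intensity: float, N: float) -> float:
    """Counts per molecule: mean count rate (kHz) divided by particle number."""
    if N <= 0:
        raise ValueError("N must be positive")
    return mean_intensity / N


def size_ratio(D_a: float, D_b: float) -> float:
    """Hydrodynamic radius ratio R_a/R_b = D_b/D_a (Stokes-Einstein)."""
    if D_a <= 0 or D_b <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return D_b / D_a


def qc_photobleach(trace, max_decay_fraction: float = 0.2, n_segments: int = 20) -> dict:
    """Flag channels whose intensity decays beyond ``max_decay_fraction``.

    A linear trend is fitted to the segment-averaged intensity; a channel
    fails when the fitted total decay over the record exceeds the given
    fraction of the fitted initial level.  Returns channel -> bool (pass).
    """
    if trace.n_bins <= 10:
        raise ValueError("trace too short for bleach QC")
    result = {}
    for ch, counts in trace.counts.items():
        counts = np.asarray(counts, dtype=float)
        n_seg = min(n_segments, counts.size)
        seg = np.array_split(counts, n_seg)
        y = np.array([s.mean() for s in seg])
        x = np.linspace(0.0, 1.0, n_seg)
        slope, intercept = np.polyfit(x, y, 1)
        if intercept <= 0:
            result[ch] = bool(y.mean() >= 0) if slope >= 0 else False
            continue
        decay = -slope / intercept  # fraction of initial level lost over record
        result[ch] = bool(decay <= max_decay_fraction)
    return result


# ---------------------------------------------------------------------------
# internal parameterization


def _unpack(theta, n_comp, triplet, fix_structure, structure_param,
            fixed_tau=None):
    k = 0
    N = np.exp(theta[k]); k += 1
    F = []
    rem = 1.0
    for _ in range(n_comp - 1):
        q = theta[k]; k += 1
        F.append(rem * q)
        rem *= 1.0 - q
    F.append(rem)
    if fixed_tau is not None:
        taus = list(fixed_tau)
    else:
        ln_tau1 = theta[k]; k += 1
        taus = [np.exp(ln_tau1)]
        for _ in range(n_comp - 1):
            taus.append(taus[-1] * np.exp(theta[k])); k += 1
    if triplet:
        T = theta[k]; k += 1
        e_T = theta[k]; k += 1
        tau_T = taus[0] / 5.0 * np.exp(-e_T)
    else:
        T, tau_T = 0.0, taus[0] / 50.0
    if not fix_structure:
        structure_param = theta[k]; k += 1
    return N, tuple(F), tuple(taus), T, tau_T, structure_param


def _model_from_theta(theta, n_comp, triplet, fix_structure, structure_param,
                      fixed_tau=None):
    N, F, tau, T, tau_T, s = _unpack(theta, n_comp, triplet, fix_structure,
                                     structure_param, fixed_tau)
    return FcsModel(N=N, F=F, tau=tau, structure_param=s, triplet_T=max(T, 0.0),
                    triplet_tau=tau_T)


def _eval_theta(theta, lags, n_comp, triplet, fix_structure, structure_param,
                fixed_tau=None):
    N, F, tau, T, tau_T, s = _unpack(theta, n_comp, triplet, fix_structure,
                                     structure_param, fixed_tau)
    s2 = s ** 2
    g = np.zeros_like(lags)
    for F_i, tau_i in zip(F, tau):
        g += F_i / ((1.0 + lags / tau_i) * np.sqrt(1.0 + lags / (s2 * tau_i)))
    if triplet and T > 0:
        g *= 1.0 + (T / (1.0 - T)) * np.exp(-lags / tau_T)
    return 1.0 + g / N


def _starting_points(curve, n_comp, triplet, fix_structure, structure_param,
                     fixed_tau=None):
    lags, G = curve.lags, curve.G
    amp = max(np.mean(G[: max(3, len(G) // 50)]) - 1.0, 1e-6)
    N0 = 1.0 / amp
    # observed half-decay lag
    below = np.nonzero(G - 1.0 <= amp / 2.0)[0]
    tau_c = lags[below[0]] if below.size else np.sqrt(lags[0] * lags[-1])
    tau_c = float(np.clip(tau_c, lags[0] * 2, lags[-1] / 2))
    if n_comp == 1:
        splits = [(tau_c,)]
    elif n_comp == 2:
        splits = [(tau_c / r, tau_c * r) for r in (3.0, 10.0, 30.0)]
    else:
        splits = [
            (tau_c / r, tau_c, tau_c * r) for r in (5.0, 20.0)
        ] + [(tau_c / 100.0, tau_c / 3.0, tau_c * 10.0)]
    starts = []
    for taus in splits:
        taus = np.clip(np.sort(taus), lags[0] / 10.0, lags[-1] * 10.0)
        theta = [np.log(N0)]
        theta += [1.0 / (n_comp - i) for i in range(n_comp - 1)]  # equal fractions
        if fixed_tau is None:
            theta.append(np.log(taus[0]))
            for a, b in zip(taus, taus[1:]):
                theta.append(max(np.log(b / a), 0.5))
        if triplet:
            theta += [0.05, np.log(10.0)]  # T0, tau_T = tau_1/50
        if not fix_structure:
            theta.append(structure_param)
        starts.append(np.array(theta))
    return starts


def _bounds(curve, n_comp, triplet, fix_structure, fixed_tau=None):
    lags = curve.lags
    lo = [np.log(1e-4)]
    hi = [np.log(1e6)]
    for _ in range(n_comp - 1):
        lo.append(0.0); hi.append(1.0)
    if fixed_tau is None:
        lo.append(np.log(lags[0] / 100.0)); hi.append(np.log(lags[-1] * 100.0))
        for _ in range(n_comp - 1):
            lo.append(np.log(1.2)); hi.append(25.0)
    if triplet:
        lo += [0.0, 0.0]; hi += [0.5, 14.0]
    if not fix_structure:
        lo.append(1.0); hi.append(30.0)
    return np.array(lo), np.array(hi)


def fit_fcs(
    curve: CorrelationCurve,
    n_components: int = 1,
    volume: DetectionVolume = DetectionVolume(),
    fix_structure: bool = True,
    triplet: bool = True,
    weighted: Optional[bool] = None,
    init: Optional[np.ndarray] = None,
    fix_tau: Optional[tuple] = None,
) -> FcsFitResult:
    """Fit the diffusion + triplet model to a correlation curve.

    Parameters
    ----------
    curve : CorrelationCurve
    n_components : int
        Number of diffusing components (1-3).
    volume : DetectionVolume
        Supplies the structure parameter (fixed by default) and the beam
        waist used to convert diffusion times to coefficients.
    triplet : bool
        Include the fast dark-state term.
    weighted : bool, optional
        Force weighted/unweighted residuals; by default weights 1/sigma^2
        are applied whenever the curve carries sigma.
    init : array, optional
        Explicit internal starting vector (expert use); otherwise several
        deterministic starts are tried.
    fix_tau : tuple, optional
        Hold the diffusion times at these values and fit only amplitude
        parameters; used e.g. for cross-correlation curves whose diffusion
        time is constrained from the autocorrelations (an unconstrained
        amplitude is unidentifiable when the fitted time falls below the
        first lag).
    """
    if not 1 <= n_components <= 3:
        raise ValueError("n_components must be 1, 2 or 3")
    if fix_tau is not None:
        fix_tau = tuple(float(t) for t in fix_tau)
        if len(fix_tau) != n_components:
            raise ValueError("fix_tau must provide one time per component")
    if not (np.all(np.isfinite(curve.G)) and np.all(np.isfinite(curve.lags))):
        raise ValueError("curve contains non-finite values")
    n_free = (1 + (n_components - 1) + (0 if fix_tau is not None else n_components)
              + (2 if triplet else 0) + (0 if fix_structure else 1))
    if len(curve.lags) < 5 * n_free:
        raise ValueError("curve has too few lag points for the requested model")
    if weighted is None:
        weighted = curve.sigma is not None
    if weighted and curve.sigma is None:
        raise ValueError("weighted fit requested but curve has no sigma")
    w = 1.0 / np.where(curve.sigma > 0, curve.sigma, np.inf) if weighted else None

    lags, G = curve.lags, curve.G
    sp = volume.structure_param

    def residuals(theta):
        r = _eval_theta(theta, lags, n_components, triplet, fix_structure, sp,
                        fix_tau) - G
        return r * w if w is not None else r

    lo, hi = _bounds(curve, n_components, triplet, fix_structure, fix_tau)
    starts = [init] if init is not None else _starting_points(
        curve, n_components, triplet, fix_structure, sp, fix_tau
    )
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        model = _model_from_theta(starts[0], n_components, triplet,
                                  fix_structure, sp, fix_tau)
        return FcsFitResult(model=model, converged=False, n_points=len(lags))

    model = _model_from_theta(best.x, n_components, triplet, fix_structure, sp,
                              fix_tau)
    dof = max(len(lags) - n_free, 1)
    rss = 2.0 * best.cost
    chi2_red = rss / dof if weighted else np.nan
    stderr = _propagate_stderr(best, n_components, triplet, fix_structure, sp,
                               weighted, rss, dof, fix_tau)
    D = tuple(diffusion_coefficient(t, volume.w0) for t in model.tau)
    mean_int = curve.mean_intensity.get(curve.pair[0]) if curve.mean_intensity else None
    cpm_val = cpm(mean_int, model.N) if mean_int is not None else None
    converged = bool(best.status > 0)
    return FcsFitResult(
        model=model, stderr=stderr, chi2_reduced=chi2_red, D=D, cpm=cpm_val,
        converged=converged, cost=rss, n_points=len(lags),
    )


def _propagate_stderr(sol, n_comp, triplet, fix_structure, sp, weighted, rss,
                      dof, fixed_tau=None):
    """Delta-method standard errors on (N, F_i, tau_i, T, tau_T)."""
    try:
        J = sol.jac
        cov_theta = np.linalg.pinv(J.T @ J)
        if not weighted:
            cov_theta *= rss / dof
        names = (["N"] + [f"F{i+1}" for i in range(n_comp)]
                 + [f"tau{i+1}" for i in range(n_comp)] + ["triplet_T", "triplet_tau"])

        def phys(theta):
            N, F, tau, T, tau_T, _ = _unpack(theta, n_comp, triplet,
                                             fix_structure, sp, fixed_tau)
            return np.array([N, *F, *tau, T, tau_T])

        p0 = phys(sol.x)
        Jp = np.empty((p0.size, sol.x.size))
        for k in range(sol.x.size):
            h = 1e-6 * max(abs(sol.x[k]), 1e-3)
            xp = sol.x.copy(); xp[k] += h
            xm = sol.x.copy(); xm[k] -= h
            Jp[:, k] = (phys(xp) - phys(xm)) / (2 * h)
        cov_p = Jp @ cov_theta @ Jp.T
        se = np.sqrt(np.clip(np.diag(cov_p), 0.0, None))
        return dict(zip(names, se))
    except Exception:
        return {}


def select_n_components(
    curve: CorrelationCurve,
    volume: DetectionVolume = DetectionVolume(),
    max_components: int = 3,
    alpha: float = 0.05,
    min_fraction: float = 0.02,
    **fit_kwargs,
) -> tuple:
    """Choose the number of components by nested F-tests on residual sums.

    A richer model is accepted only if it improves the (weighted) residual
    sum significantly at level ``alpha`` and all its fractions exceed
    ``min_fraction``.  Returns (chosen_n, {n: FcsFitResult}).
    """
    fits = {}
    chosen = 1
    fits[1] = fit_fcs(curve, 1, volume, **fit_kwargs)
    for n in range(2, max_components + 1):
        try:
            cand = fit_fcs(curve, n, volume, **fit_kwargs)
        except ValueError:
            break
        fits[n] = cand
        base = fits[chosen]
        extra = 2  # one fraction + one diffusion time
        dof2 = cand.n_points - (1 + 2 * n - 1 + 2)
        if cand.cost >= base.cost or dof2 <= 0:
            continue
        F = ((base.cost - cand.cost) / extra) / (cand.cost / dof2)
        p = f_dist.sf(F, extra, dof2)
        if p < alpha and min(cand.model.F) >= min_fraction and cand.converged:
            chosen = n
    return chosen, fits
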