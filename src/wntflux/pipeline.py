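"""Scenario generators and end-to-end pipelines.

The synthetic scenarios encode the study conditions of the two analyses:

FCS/FCCS (gastrula-stage extracellular measurements)
    Extracellular GFP-Wnt3a dynamics are two-component: a freely diffusing
    fast component (D_fast = 12.6 um^2/s, fraction 19%) and a slow,
    matrix-associated component (D_slow = 0.09 um^2/s, fraction 81%).
    Windowed records split into a high-brightness population (CPM >= 7 kHz
    per molecule; large multi-Wnt assemblies, uniformly slow) and a
    low-brightness population (small complexes, broad mobility).
    Co-expression of sFRP2 removes the high-brightness population.

AUC-FDS (conditioned-medium sedimentation at 42,000 r.p.m., 20 C)
    Secreted GFP sediments as a 2.8 S / ~30 kDa monomer; GFP-WntD as a
    4.1 S / 61 kDa monomer.  GFP-Wnt3a shows a 7.0 S / ~150 kDa
    afamin-complex peak plus widely distributed high-molecular-weight
    (HMW) assemblies whose smallest member is ~9.6 S / ~200 kDa.  A
    serum-albumin-bound dye contributes a ~4.2 S background peak.  The
    mock-treated composition is 35.1% afamin-complex and 51.1% HMW of the
    whole distribution area; afamin depletion shifts these to 14.1% and
    69.6%.  Fzd8-CRD or sFRP2 co-culture transfers area into new ~6.0 S
    or ~5.4 S complex peaks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .config import RunConfig, substream_rng
from .correlate import CorrelationCurve
from .csdist import fit_cs, quantify_peaks
from .fccs import compute_rca
from .fcsfit import fit_fcs
from .fluctsim import add_curve_noise, analytic_correlation
from .models import DetectionVolume, FcsModel
from .popsplit import classify_cpm, compare_counts, compare_dslow, cpm_histogram
from .sedsim import SedSpecies, rpm_to_omega, simulate_sv

__all__ = [
    "EMBRYO_FCS",
    "AUC_SPECIES",
    "AUC_SCENARIOS",
    "default_lag_grid",
    "embryo_curve",
    "sample_window_curves",
    "fccs_measurement_curves",
    "run_fcs_pipeline",
    "run_auc_pipeline",
]

# two-component extracellular mobility of GFP-Wnt3a in gastrula embryos
EMBRYO_FCS = {
    "D_fast": 12.6,  # um^2/s
    "D_slow": 0.09,  # um^2/s
    "f_fast": 0.19,
    "f_slow": 0.81,
    "N": 5.0,  # particles in the detection volume
    "triplet_T": 0.15,
    "triplet_tau": 4e-6,  # s
    "noise_frac": 0.01,  # curve noise, fraction of the G(0)-1 amplitude
}

# Mixture species share one hydrodynamic shape class (frictional ratio), as
# the single-f/f0 c(s) model assumes, anchored at the smallest HMW assembly
# (9.6 S at its trimer-scale 200 kDa): M(s) = 200 * (s/9.6)^1.5.  Monomer
# calibration runs keep their printed masses.
def _closure_mass(s: float) -> float:
    return 200.0 * (s / 9.6) ** 1.5


# sedimenting species: (s / S, M / kDa)
AUC_SPECIES = {
    "gfp": (2.8, 30.0),
    "wntd": (4.1, 61.0),
    "albumin_dye": (4.2, _closure_mass(4.2)),
    "wnt3a_afamin": (7.0, _closure_mass(7.0)),
    "hmw_small": (9.6, 200.0),  # smallest HMW assembly (trimer scale)
    "hmw_mid": (11.8, _closure_mass(11.8)),
    "hmw_large": (14.0, _closure_mass(14.0)),
    "wnt3a_fzd8crd": (6.0, _closure_mass(6.0)),
    "wnt3a_sfrp2": (5.4, _closure_mass(5.4)),
}

# scenario -> {species key: fractional signal}; fractions sum to 1
AUC_SCENARIOS = {
    "gfp_monomer": {"gfp": 1.0},
    "wntd_monomer": {"wntd": 1.0},
    # two-species run resolving the afamin complex against the smallest HMW
    "wnt3a_two_species": {"wnt3a_afamin": 0.5, "hmw_small": 0.5},
    # whole-distribution compositions (albumin-dye background + HMW split
    # evenly over three assembly sizes)
    "wnt3a_mixture_mock": {
        "albumin_dye": 0.138, "wnt3a_afamin": 0.351,
        "hmw_small": 0.1703, "hmw_mid": 0.1703, "hmw_large": 0.1704,
    },
    "wnt3a_afamin_depleted": {
        "albumin_dye": 0.163, "wnt3a_afamin": 0.141,
        "hmw_small": 0.232, "hmw_mid": 0.232, "hmw_large": 0.232,
    },
    "wnt3a_plus_fzd8crd": {
        "albumin_dye": 0.14, "wnt3a_fzd8crd": 0.45,
        "wnt3a_afamin": 0.15, "hmw_small": 0.09, "hmw_mid": 0.09,
        "hmw_large": 0.08,
    },
    "wnt3a_plus_sfrp2": {
        "albumin_dye": 0.14, "wnt3a_sfrp2": 0.35,
        "wnt3a_afamin": 0.174, "hmw_small": 0.112, "hmw_mid": 0.112,
        "hmw_large": 0.112,
    },
}

AUC_S_RANGES = {
    "gfp_monomer": (0.5, 6.0),
    "wntd_monomer": (1.0, 8.0),
    "wnt3a_two_species": (3.0, 14.0),
    "wnt3a_mixture_mock": (2.0, 18.0),
    "wnt3a_afamin_depleted": (2.0, 18.0),
    "wnt3a_plus_fzd8crd": (2.0, 18.0),
    "wnt3a_plus_sfrp2": (2.0, 18.0),
}


def default_lag_grid(n: int = 160, lag_min: float = 2e-6, lag_max: float = 10.0):
    return np.geomspace(lag_min, lag_max, n)


def _embryo_model(volume: DetectionVolume, d_fast=None, d_slow=None,
                  f_slow=None, N=None) -> FcsModel:
    p = EMBRYO_FCS
    d_fast = p["D_fast"] if d_fast is None else d_fast
    d_slow = p["D_slow"] if d_slow is None else d_slow
    f_slow = p["f_slow"] if f_slow is None else f_slow
    N = p["N"] if N is None else N
    tau_fast = volume.w0 ** 2 / (4.0 * d_fast)
    tau_slow = volume.w0 ** 2 / (4.0 * d_slow)
    return FcsModel(
        N=N, F=(1.0 - f_slow, f_slow), tau=(tau_fast, tau_slow),
        structure_param=volume.structure_param,
        triplet_T=p["triplet_T"], triplet_tau=p["triplet_tau"],
    )


def embryo_curve(volume: DetectionVolume, seed: int, lags=None,
                 mean_intensity: Optional[float] = None, **model_kwargs
                 ) -> CorrelationCurve:
    """One noisy synthetic correlation curve under the embryo conditions."""
    lags = default_lag_grid() if lags is None else lags
    model = _embryo_model(volume, **model_kwargs)
    clean = analytic_correlation(model, lags)
    sigma = EMBRYO_FCS["noise_frac"] * model.amplitude
    noisy = add_curve_noise(clean, sigma, seed=seed)
    if mean_intensity is not None:
        noisy.mean_intensity = {"g": mean_intensity}
    noisy.pair = ("g", "g")
    return noisy


def sample_window_curves(scenario: str, n_windows: int, volume: DetectionVolume,
                         seed: int) -> list:
    """Per-window noisy curves for the windowed brightness analysis.

    ``embryo_two_component`` mixes a high-brightness population (40% of
    windows; CPM ~ 10.5 +- 1.5 kHz, uniformly slow D_slow) with a
    low-brightness one (CPM ~ 3.5 +- 1.5 kHz, broadly distributed D_slow);
    ``embryo_plus_sfrp2`` contains the low-brightness population only.
    """
    if scenario not in ("embryo_two_component", "embryo_plus_sfrp2"):
        raise ValueError(
            f"unknown FCS scenario {scenario!r}; choose one of "
            "'embryo_two_component', 'embryo_plus_sfrp2', "
            "'codiffusion', 'independent'")
    rng = np.random.default_rng(seed)
    p_high = 0.4 if scenario == "embryo_two_component" else 0.0
    curves = []
    for w in range(n_windows):
        high = rng.random() < p_high
        if high:
            cpm_w = float(np.clip(rng.normal(10.5, 1.5), 7.2, 20.0))
            d_slow = float(np.exp(rng.normal(np.log(0.03), 0.5)))
        else:
            cpm_w = float(np.clip(rng.normal(3.5, 1.5), 0.5, 6.8))
            d_slow = float(np.exp(rng.normal(np.log(0.3), 1.2)))
        d_slow = min(d_slow, EMBRYO_FCS["D_fast"] / 4.0)
        curves.append(embryo_curve(
            volume, seed=int(rng.integers(2 ** 31)), d_slow=d_slow,
            mean_intensity=cpm_w * EMBRYO_FCS["N"],
        ))
    return curves


def fccs_measurement_curves(n_g: float, n_r: float, n_gr: float,
                            volume: DetectionVolume, seed: int,
                            d_complex: float = 12.6, lags=None) -> tuple:
    """(green auto, red auto, cross) noisy curves for one FCCS measurement.

    ``n_g``/``n_r`` are total green/red particle numbers in the volume and
    ``n_gr`` the number of double-labeled complexes; ideal-label amplitude
    algebra gives amp_c = n_gr / (n_g n_r).
    """
    if n_gr > min(n_g, n_r) + 1e-9:
        raise ValueError("double-labeled particles cannot exceed either total")
    lags = default_lag_grid() if lags is None else lags
    tau = volume.w0 ** 2 / (4.0 * d_complex)
    ss = np.random.SeedSequence(seed).spawn(3)
    out = []
    for k, N in enumerate([n_g, n_r, (n_g * n_r / n_gr) if n_gr > 0 else None]):
        if N is None:
            # no co-diffusion: flat unity curve, amplitude only from noise
            model = FcsModel(N=1e6, F=(1.0,), tau=(tau,),
                             structure_param=volume.structure_param)
        else:
            model = FcsModel(N=N, F=(1.0,), tau=(tau,),
                             structure_param=volume.structure_param)
        clean = analytic_correlation(model, lags)
        sigma = 0.01 * (1.0 / min(n_g, n_r))
        out.append(add_curve_noise(clean, sigma, seed=int(ss[k].generate_state(1)[0] % 2**31)))
    out[0].pair = ("g", "g")
    out[1].pair = ("r", "r")
    out[2].pair = ("g", "r")
    return tuple(out)


def embryo_recovery_experiment(volume: DetectionVolume, n_curves: int = 20,
                               seed: int = 0) -> dict:
    """Fit a batch of synthetic embryo-condition curves; report medians.

    Each curve is generated from the two-component + triplet model at the
    embryo parameters and fitted blind; the medians of the recovered fast
    and slow diffusion coefficients and of the slow fraction summarize the
    parameter-recovery performance.
    """
    rng = np.random.default_rng(seed)
    d_fast, d_slow, f_slow = [], [], []
    for _ in range(n_curves):
        curve = embryo_curve(volume, seed=int(rng.integers(2 ** 31)))
        fit = fit_fcs(curve, 2, volume, triplet=True)
        d_fast.append(fit.D[0])
        d_slow.append(fit.D[-1])
        f_slow.append(fit.model.F[-1])
    return {
        "median_d_fast": float(np.median(d_fast)),
        "median_d_slow": float(np.median(d_slow)),
        "median_f_slow_pct": float(np.median(f_slow) * 100.0),
        "n": n_curves,
    }


def resolved_peaks(summary: dict, n: int = 2) -> list:
    """The n largest-area peaks of an AUC summary, ordered by s."""
    peaks = sorted(summary["peaks"], key=lambda p: p["area"], reverse=True)[:n]
    return sorted(peaks, key=lambda p: p["s_peak"])


# ---------------------------------------------------------------------------
# pipelines


# FCCS scenarios: total particle numbers per channel and double-labeled count
FCCS_SCENARIOS = {
    "codiffusion": (5.0, 5.0, 5.0),   # every particle carries both labels
    "independent": (5.0, 5.0, 0.0),   # free labels, no complexes
}


def run_fcs_pipeline(config: RunConfig, scenario: str, n_windows: int = 40,
                     out_dir=None) -> dict:
    """Windowed FCS analysis (or FCCS RCA summary) of one scenario."""
    volume = config.volume
    if scenario in FCCS_SCENARIOS:
        from .fccs import fit_fccs
        n_g, n_r, n_gr = FCCS_SCENARIOS[scenario]
        rng = substream_rng(config.seed, f"fccs:{scenario}")
        rcas = []
        for _ in range(n_windows):
            curves = fccs_measurement_curves(
                n_g, n_r, n_gr, volume, seed=int(rng.integers(2 ** 31)))
            rcas.append(fit_fccs(*curves, volume).rca)
        summary = {
            "scenario": scenario, "n_measurements": n_windows,
            "rca_mean": float(np.mean(rcas)), "rca_sd": float(np.std(rcas, ddof=1)),
            "rca": rcas, "seed": config.seed,
            "config_hash": config.config_hash(), "version": __version__,
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"fcs_{scenario}.json").write_text(json.dumps(summary, indent=1))
        return summary
    rng_seed = int(substream_rng(config.seed, f"fcs:{scenario}").integers(2 ** 31))
    curves = sample_window_curves(scenario, n_windows, volume, rng_seed)
    meas = []
    for w, curve in enumerate(curves):
        fit = fit_fcs(curve, 2, volume, triplet=True)
        from .popsplit import _measurement_from_fit
        meas.append(_measurement_from_fit(w, config.window_length, fit,
                                          fit.converged, scenario))
    ok = [m for m in meas if m.qc_pass]
    labels = classify_cpm(ok, config.cpm_threshold)
    high = [m for m, l in zip(ok, labels) if l == "high"]
    low = [m for m, l in zip(ok, labels) if l == "low"]
    summary = {
        "scenario": scenario,
        "n_windows": n_windows,
        "n_qc_pass": len(ok),
        "n_high": len(high),
        "n_low": len(low),
        "median_d_slow_high": float(np.median([m.d_slow for m in high])) if high else None,
        "median_d_slow_low": float(np.median([m.d_slow for m in low])) if low else None,
        "histogram": {f"{lo:g}-{hi:g}": len(v) for (lo, hi), v in
                      cpm_histogram(ok, config.cpm_bin_width).items()},
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    if high and low:
        p, method = compare_dslow([m.d_slow for m in high], [m.d_slow for m in low])
        summary["wilcoxon_p_high_vs_low"] = p
        summary["wilcoxon_method"] = method
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"fcs_{scenario}.json").write_text(json.dumps(summary, indent=1))
    return summary


def compare_fcs_conditions(config: RunConfig, summaries: dict) -> dict:
    """High/low population counts across conditions: Fisher + Bonferroni."""
    names = list(summaries)
    tables, pairs = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tables.append([[summaries[a]["n_high"], summaries[a]["n_low"]],
                           [summaries[b]["n_high"], summaries[b]["n_low"]]])
            pairs.append((a, b))
    res = compare_counts(tables)
    return {"pairs": [list(p) for p in pairs], **res}


def run_auc_pipeline(config: RunConfig, scenario: str, out_dir=None,
                     grid_step: float = 0.1) -> dict:
    """Sedimentation pipeline: simulate scans, invert to c(s), quantify."""
    if scenario not in AUC_SCENARIOS:
        raise ValueError(
            f"unknown AUC scenario {scenario!r}; choose one of "
            f"{sorted(AUC_SCENARIOS)}")
    comp = AUC_SCENARIOS[scenario]
    species = [SedSpecies(s=AUC_SPECIES[k][0], M=AUC_SPECIES[k][1],
                          vbar=config.vbar, signal=frac)
               for k, frac in comp.items()]
    seed = int(substream_rng(config.seed, f"auc:{scenario}").integers(2 ** 31))
    exp = simulate_sv(
        species, radii=config.radii, times=config.times,
        omega=rpm_to_omega(config.rpm), solvent=config.solvent,
        noise_sigma=config.sv_noise_sigma, seed=seed,
    )
    lo, hi = AUC_S_RANGES[scenario]
    s_grid = np.arange(lo, hi + grid_step / 2, grid_step)
    dist = fit_cs(exp, s_grid, vbar=config.vbar)
    quant = quantify_peaks(dist)
    summary = {
        "scenario": scenario,
        "ffr": dist.ffr,
        "lambda_reg": dist.lambda_reg,
        "rmsd": dist.rmsd,
        "baseline": dist.baseline,
        "peaks": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in pk.items()}
            for pk in quant.peaks
        ],
        "relative_area_sum": float(sum(p["relative_area"] for p in quant.peaks)),
        "truth": comp,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"auc_{scenario}.json").write_text(json.dumps(summary, indent=1))
    return summary
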