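"""Windowed brightness/mobility analysis and population statistics.

A long measurement record is cut into fixed windows (default 10 s); each
window is correlated and fitted independently, yielding per-window counts
per molecule (CPM) and a slow-component diffusion coefficient.  Windows
are classified into a high- and a low-brightness population at a CPM
threshold (default 7.0 kHz per molecule, boundary inclusive to "high"),
slow-diffusion distributions are compared across populations with the
Wilcoxon rank-sum test, and population counts across conditions with
two-sided Fisher's exact tests under Bonferroni correction.  Grouped RCA
samples are compared by one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import stats

from .correlate import CorrelationCurve, multitau_correlate
from .fcsfit import fit_fcs, qc_photobleach
from .fluctsim import IntensityTrace
from .models import DetectionVolume

__all__ = [
    "WindowedMeasurement",
    "PopulationSummary",
    "window_analyze",
    "classify_cpm",
    "cpm_histogram",
    "compare_dslow",
    "compare_counts",
    "compare_rca_groups",
]

CPM_THRESHOLD_DEFAULT = 7.0  # kHz per molecule
CPM_BIN_WIDTH_DEFAULT = 3.5  # kHz per molecule


@dataclass
class WindowedMeasurement:
    window_index: int
    window_length: float  # s
    cpm: float  # kHz per molecule
    d_slow: float  # um^2/s
    d_fast: float  # um^2/s
    f_slow: float
    qc_pass: bool = True
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.d_fast < self.d_slow:
            raise ValueError("d_fast must be >= d_slow")
        if not 0.0 <= self.f_slow <= 1.0:
            raise ValueError("f_slow must lie in [0, 1]")


@dataclass
class PopulationSummary:
    threshold: float
    counts: dict  # condition -> (n_high, n_low)
    wilcoxon_p: dict = field(default_factory=dict)
    fisher_p_raw: dict = field(default_factory=dict)
    fisher_p_adjusted: dict = field(default_factory=dict)
    histogram: dict = field(default_factory=dict)


def window_analyze(
    record,
    window_length: float = 10.0,
    volume: DetectionVolume = DetectionVolume(),
    n_components: int = 2,
    triplet: bool = True,
    max_decay_fraction: float = 0.2,
    m: int = 16,
    condition: Optional[str] = None,
) -> list:
    """Per-window correlation + fit over a long record.

    ``record`` is either an :class:`IntensityTrace` (windows are cut,
    correlated with the multi-tau estimator and fitted) or a sequence of
    per-window :class:`CorrelationCurve` objects (each fitted directly;
    the curve's ``mean_intensity`` supplies the CPM numerator).  Windows
    with failed bleach QC or non-converged fits are flagged
    ``qc_pass=False``.
    """
    measurements: list = []
    if isinstance(record, IntensityTrace):
        n_per = int(round(window_length / record.bin_width))
        n_windows = record.n_bins // n_per
        if n_windows < 2:
            raise ValueError("record shorter than two windows")
        for widx in range(n_windows):
            sl = slice(widx * n_per, (widx + 1) * n_per)
            sub = IntensityTrace(
                bin_width=record.bin_width,
                counts={ch: np.asarray(c[sl]) for ch, c in record.counts.items()},
            )
            qc = all(qc_photobleach(sub, max_decay_fraction).values())
            ch = sub.channel_names[0]
            try:
                curve = multitau_correlate(sub, ch, ch, m=m)
                fit = fit_fcs(curve, n_components, volume, triplet=triplet)
            except ValueError:
                measurements.append(
                    WindowedMeasurement(widx, window_length, 0.0, 0.0, 0.0, 0.0,
                                        qc_pass=False, condition=condition)
                )
                continue
            measurements.append(_measurement_from_fit(widx, window_length, fit,
                                                      qc and fit.converged, condition))
    else:
        curves = list(record)
        if len(curves) < 1:
            warnings.warn("empty curve series", stacklevel=2)
        for widx, curve in enumerate(curves):
            try:
                fit = fit_fcs(curve, n_components, volume, triplet=triplet)
            except ValueError:
                measurements.append(
                    WindowedMeasurement(widx, window_length, 0.0, 0.0, 0.0, 0.0,
                                        qc_pass=False, condition=condition)
                )
                continue
            measurements.append(_measurement_from_fit(widx, window_length, fit,
                                                      fit.converged, condition))
    if measurements and not any(mm.qc_pass for mm in measurements):
        warnings.warn("all windows failed QC", stacklevel=2)
    return measurements


def _measurement_from_fit(widx, window_length, fit, qc_pass, condition):
    D = fit.D
    if len(D) >= 2:
        d_fast, d_slow = D[0], D[-1]
        f_slow = fit.model.F[-1]
    else:
        d_fast = d_slow = D[0]
        f_slow = 1.0
    return WindowedMeasurement(
        window_index=widx, window_length=window_length,
        cpm=fit.cpm if fit.cpm is not None else np.nan,
        d_slow=d_slow, d_fast=d_fast, f_slow=float(np.clip(f_slow, 0.0, 1.0)),
        qc_pass=bool(qc_pass), condition=condition,
    )


def classify_cpm(measurements: Sequence, threshold: float = CPM_THRESHOLD_DEFAULT) -> list:
    """Label each measurement 'high' (cpm >= threshold) or 'low'.

    The boundary value belongs to the high-brightness population.
    Accepts WindowedMeasurement objects or bare CPM numbers.
    """
    labels = []
    for mm in measurements:
        c = mm.cpm if isinstance(mm, WindowedMeasurement) else float(mm)
        labels.append("high" if c >= threshold else "low")
    return labels


def cpm_histogram(measurements: Sequence, bin_width: float = CPM_BIN_WIDTH_DEFAULT) -> dict:
    """D_slow values grouped in CPM classes of fixed width starting at 0.

    Returns {(lo, hi): [d_slow, ...]} for the occupied CPM bins.
    """
    out: dict = {}
    for mm in measurements:
        c = mm.cpm if isinstance(mm, WindowedMeasurement) else float(mm)
        k = int(np.floor(c / bin_width))
        key = (k * bin_width, (k + 1) * bin_width)
        d = mm.d_slow if isinstance(mm, WindowedMeasurement) else np.nan
        out.setdefault(key, []).append(d)
    return dict(sorted(out.items()))


def compare_dslow(group_a, group_b) -> tuple:
    """Two-sided Wilcoxon rank-sum test on slow diffusion coefficients.

    Uses the exact rank-sum distribution for small tie-free samples
    (min group size <= 10) and the tie-corrected normal approximation
    otherwise.  Returns (p_value, method).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (min(a.size, b.size) <= 10) and not ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), method


def fisher_exact_2x2(table) -> tuple:
    """Two-sided Fisher's exact test by the probability-mass criterion.

    Returns (p, degenerate): a table with a zero margin carries no
    information and reports p = 1 with the degenerate flag set.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0, True
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(p, 1.0)), False


def compare_counts(tables: Sequence) -> dict:
    """Per-table two-sided Fisher p-values with Bonferroni adjustment.

    Returns {'p_raw': [...], 'p_adjusted': [...], 'degenerate': [...]} with
    adjusted p = min(1, m * p_raw) for m tables.
    """
    m = len(tables)
    if m == 0:
        raise ValueError("no tables supplied")
    p_raw, degenerate = [], []
    for t in tables:
        p, dg = fisher_exact_2x2(t)
        p_raw.append(p)
        degenerate.append(dg)
    p_adj = [min(1.0, m * p) for p in p_raw]
    return {"p_raw": p_raw, "p_adjusted": p_adj, "degenerate": degenerate}


def compare_rca_groups(groups: dict) -> dict:
    """One-way ANOVA followed by Tukey's HSD on named RCA samples.

    Returns {'anova_p': float, 'pairs': {(a, b): {'estimate', 'ci_low',
    'ci_high', 'p_adjusted'}}}.  With zero pooled variance the p-values are
    undefined and reported as NaN with a degenerate flag.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    ss_w = sum(((s - s.mean()) ** 2).sum() for s in samples)
    degenerate = ss_w == 0.0
    out: dict = {"degenerate": degenerate, "pairs": {}}
    if degenerate:
        out["anova_p"] = np.nan
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                est = samples[names.index(b)].mean() - samples[i].mean()
                out["pairs"][(a, b)] = {
                    "estimate": est, "ci_low": np.nan, "ci_high": np.nan,
                    "p_adjusted": np.nan,
                }
        return out
    out["anova_p"] = float(stats.f_oneway(*samples).pvalue)
    hsd = stats.tukey_hsd(*samples)
    ci = hsd.confidence_interval(0.95)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            out["pairs"][(a, b)] = {
                "estimate": float(samples[j].mean() - samples[i].mean()),
                "ci_low": float(ci.low[j, i]),
                "ci_high": float(ci.high[j, i]),
                "p_adjusted": float(hsd.pvalue[i, j]),
            }
    return out
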