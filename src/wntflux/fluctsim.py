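"""Synthetic fluorescence-fluctuation data.

Two generators are provided:

* :func:`simulate_trace` — a particle-based Brownian-dynamics simulation:
  point emitters diffuse through a periodic cubic box containing a centred
  3D-Gaussian detection volume, blink between a bright and a dark (triplet)
  state, and emit Poisson-distributed photons per bin.  Species sharing a
  ``colabel_id`` co-diffuse as one complex, which is what creates
  cross-correlation between detection channels.
* :func:`analytic_correlation` / :func:`add_curve_noise` — the closed-form
  correlation model evaluated on a lag grid, optionally with Gaussian noise;
  this is the fast route used for fitting studies where the photon-level
  detail of the trace is irrelevant.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np

from .correlate import CorrelationCurve
from .models import DetectionVolume, FcsModel, fcs_correlation

__all__ = [
    "DiffusingSpecies",
    "IntensityTrace",
    "simulate_trace",
    "analytic_correlation",
    "add_curve_noise",
]


@dataclass
class DiffusingSpecies:
    """One diffusing emitter species.

    Parameters
    ----------
    D : float
        Diffusion coefficient in um^2/s.
    mean_count : float
        Expected number of particles in the simulation box (not in the
        detection volume).
    brightness : dict
        Per-channel molecular brightness in kHz per molecule, e.g.
        ``{"g": 10.0, "r": 0.0}``.
    triplet_fraction, triplet_time : float
        Stationary dark-state fraction in [0, 1) and relaxation time (s) of
        the two-state blinking process.
    colabel_id : str, optional
        Species sharing an id ride on the same particle positions
        (a dual-labeled complex).
    """

    D: float
    mean_count: float
    brightness: dict
    triplet_fraction: float = 0.0
    triplet_time: float = 1e-5
    colabel_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.mean_count < 0:
            raise ValueError("mean_count must be non-negative")
        if any(b < 0 for b in self.brightness.values()):
            raise ValueError("brightness must be non-negative")
        if not (0 <= self.triplet_fraction < 1):
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.triplet_time <= 0:
            raise ValueError("triplet time must be positive")


@dataclass
class IntensityTrace:
    """Binned photon counts per channel."""

    bin_width: float
    counts: dict  # channel name -> integer array
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lengths = {len(c) for c in self.counts.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        for name, c in self.counts.items():
            arr = np.asarray(c)
            if np.any(arr < 0):
                raise ValueError(f"negative counts in channel {name}")
            self.counts[name] = arr

    @property
    def channel_names(self) -> list:
        return list(self.counts)

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.counts.values())))

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def mean_rate_khz(self) -> dict:
        """Mean count rate per channel in kHz."""
        return {ch: float(np.mean(c)) / self.bin_width / 1e3 for ch, c in self.counts.items()}


def _collect_channels(species: Sequence[DiffusingSpecies], channels) -> list:
    if channels is not None:
        return list(channels)
    seen: list = []
    for sp in species:
        for ch in sp.brightness:
            if ch not in seen:
                seen.append(ch)
    return seen or ["g"]


def simulate_trace(
    species: Sequence[DiffusingSpecies],
    volume: DetectionVolume,
    box: float | None = None,
    bin_width: float = 2e-6,
    duration: float = 10.0,
    seed: int = 0,
    channels: Sequence[str] | None = None,
    bleach_decay: float = 0.0,
    chunk_bins: int = 50_000,
) -> IntensityTrace:
    """Brownian-dynamics photon trace through a Gaussian detection volume.

    Particle displacements per bin have per-axis variance ``2 D bin_width``;
    positions wrap periodically in a cube of edge ``box`` (default 12 w0)
    centred on the detection volume.  The per-bin expected count is the sum
    over bright particles of ``brightness * W(x, y, z) * bin_width`` with
    detection weight ``W = exp(-2(x^2+y^2)/w0^2 - 2 z^2/z0^2)``; emitted
    counts are Poisson draws.  ``bleach_decay`` optionally applies a linear
    intensity decay (fraction of the initial rate lost over the record) for
    QC testing.
    """
    if duration <= 0 or bin_width <= 0:
        raise ValueError("duration and bin_width must be positive")
    if box is None:
        box = 12.0 * volume.w0
    if box < 10.0 * volume.w0:
        raise ValueError("box edge must be at least 10 w0")
    fast = [sp for sp in species if sp.D > 0]
    if fast:
        guard = min(volume.w0 ** 2 / (20.0 * sp.D) for sp in fast)
        if bin_width > guard:
            warnings.warn(
                f"bin_width {bin_width:g}s exceeds temporal-resolution guard {guard:g}s",
                stacklevel=2,
            )
    ch_names = _collect_channels(species, channels)
    n_bins = int(round(duration / bin_width))
    rng = np.random.default_rng(seed)

    # group co-labeled species onto shared particle positions
    groups: dict = {}
    for idx, sp in enumerate(species):
        key = sp.colabel_id if sp.colabel_id is not None else f"__solo_{idx}"
        groups.setdefault(key, []).append(sp)

    rate = {ch: np.zeros(n_bins) for ch in ch_names}
    half = box / 2.0
    for members in groups.values():
        counts_m = {m.mean_count for m in members}
        if len(counts_m) > 1:
            raise ValueError("co-labeled species must share mean_count")
        n_p = int(round(members[0].mean_count))
        if n_p == 0:
            continue
        D = members[0].D
        if any(m.D != D for m in members):
            raise ValueError("co-labeled species must share D (they co-diffuse)")
        pos = rng.uniform(-half, half, size=(n_p, 3))
        sigma_step = np.sqrt(2.0 * D * bin_width)
        # independent blinking state per member species
        states = []
        for m in members:
            T = m.triplet_fraction
            bright0 = rng.random(n_p) >= T
            states.append(bright0.astype(float))
        keep_p = [np.exp(-bin_width / m.triplet_time) for m in members]

        # cap chunk memory: ~2e6 particle-bin elements per array
        chunk = min(chunk_bins, max(1000, 2_000_000 // max(n_p, 1)))
        start = 0
        while start < n_bins:
            stop = min(start + chunk, n_bins)
            nb = stop - start
            if D > 0:
                steps = rng.normal(0.0, sigma_step, size=(nb, n_p, 3))
                traj = pos[None, :, :] + np.cumsum(steps, axis=0)
                pos = traj[-1]
                pos -= box * np.round(pos / box)  # keep the anchor wrapped
                traj -= box * np.round(traj / box)
            else:
                traj = np.broadcast_to(pos, (nb, n_p, 3))
            w = np.exp(
                -2.0 * (traj[..., 0] ** 2 + traj[..., 1] ** 2) / volume.w0 ** 2
                - 2.0 * traj[..., 2] ** 2 / volume.z0 ** 2
            )
            for m, st, keep in zip(members, states, keep_p):
                T = m.triplet_fraction
                if T > 0:
                    # exact per-bin update of the two-state chain: keep the
                    # current state with prob. e^{-dt/tau_T}, else resample
                    # from the stationary law
                    resample = rng.random((nb, n_p)) >= keep
                    fresh = (rng.random((nb, n_p)) >= T).astype(float)
                    bright = np.empty((nb, n_p))
                    cur = st
                    for t in range(nb):  # sequential dependence, cheap in nb
                        cur = np.where(resample[t], fresh[t], cur)
                        bright[t] = cur
                    st[:] = cur
                    weff = w * bright
                else:
                    weff = w
                for ch, b in m.brightness.items():
                    if b > 0 and ch in rate:
                        rate[ch][start:stop] += b * 1e3 * weff.sum(axis=1)
            start = stop

    counts = {}
    decay = 1.0 - bleach_decay * (np.arange(n_bins) / max(n_bins - 1, 1)) if bleach_decay else 1.0
    for ch in ch_names:
        lam = rate[ch] * bin_width * decay
        counts[ch] = rng.poisson(lam)
    return IntensityTrace(bin_width=bin_width, counts=counts, seed=seed)


def analytic_correlation(model: FcsModel, lags) -> CorrelationCurve:
    """Evaluate the forward correlation model on a lag grid as a curve."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be strictly positive and increasing")
    return CorrelationCurve(lags=lags, G=fcs_correlation(model, lags))


def add_curve_noise(curve: CorrelationCurve, sigma_model, seed: int = 0) -> CorrelationCurve:
    """Add independent Gaussian noise per lag and record sigma on the curve.

    ``sigma_model`` may be a scalar, an array matching the lags, or a
    callable ``sigma(lags) -> array``.
    """
    if callable(sigma_model):
        sigma = np.asarray(sigma_model(curve.lags), dtype=float)
    else:
        sigma = np.broadcast_to(np.asarray(sigma_model, dtype=float), curve.lags.shape).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = np.where(sigma > 0, rng.normal(0.0, np.where(sigma > 0, sigma, 1.0)), 0.0)
    return CorrelationCurve(
        lags=curve.lags.copy(),
        G=curve.G + noise,
        sigma=sigma,
        pair=curve.pair,
        n_averaged=curve.n_averaged,
        mean_intensity=dict(curve.mean_intensity),
    )
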