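"""Readers and writers for the project's plain-text interchange formats.

* intensity traces: CSV with columns ``time_s, counts_<channel>`` plus a
  JSON metadata sidecar (bin width, seed, detection volume, species);
* correlation curves: CSV with columns ``lag_s, G, sigma``;
* sedimentation-velocity scan sets: CSV matrix whose first column is
  ``radius_cm`` and remaining columns the signal at each scan time, plus a
  JSON metadata sidecar (rotor speed, solvent, noise, seed).

All round-trips are bit-exact up to float formatting (full precision is
written).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .correlate import CorrelationCurve
from .fluctsim import IntensityTrace
from .sedsim import Solvent, SVExperiment

__all__ = [
    "write_trace", "read_trace",
    "write_curve", "read_curve",
    "write_sv", "read_sv",
]


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_trace(trace: IntensityTrace, path, metadata: Optional[dict] = None) -> None:
    n = trace.n_bins
    data = {"time_s": np.arange(n) * trace.bin_width}
    for ch in trace.channel_names:
        data[f"counts_{ch}"] = np.asarray(trace.counts[ch], dtype=int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    meta = {"bin_width": trace.bin_width, "seed": trace.seed,
            "channels": trace.channel_names}
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> IntensityTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text())
    counts = {
        col[len("counts_"):]: df[col].to_numpy(dtype=int)
        for col in df.columns if col.startswith("counts_")
    }
    return IntensityTrace(bin_width=float(meta["bin_width"]), counts=counts,
                          seed=meta.get("seed"))


def write_curve(curve: CorrelationCurve, path) -> None:
    df = pd.DataFrame({
        "lag_s": curve.lags,
        "G": curve.G,
        "sigma": curve.sigma if curve.sigma is not None else np.full_like(curve.lags, np.nan),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"pair": list(curve.pair), "n_averaged": curve.n_averaged,
            "mean_intensity": curve.mean_intensity}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    sigma = df["sigma"].to_numpy()
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return CorrelationCurve(
        lags=df["lag_s"].to_numpy(),
        G=df["G"].to_numpy(),
        sigma=None if np.all(np.isnan(sigma)) else sigma,
        pair=tuple(meta.get("pair", ("g", "g"))),
        n_averaged=int(meta.get("n_averaged", 1)),
        mean_intensity=meta.get("mean_intensity", {}),
    )


def write_sv(exp: SVExperiment, path) -> None:
    cols = {"radius_cm": exp.radii}
    for k, t in enumerate(exp.times):
        cols[f"t_{t:.6g}"] = exp.signal[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "omega_rad_s": exp.omega,
        "times_s": [float(t) for t in exp.times],
        "solvent": {"density": exp.solvent.density,
                    "viscosity": exp.solvent.viscosity,
                    "temperature": exp.solvent.temperature},
        "noise_sigma": exp.noise_sigma,
        "seed": exp.seed,
        "meta": exp.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_sv(path) -> SVExperiment:
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(_sidecar(path).read_text())
    radii = df["radius_cm"].to_numpy()
    signal = df[[c for c in df.columns if c.startswith("t_")]].to_numpy().T
    sol = meta["solvent"]
    return SVExperiment(
        radii=radii,
        times=np.asarray(meta["times_s"], dtype=float),
        signal=signal,
        omega=float(meta["omega_rad_s"]),
        solvent=Solvent(**sol),
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
        seed=meta.get("seed"),
        meta=meta.get("meta", {}),
    )
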