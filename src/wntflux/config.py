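"""Run configuration: defaults for both pipelines, JSON round-trip, seeds.

All randomness in a pipeline run flows from one root seed via named
substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .models import DetectionVolume
from .sedsim import DEFAULT_RPM, Solvent

__all__ = ["RunConfig", "substream_seed", "substream_rng"]


def substream_seed(root_seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic named substream of a root seed."""
    return np.random.SeedSequence([int(root_seed), zlib.crc32(name.encode())])


def substream_rng(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(root_seed, name))


@dataclass
class RunConfig:
    seed: int = 0
    # confocal calibration (the instrument class default; config-overridable)
    w0: float = 0.2  # um
    structure_param: float = 5.0
    # windowed brightness analysis
    window_length: float = 10.0  # s
    cpm_threshold: float = 7.0  # kHz per molecule
    cpm_bin_width: float = 3.5  # kHz per molecule
    # sedimentation defaults
    rpm: float = DEFAULT_RPM
    meniscus: float = 6.0  # cm
    base: float = 7.2  # cm
    n_radii: int = 400
    scan_interval: float = 300.0  # s
    n_scans: int = 40
    sv_noise_sigma: float = 0.01  # fraction of unit total loading
    vbar: float = 0.73  # mL/g
    solvent: Solvent = field(default_factory=Solvent)
    output_dir: str = "results"

    @property
    def volume(self) -> DetectionVolume:
        return DetectionVolume.from_structure_param(self.w0, self.structure_param)

    @property
    def radii(self) -> np.ndarray:
        return np.linspace(self.meniscus, self.base, self.n_radii)

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.n_scans + 1) * self.scan_interval

    def to_json(self, path=None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["solvent"] = Solvent(**d["solvent"])
        return cls(**d)

    def config_hash(self) -> str:
        return f"{zlib.crc32(self.to_json().encode()):08x}"
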