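"""Confocal detection geometry and the multi-component FCS diffusion model.

The fluorescence autocorrelation of freely diffusing emitters detected
through a 3D-Gaussian confocal volume decays, per diffusing component, as

    g_i(tau) = (1 + tau/tau_i)^(-1) * (1 + tau/(s^2 tau_i))^(-1/2)

where ``tau_i`` is the lateral diffusion time of component *i* and
``s = z0/w0`` the axial-to-lateral aspect ratio of the detection volume.
The full model with ``n`` components and a fast dark-state (triplet) term is

    G(tau) = 1 + (1/N) * T(tau) * sum_i F_i g_i(tau)
    T(tau) = 1 + (T_f/(1 - T_f)) * exp(-tau/tau_T)

with ``N`` the mean particle number in the effective volume
``V_eff = pi^{3/2} w0^2 z0``, fractions ``F_i`` summing to one, triplet
fraction ``T_f`` and triplet relaxation time ``tau_T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectionVolume", "FcsModel", "fcs_correlation"]


@dataclass(frozen=True)
class DetectionVolume:
    """3D-Gaussian confocal detection volume.

    Parameters
    ----------
    w0 : float
        Lateral 1/e^2 radius in micrometres.
    z0 : float
        Axial 1/e^2 half-length in micrometres.
    """

    w0: float = 0.2
    z0: float = 1.0

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.z0 <= 0:
            raise ValueError("w0 and z0 must be positive")

    @property
    def structure_param(self) -> float:
        """Aspect ratio s = z0/w0 of the detection volume."""
        return self.z0 / self.w0

    @property
    def v_eff(self) -> float:
        """Effective volume pi^{3/2} w0^2 z0 in cubic micrometres.

        Defined so that the correlation amplitude of a single species obeys
        G(0) - 1 = 1/(C * v_eff) for concentration C.
        """
        return float(np.pi ** 1.5 * self.w0 ** 2 * self.z0)

    @classmethod
    def from_structure_param(cls, w0: float, structure_param: float) -> "DetectionVolume":
        return cls(w0=w0, z0=w0 * structure_param)


@dataclass
class FcsModel:
    """Parameters of the multi-component diffusion + triplet model.

    ``tau`` must be strictly increasing (components ordered fast to slow)
    and ``F`` must sum to one.
    """

    N: float
    F: tuple = (1.0,)
    tau: tuple = (1e-4,)
    structure_param: float = 5.0
    triplet_T: float = 0.0
    triplet_tau: float = 1e-5
    strict_tau1_axial: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.F = tuple(float(f) for f in np.atleast_1d(self.F))
        self.tau = tuple(float(t) for t in np.atleast_1d(self.tau))
        if self.N <= 0:
            raise ValueError("N must be positive")
        if len(self.F) != len(self.tau):
            raise ValueError("F and tau must have equal length")
        if not np.isclose(sum(self.F), 1.0, atol=1e-8):
            raise ValueError(f"fractions must sum to 1, got {sum(self.F)}")
        if any(t <= 0 for t in self.tau):
            raise ValueError("diffusion times must be positive")
        if any(b <= a for a, b in zip(self.tau, self.tau[1:])):
            raise ValueError("diffusion times must be strictly increasing")
        if not (0 <= self.triplet_T < 1):
            raise ValueError("triplet fraction must be in [0, 1)")
        if self.triplet_tau <= 0:
            raise ValueError("triplet time must be positive")
        if self.structure_param <= 0:
            raise ValueError("structure parameter must be positive")

    @property
    def n_components(self) -> int:
        return len(self.tau)

    @property
    def amplitude(self) -> float:
        """Diffusion amplitude G(0+) - 1 with the triplet term excluded."""
        return 1.0 / self.N

    def __call__(self, lags) -> np.ndarray:
        return fcs_correlation(self, lags)


def fcs_correlation(model: FcsModel, lags) -> np.ndarray:
    """Evaluate the model correlation function G(tau) on ``lags`` (seconds).

    The axial factor uses tau_i per component by default; with
    ``strict_tau1_axial`` the axial time is pinned to the fastest component
    for every component (a published variant of the same model family).
    """
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be non-negative")
    s2 = model.structure_param ** 2
    g = np.zeros_like(tau)
    for F_i, tau_i in zip(model.F, model.tau):
        tau_ax = model.tau[0] if model.strict_tau1_axial else tau_i
        g += F_i / ((1.0 + tau / tau_i) * np.sqrt(1.0 + tau / (s2 * tau_ax)))
    trip = 1.0
    if model.triplet_T > 0:
        T = model.triplet_T
        trip = 1.0 + (T / (1.0 - T)) * np.exp(-tau / model.triplet_tau)
    return 1.0 + (1.0 / model.N) * trip * g
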