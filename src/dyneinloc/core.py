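"""Parameter containers and the Machin number.

Units are fixed to the pN / μm / s system throughout the package:
flexural rigidity κ in pN·μm², normal drag coefficient ξₙ in pN·s/μm²,
forces in pN, lengths in μm, time in s.  SI converters live at the I/O
boundary (:mod:`dyneinloc.io`), never inside the mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MechanicalParams",
    "WaveSpec",
    "InvalidParameterError",
    "GridError",
    "ModelInconsistencyError",
    "machin_number",
    "chlamydomonas_defaults",
]


class InvalidParameterError(ValueError):
    """A mechanical or wave parameter violates its physical constraints."""


class GridError(ValueError):
    """A sampling grid is unusable (non-uniform, too coarse, mismatched)."""


class ModelInconsistencyError(RuntimeError):
    """Input data are inconsistent with the traveling-wave force-balance model."""


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical parameters of the axoneme.

    Parameters
    ----------
    kappa : float
        Flexural rigidity κ of the whole axoneme, pN·μm².  Intact axonemes
        measure around 800 pN·μm².
    xi_n : float
        Normal (perpendicular) drag coefficient per unit length ξₙ,
        pN·s/μm², from resistive-force theory.
    a : float
        Moment arm converting a dynein's axial force into a bending moment,
        μm.  Comparable to the inter-doublet spacing, ~0.03 μm.
    delta : float
        Axial spacing of outer-arm dyneins along a doublet, μm (24 nm).
    F : float
        Single-dynein force magnitude, pN (outer arms generate up to 5 pN).
    L : float
        Axoneme length, μm.
    """

    kappa: float
    xi_n: float
    a: float
    delta: float
    F: float
    L: float

    def __post_init__(self) -> None:
        for name in ("kappa", "xi_n", "a", "delta", "F", "L"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if self.delta > self.L:
            raise InvalidParameterError(
                f"dynein spacing delta={self.delta} μm exceeds axoneme length L={self.L} μm"
            )
        if not self.a < 0.2:
            raise InvalidParameterError(
                f"moment arm a={self.a} μm must be below 0.2 μm (sub-diameter scale)"
            )

    @property
    def force_density(self) -> float:
        """Force density f = F/δ of a fully active row of dyneins, pN/μm."""
        return self.F / self.delta


@dataclass(frozen=True)
class WaveSpec:
    """A base-to-tip traveling sinusoid y(x,t) = y₀ sin[2π(x/λ − νt) + φ₀].

    ``lam`` is the wavelength λ (μm), ``nu`` the temporal frequency ν (Hz),
    ``y0`` the amplitude (μm) and ``phi0`` a spatial phase offset (rad).
    The wave speed is λν, directed from base to tip.
    """

    lam: float
    nu: float = 0.0
    y0: float = 1.0
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lam > 0) or not math.isfinite(self.lam):
            raise InvalidParameterError(f"wavelength lam must be > 0, got {self.lam!r}")
        if self.nu < 0 or not math.isfinite(self.nu):
            raise InvalidParameterError(f"frequency nu must be >= 0, got {self.nu!r}")
        if self.y0 < 0 or not math.isfinite(self.y0):
            raise InvalidParameterError(f"amplitude y0 must be >= 0, got {self.y0!r}")

    @property
    def k(self) -> float:
        """Spatial angular wavenumber 2π/λ, rad/μm."""
        return 2.0 * math.pi / self.lam

    @property
    def speed(self) -> float:
        """Wave speed λν, μm/s (base to tip)."""
        return self.lam * self.nu


def machin_number(params: MechanicalParams, wave: WaveSpec) -> float:
    """Machin number Ma = ν ξₙ λ⁴ / ((2π)³ κ).

    The dimensionless ratio of the hydrodynamic (viscous) to elastic moment
    densities for a traveling wave of wavelength λ and frequency ν.  Ma ≪ 1
    means elasticity dominates (short, slow waves on a stiff axoneme); Ma ≫ 1
    means drag dominates.
    """
    if not isinstance(params, MechanicalParams):
        raise TypeError("params must be a MechanicalParams")
    if not isinstance(wave, WaveSpec):
        raise TypeError("wave must be a WaveSpec")
    return wave.nu * params.xi_n * wave.lam**4 / ((2.0 * math.pi) ** 3 * params.kappa)


def chlamydomonas_defaults(xi_n: float, L: float = 10.0) -> MechanicalParams:
    """Default parameter fixture: a=0.03 μm, F=5 pN, δ=0.024 μm, κ=800 pN·μm².

    ξₙ has no single canonical value (it depends on medium viscosity and
    geometry) and must be supplied explicitly.  L defaults to 10 μm, the
    scale of a Chlamydomonas cilium.
    """
    return MechanicalParams(kappa=800.0, xi_n=xi_n, a=0.03, delta=0.024, F=5.0, L=L)
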