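"""Closed-form traveling-wave solutions of the moment-density balance.

For an infinitely long axoneme the balance a ∂f/∂x = −ξₙ ∂y/∂t − κ ∂⁴y/∂x⁴
admits the traveling-wave pair

    y(x,t) = y₀ sin[2π(x/λ − νt)]
    f(x,t) = f₀ sin[2π(x/λ − νt) + φ]

with phase φ = arctan(1/Ma) and amplitude f₀ = (y₀ κ k³ / a) √(1 + Ma²),
k = 2π/λ.  (The amplitude follows by substituting the sinusoids into the
balance and matching the sin and cos components; the tests verify this
symbolically.)  φ > 0 means the force leads the amplitude in space; the
curvature C = −k²y lags the force in time by π − φ, running from π/2 in the
elastic limit (Ma → 0) to π in the drag limit (Ma → ∞).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GridError, InvalidParameterError, MechanicalParams, WaveSpec, machin_number
from .continuum import ForceField, WaveformField

__all__ = [
    "PhaseResult",
    "force_phase",
    "curvature_lag",
    "ma_from_phase",
    "force_amplitude",
    "analytic_pair",
]


@dataclass(frozen=True)
class PhaseResult:
    """Phase relations of a traveling wave at Machin number ``Ma``.

    ``phi`` is the spatial phase by which the force leads the amplitude
    (rad); ``curvature_lag`` = π − φ is the temporal phase by which the
    curvature lags the force (rad).
    """

    Ma: float
    phi: float
    curvature_lag: float

    @classmethod
    def from_ma(cls, Ma: float) -> "PhaseResult":
        return cls(Ma=Ma, phi=force_phase(Ma), curvature_lag=curvature_lag(Ma))


def force_phase(Ma: float) -> float:
    """Phase φ = arctan(1/Ma) by which the force leads the amplitude, rad.

    φ = π/2 in the elastic limit Ma = 0 and decreases monotonically toward 0
    as drag comes to dominate.
    """
    if Ma < 0 or not math.isfinite(Ma):
        raise InvalidParameterError(f"Machin number must be >= 0, got {Ma!r}")
    if Ma == 0:
        return math.pi / 2
    return math.atan(1.0 / Ma)


def curvature_lag(Ma: float) -> float:
    """Temporal phase π − arctan(1/Ma) by which curvature lags the force, rad.

    π/2 in the elastic limit, 3π/4 (135°) at Ma = 1, approaching π in the
    drag-dominated limit.
    """
    return math.pi - force_phase(Ma)


def ma_from_phase(phi: float) -> float:
    """Machin number from the force-leads-amplitude phase: Ma = 1/tan(φ).

    Exact inverse of :func:`force_phase` on φ ∈ (0, π/2].
    """
    if not (0.0 < phi <= math.pi / 2) or not math.isfinite(phi):
        raise InvalidParameterError(
            f"phase must lie in (0, pi/2] for a traveling-wave solution, got {phi!r}"
        )
    if phi == math.pi / 2:
        return 0.0
    return 1.0 / math.tan(phi)


def force_amplitude(wave: WaveSpec, params: MechanicalParams) -> float:
    """Force-density amplitude f₀ = (y₀ κ k³ / a) √(1 + Ma²), pN/μm."""
    Ma = machin_number(params, wave)
    return wave.y0 * params.kappa * wave.k**3 / params.a * math.sqrt(1.0 + Ma**2)


def analytic_pair(
    wave: WaveSpec,
    params: MechanicalParams,
    nx_per_wavelength: int = 128,
    nt_per_period: int = 32,
    n_wavelengths: int = 1,
    n_periods: int = 1,
) -> tuple[WaveformField, ForceField]:
    """Sampled traveling-wave (waveform, force) pair satisfying the balance.

    The grids are periodic: x covers ``n_wavelengths`` wavelengths at
    ``nx_per_wavelength`` points each (endpoint excluded), and t covers
    ``n_periods`` beat periods at ``nt_per_period`` frames each (for ν = 0 a
    single static frame is returned).
    """
    if nx_per_wavelength < 16:
        raise GridError(
            f"need at least 16 points per wavelength, got {nx_per_wavelength}"
        )
    if n_wavelengths < 1 or n_periods < 1:
        raise GridError("domain must cover at least one wavelength and one period")
    nx = nx_per_wavelength * n_wavelengths
    x = np.linspace(0.0, n_wavelengths * wave.lam, nx, endpoint=False)
    if wave.nu > 0:
        nt = nt_per_period * n_periods
        t = np.linspace(0.0, n_periods / wave.nu, nt, endpoint=False)
        periodic_t = nt >= 3
    else:
        t = np.zeros(1)
        periodic_t = False
    Ma = machin_number(params, wave)
    phi = force_phase(Ma)
    f0 = force_amplitude(wave, params)
    arg = 2.0 * np.pi * (x[None, :] / wave.lam - wave.nu * t[:, None]) + wave.phi0
    y = wave.y0 * np.sin(arg)
    f = f0 * np.sin(arg + phi)
    w = WaveformField(x=x, t=t, y=y, periodic_in_x=True, periodic_in_t=periodic_t)
    g = ForceField(x=x, t=t, f=f, periodic_in_x=True)
    return w, g
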