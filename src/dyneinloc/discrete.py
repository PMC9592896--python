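"""Mechanics of one or a few discrete dyneins.

A single active dynein contributes a point bending moment of magnitude aF
(moment arm a, axial force F).  Two dyneins on opposite sides of the
axoneme and at different axial positions sandwich a region of constant
moment M = aF, which — through the Euler–Bernoulli beam relation M = −κC —
produces a bend strictly between them; the curvature outside the pair is
zero.  A pair of adjacent dyneins on the *same* side with unequal forces
produces a net normal force a·ΔF/δ that can balance hydrodynamic drag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import GridError, InvalidParameterError
from ._numerics import check_uniform

__all__ = [
    "DyneinPairScenario",
    "MomentProfile",
    "pair_moment_profile",
    "shape_from_moment",
    "pair_bend",
    "normal_force_from_pair",
    "cumulative_moment",
]


@dataclass(frozen=True)
class DyneinPairScenario:
    """Two active dyneins on opposite sides of the axoneme.

    ``x_left`` is the axial position (μm) of the DM6-9-side dynein (positive
    moment), ``x_right`` that of the DM1-4-side dynein (negative moment);
    ``F_left``/``F_right`` are the force magnitudes in pN.
    """

    x_left: float
    x_right: float
    F_left: float
    F_right: float

    def __post_init__(self) -> None:
        if self.F_left < 0 or self.F_right < 0:
            raise InvalidParameterError("dynein force magnitudes must be >= 0")
        if self.x_right < self.x_left:
            raise InvalidParameterError(
                "x_left (DM6-9 side) must not exceed x_right (DM1-4 side); "
                "the bend-forming configuration has the positive moment proximal"
            )


@dataclass(frozen=True)
class MomentProfile:
    """Bending moment M(x) (pN·μm) sampled on a uniform spatial grid (μm)."""

    x: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        check_uniform(self.x, "x")
        if np.asarray(self.M).shape != np.asarray(self.x).shape:
            raise GridError("M must have the same shape as x")


def pair_moment_profile(
    scenario: DyneinPairScenario, a: float, x: np.ndarray, L: float | None = None
) -> MomentProfile:
    """Integrated bending moment of a dynein pair along the axoneme.

    M(x) is piecewise constant: zero proximal to both motors, jumping by
    +a·F_left at ``x_left`` and by −a·F_right at ``x_right`` (each jump
    placed on the nearest grid node).  For equal forces the moment is a·F
    between the motors and zero distal to both.
    """
    if a <= 0:
        raise InvalidParameterError(f"moment arm a must be > 0, got {a}")
    x = np.asarray(x, dtype=float)
    check_uniform(x, "x")
    lo, hi = x[0], x[-1] if L is None else L
    for pos, name in ((scenario.x_left, "x_left"), (scenario.x_right, "x_right")):
        if pos < min(lo, 0.0) - 1e-12 or pos > hi + 1e-12:
            raise InvalidParameterError(f"{name}={pos} μm lies outside [0, {hi}] μm")
    i_left = int(np.argmin(np.abs(x - scenario.x_left)))
    i_right = int(np.argmin(np.abs(x - scenario.x_right)))
    M = np.zeros_like(x)
    M[i_left:] += a * scenario.F_left
    M[i_right:] -= a * scenario.F_right
    return MomentProfile(x=x, M=M)


def shape_from_moment(profile: MomentProfile, kappa: float) -> np.ndarray:
    """Shape y(x) of a clamped-base beam carrying moment profile M(x).

    Curvature follows the beam equation C = −M/κ; the shape is the double
    cumulative (trapezoidal) integral of C with clamped base, y(0) = y′(0) = 0.
    The curvature is exactly zero wherever M is zero.
    """
    if kappa <= 0:
        raise InvalidParameterError(f"flexural rigidity kappa must be > 0, got {kappa}")
    C = -np.asarray(profile.M, dtype=float) / kappa
    slope = cumulative_trapezoid(C, profile.x, initial=0.0)
    return cumulative_trapezoid(slope, profile.x, initial=0.0)


def pair_bend(
    scenario: DyneinPairScenario, a: float, kappa: float, x: np.ndarray, L: float | None = None
) -> tuple[MomentProfile, np.ndarray]:
    """Moment profile and static bend shape of a balanced dynein pair.

    Only balanced pairs (F_left == F_right) are admitted here: an unbalanced
    pair leaves a residual moment distal to both motors, which in statics
    produces rigid-body rotation rather than a well-defined bend.
    """
    if not np.isclose(scenario.F_left, scenario.F_right):
        raise InvalidParameterError(
            "static bend shapes are only defined for balanced pairs "
            "(F_left == F_right); unbalanced moments lead to rotations"
        )
    profile = pair_moment_profile(scenario, a, x, L)
    return profile, shape_from_moment(profile, kappa)


def normal_force_from_pair(F1: float, F2: float, a: float, delta: float) -> float:
    """Net normal force from two adjacent same-side dyneins: a·(F2 − F1)/δ, pN.

    Equal forces give zero; a gradient of motor force along the doublet
    produces a transverse force that can balance hydrodynamic drag.
    """
    if delta <= 0:
        raise InvalidParameterError(f"dynein spacing delta must be > 0, got {delta}")
    return a * (F2 - F1) / delta


def cumulative_moment(f: np.ndarray, a: float, x: np.ndarray) -> MomentProfile:
    """Bending moment M(x) = ∫₀ˣ a·f(x′) dx′ of a force-density field.

    Trapezoidal cumulative integral from the base; M(0) = 0.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    check_uniform(x, "x")
    if f.shape != x.shape:
        raise GridError("f must be sampled on the same grid as x")
    M = cumulative_trapezoid(a * f, x, initial=0.0)
    return MomentProfile(x=x, M=M)
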