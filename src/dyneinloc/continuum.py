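"""Continuum force balance on the beating axoneme.

The differential force density f(x,t) (pN/μm) is the per-length dynein force
on the DM6-9 side minus the DM1-4 side; positive f means DM6-9 dominates.
Three balances are implemented, all in the small-amplitude limit where the
curvature is C ≅ ∂²y/∂x²:

* static:         a f        = −κ ∂³y/∂x³          (elasticity only)
* hydrodynamic:   a ∂f/∂x    = −ξₙ ∂y/∂t           (drag only)
* full balance:   a ∂f/∂x    = −ξₙ ∂y/∂t − κ ∂⁴y/∂x⁴

The full balance is the moment-density statement m_motors + m_drag +
m_elastic = 0; its residual is the package's model-consistency check.

Spatial derivatives are spectral on periodic grids and 4th-order-accurate
finite differences (with one-sided closures) otherwise; the temporal
derivative is spectral when the time grid covers whole periods and
2nd-order central differences otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import GridError, MechanicalParams
from ._numerics import (
    check_uniform,
    fd_derivative,
    spectral_antiderivative,
    spectral_derivative,
)

__all__ = [
    "WaveformField",
    "ForceField",
    "curvature_field",
    "static_force_density",
    "hydrodynamic_force_density",
    "machin_residual",
]

#: |∂y/∂x| above which the small-amplitude approximation C ≅ y″ degrades.
SLOPE_WARN_THRESHOLD = 0.3


def _validate_field(x, t, values, name):
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    v = np.asarray(values, dtype=float)
    check_uniform(x, "x")
    if t.ndim != 1 or t.size < 1:
        raise GridError("t must be 1-D with at least one sample")
    if t.size > 1:
        check_uniform(t, "t")
    if v.shape != (t.size, x.size):
        raise GridError(
            f"{name} must have shape (nt, nx) = ({t.size}, {x.size}), got {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise GridError(f"{name} must be finite everywhere")
    return x, t, v


@dataclass(frozen=True)
class WaveformField:
    """Transverse amplitude y(x,t) (μm) sampled on a uniform (x,t) grid.

    ``y`` has shape (nt, nx): row i is the spatial profile at time t[i].
    ``periodic_in_x`` declares that the spatial domain covers an integer
    number of wavelengths with the endpoint excluded (x spans [x0, x0 + nx·h));
    ``periodic_in_t`` likewise for whole temporal periods.
    """

    x: np.ndarray
    t: np.ndarray
    y: np.ndarray
    periodic_in_x: bool = False
    periodic_in_t: bool = False

    def __post_init__(self) -> None:
        x, t, y = _validate_field(self.x, self.t, self.y, "y")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def x_period(self) -> float:
        """Domain length for spectral transforms (endpoint excluded)."""
        return self.x.size * self.dx

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise GridError("time grid has a single sample; no time step defined")
        return float(self.t[1] - self.t[0])

    def x_derivative(self, order: int) -> np.ndarray:
        if self.periodic_in_x:
            return spectral_derivative(self.y, self.x_period, order, axis=1)
        if self.x.size < 8:
            raise GridError("need at least 8 spatial samples for derivatives")
        return fd_derivative(self.y, self.dx, order, axis=1)

    def t_derivative(self) -> np.ndarray:
        if self.t.size < 3:
            raise GridError("need at least 3 time samples for a temporal derivative")
        if self.periodic_in_t:
            t_period = self.t.size * self.dt
            return spectral_derivative(self.y, t_period, 1, axis=0)
        return np.gradient(self.y, self.dt, axis=0)

    def time_slice(self, index: int = 0) -> "WaveformField":
        """Single-frame copy (useful for static analyses)."""
        return WaveformField(
            x=self.x,
            t=self.t[index : index + 1],
            y=self.y[index : index + 1],
            periodic_in_x=self.periodic_in_x,
            periodic_in_t=False,
        )


@dataclass(frozen=True)
class ForceField:
    """Differential force density f(x,t) (pN/μm) on the waveform's grid.

    Positive f means the DM6-9-side dyneins dominate the DM1-4 side.
    """

    x: np.ndarray
    t: np.ndarray
    f: np.ndarray
    periodic_in_x: bool = False

    def __post_init__(self) -> None:
        x, t, f = _validate_field(self.x, self.t, self.f, "f")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def x_period(self) -> float:
        return self.x.size * self.dx


def _check_same_grids(w: WaveformField, g: ForceField) -> None:
    if w.y.shape != g.f.shape or not (
        np.allclose(w.x, g.x) and np.allclose(w.t, g.t)
    ):
        raise GridError("waveform and force fields must share the same (x, t) grid")


def _warn_if_large_slope(w: WaveformField) -> None:
    slope = w.x_derivative(1)
    peak = float(np.max(np.abs(slope)))
    if peak > SLOPE_WARN_THRESHOLD:
        warnings.warn(
            f"max |dy/dx| = {peak:.3f} rad exceeds {SLOPE_WARN_THRESHOLD}; the "
            "small-amplitude approximation C = d2y/dx2 is unreliable",
            stacklevel=3,
        )


def curvature_field(w: WaveformField) -> np.ndarray:
    """Small-amplitude curvature C(x,t) ≅ ∂²y/∂x², 1/μm."""
    _warn_if_large_slope(w)
    return w.x_derivative(2)


def static_force_density(w: WaveformField, params: MechanicalParams) -> ForceField:
    """Force density balancing elasticity alone: f = −(κ/a) ∂³y/∂x³.

    Valid for a static (unmoving) axoneme, where the integrated motor moment
    equals the elastic bending moment −κC at every point.
    """
    if w.x.size < 8:
        raise GridError("need at least 8 spatial samples for the third derivative")
    _warn_if_large_slope(w)
    f = -(params.kappa / params.a) * w.x_derivative(3)
    return ForceField(x=w.x, t=w.t, f=f, periodic_in_x=w.periodic_in_x)


def hydrodynamic_force_density(w: WaveformField, params: MechanicalParams) -> ForceField:
    """Force density balancing drag alone: a ∂f/∂x = −ξₙ ∂y/∂t, integrated in x.

    The balance fixes f only up to a constant per time slice.  On periodic
    domains the constant is set by zero spatial mean; on finite domains f is
    anchored at the base by the static balance f(0) = −(κ/a) y‴(0).
    """
    if w.t.size < 2:
        raise GridError("need at least 2 time samples to form a velocity")
    if w.t.size == 2:
        # central differences need 3 frames; 2 frames give a forward estimate
        dydt = (w.y[1] - w.y[0]) / w.dt * np.ones_like(w.y)
    else:
        dydt = w.t_derivative()
    dfdx = -(params.xi_n / params.a) * dydt
    if w.periodic_in_x:
        f = spectral_antiderivative(dfdx, w.x_period, axis=1)
    else:
        f = cumulative_trapezoid(dfdx, w.x, axis=1, initial=0.0)
        base = -(params.kappa / params.a) * w.x_derivative(3)[:, :1]
        f = f + base
    return ForceField(x=w.x, t=w.t, f=f, periodic_in_x=w.periodic_in_x)


def machin_residual(
    w: WaveformField, g: ForceField, params: MechanicalParams
) -> np.ndarray:
    """Residual of the full moment-density balance, pN/μm².

    Returns a ∂f/∂x + ξₙ ∂y/∂t + κ ∂⁴y/∂x⁴ pointwise; it vanishes exactly
    when (y, f) satisfy the traveling-wave force balance.
    """
    _check_same_grids(w, g)
    if g.periodic_in_x:
        dfdx = spectral_derivative(g.f, g.x_period, 1, axis=1)
    else:
        dfdx = fd_derivative(g.f, g.dx, 1, axis=1)
    dydt = w.t_derivative() if w.t.size >= 3 else np.zeros_like(w.y)
    d4y = w.x_derivative(4)
    return params.a * dfdx + params.xi_n * dydt + params.kappa * d4y
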