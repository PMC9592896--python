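"""Synthetic beating waveforms and worked dynein-pair scenarios.

The generator produces the traveling sinusoids the continuum model assumes —
y = y₀ sin[2π(x/λ − νt) + φ₀] on periodic grids — with optional additive
Gaussian noise, so every analysis stage can be exercised without external
data.  Pair-scenario presets return a discrete two-dynein configuration
together with its closed-form bending-moment profile for use as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridError, InvalidParameterError, MechanicalParams, WaveSpec
from .continuum import WaveformField
from .discrete import DyneinPairScenario, MomentProfile, pair_moment_profile

__all__ = ["NoiseSpec", "generate", "PAIR_PRESETS", "generate_pair_scenario"]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise: standard deviation σ (μm) and seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError(f"noise sigma must be >= 0, got {self.sigma}")


def generate(
    wave: WaveSpec,
    params: MechanicalParams,
    nx_per_wavelength: int = 128,
    nt_per_period: int = 32,
    n_wavelengths: int = 1,
    n_periods: int = 1,
    noise: NoiseSpec | None = None,
) -> WaveformField:
    """Sample a (possibly noisy) traveling sinusoid on a periodic grid.

    Identical arguments (including the noise seed) give bit-identical output;
    randomness comes from a single explicitly seeded generator per call.
    """
    if nx_per_wavelength < 16:
        raise GridError(
            f"need at least 16 points per wavelength, got {nx_per_wavelength}"
        )
    if nt_per_period < 2 and wave.nu > 0:
        raise GridError("need at least 2 frames per period for a moving wave")
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
    arg = 2.0 * np.pi * (x[None, :] / wave.lam - wave.nu * t[:, None]) + wave.phi0
    y = wave.y0 * np.sin(arg)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        y = y + rng.normal(0.0, noise.sigma, size=y.shape)
    return WaveformField(x=x, t=t, y=y, periodic_in_x=True, periodic_in_t=periodic_t)


PAIR_PRESETS = ("opposite_pair", "equal_opposite_same_x", "single_motor_basal")


def generate_pair_scenario(
    preset: str,
    params: MechanicalParams | None = None,
    n_grid: int = 2001,
) -> tuple[DyneinPairScenario, MomentProfile]:
    """A named two-dynein scenario plus its closed-form moment profile.

    Presets (positions on a length-L axoneme, forces F from ``params``;
    defaults a = 0.03 μm, F = 5 pN, κ = 800 pN·μm², L = 10 μm):

    * ``opposite_pair`` — a DM6-9-side dynein at 0.4 L and a DM1-4-side dynein at
      0.6 L with equal forces: moment a·F strictly between them, zero outside.
    * ``equal_opposite_same_x`` — both dyneins at mid-length: the moments
      cancel and the profile is identically zero.
    * ``single_motor_basal`` — one distal dynein with the counter-moment
      supplied by the basal sliding constraint: constant moment a·F from the
      base up to the motor at 0.6 L, zero beyond.
    """
    if params is None:
        from .core import chlamydomonas_defaults

        params = chlamydomonas_defaults(xi_n=1e-3)
    x = np.linspace(0.0, params.L, n_grid)
    if preset == "opposite_pair":
        scenario = DyneinPairScenario(0.4 * params.L, 0.6 * params.L, params.F, params.F)
    elif preset == "equal_opposite_same_x":
        scenario = DyneinPairScenario(0.5 * params.L, 0.5 * params.L, params.F, params.F)
    elif preset == "single_motor_basal":
        scenario = DyneinPairScenario(0.0, 0.6 * params.L, params.F, params.F)
    else:
        raise InvalidParameterError(
            f"unknown preset {preset!r}; available presets: {', '.join(PAIR_PRESETS)}"
        )
    expected = pair_moment_profile(scenario, params.a, x, params.L)
    return scenario, expected
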