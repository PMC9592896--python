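import math

import pytest
from hypothesis import HealthCheck, settings

from dyneinloc import MechanicalParams, WaveSpec, chlamydomonas_defaults

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> MechanicalParams:
    """Chlamydomonas-scale fixture: a=0.03, F=5, delta=0.024, kappa=800, L=10."""
    return chlamydomonas_defaults(xi_n=1e-3)


def nu_for_ma(params: MechanicalParams, lam: float, ma: float) -> float:
    """Frequency that realizes a target Machin number at wavelength lam."""
    return ma * (2.0 * math.pi) ** 3 * params.kappa / (params.xi_n * lam**4)


def wave_at_ma(params: MechanicalParams, ma: float, lam: float = 10.0, y0: float = 0.2) -> WaveSpec:
    return WaveSpec(lam=lam, nu=nu_for_ma(params, lam, ma), y0=y0)
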