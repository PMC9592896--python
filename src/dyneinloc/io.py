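"""File formats and unit conversion at the package boundary.

Waveforms and force fields travel as long-format CSV with fixed column
names (``x_um, t_s, y_um`` and ``x_um, t_s, f_pN_per_um``); parameters and
wave specifications as JSON with explicitly unit-suffixed keys.  Unknown
JSON keys are rejected rather than ignored, so silent unit mistakes fail
loudly.  SI↔(pN, μm, s) converters live here and nowhere else.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GridError, InvalidParameterError, MechanicalParams, WaveSpec
from .continuum import ForceField, WaveformField
from .discrete import MomentProfile

__all__ = [
    "params_from_json", "params_to_json", "wave_from_json", "wave_to_json",
    "waveform_to_dataframe", "waveform_from_dataframe",
    "waveform_to_csv", "waveform_from_csv",
    "force_to_csv", "force_from_csv",
    "moment_profile_to_csv", "shape_to_csv",
    "kappa_from_si", "xi_n_from_si", "force_from_si", "length_from_si",
]

_PARAM_KEYS = {
    "kappa_pN_um2": "kappa",
    "xi_n_pN_s_per_um2": "xi_n",
    "a_um": "a",
    "delta_um": "delta",
    "F_pN": "F",
    "L_um": "L",
}
_WAVE_KEYS = {"lambda_um": "lam", "nu_Hz": "nu", "y0_um": "y0", "phi0_rad": "phi0"}


def _load_mapped(data: dict, keymap: dict[str, str], what: str) -> dict:
    unknown = set(data) - set(keymap)
    if unknown:
        raise InvalidParameterError(
            f"unknown {what} keys: {sorted(unknown)}; expected {sorted(keymap)}"
        )
    missing = set(keymap) - set(data)
    if missing:
        raise InvalidParameterError(f"missing {what} keys: {sorted(missing)}")
    return {field: float(data[key]) for key, field in keymap.items()}


def params_from_json(path) -> MechanicalParams:
    """Read mechanical parameters from JSON (keys kappa_pN_um2, ..., L_um)."""
    data = json.loads(Path(path).read_text())
    return MechanicalParams(**_load_mapped(data, _PARAM_KEYS, "parameter"))


def params_to_json(params: MechanicalParams, path) -> None:
    data = {key: getattr(params, field) for key, field in _PARAM_KEYS.items()}
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def wave_from_json(path) -> WaveSpec:
    """Read a wave specification from JSON (keys lambda_um, nu_Hz, y0_um, phi0_rad)."""
    data = json.loads(Path(path).read_text())
    return WaveSpec(**_load_mapped(data, _WAVE_KEYS, "wave"))


def wave_to_json(wave: WaveSpec, path) -> None:
    data = {key: getattr(wave, field) for key, field in _WAVE_KEYS.items()}
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _field_to_frame(x, t, values, value_col) -> pd.DataFrame:
    tt, xx = np.meshgrid(t, x, indexing="ij")
    return pd.DataFrame(
        {"x_um": xx.ravel(), "t_s": tt.ravel(), value_col: np.asarray(values).ravel()}
    )


def _frame_to_field(df: pd.DataFrame, value_col: str):
    required = {"x_um", "t_s", value_col}
    if not required.issubset(df.columns):
        raise GridError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
    pivot = df.pivot_table(index="t_s", columns="x_um", values=value_col, sort=True)
    if pivot.isna().any().any():
        raise GridError("waveform table is not a complete (x, t) grid")
    return pivot.columns.to_numpy(float), pivot.index.to_numpy(float), pivot.to_numpy(float)


def waveform_to_dataframe(w: WaveformField) -> pd.DataFrame:
    return _field_to_frame(w.x, w.t, w.y, "y_um")


def waveform_from_dataframe(
    df: pd.DataFrame, periodic_in_x: bool = False, periodic_in_t: bool = False
) -> WaveformField:
    x, t, y = _frame_to_field(df, "y_um")
    return WaveformField(x=x, t=t, y=y, periodic_in_x=periodic_in_x, periodic_in_t=periodic_in_t)


def waveform_to_csv(w: WaveformField, path) -> None:
    waveform_to_dataframe(w).to_csv(path, index=False)


def waveform_from_csv(path, periodic_in_x: bool = False, periodic_in_t: bool = False) -> WaveformField:
    return waveform_from_dataframe(
        pd.read_csv(path), periodic_in_x=periodic_in_x, periodic_in_t=periodic_in_t
    )


def force_to_csv(g: ForceField, path) -> None:
    _field_to_frame(g.x, g.t, g.f, "f_pN_per_um").to_csv(path, index=False)


def force_from_csv(path, periodic_in_x: bool = False) -> ForceField:
    x, t, f = _frame_to_field(pd.read_csv(path), "f_pN_per_um")
    return ForceField(x=x, t=t, f=f, periodic_in_x=periodic_in_x)


def moment_profile_to_csv(profile: MomentProfile, path) -> None:
    pd.DataFrame({"x_um": profile.x, "M_pN_um": profile.M}).to_csv(path, index=False)


def shape_to_csv(x: np.ndarray, y: np.ndarray, path) -> None:
    pd.DataFrame({"x_um": x, "y_um": y}).to_csv(path, index=False)


# ---- SI converters (boundary only) ----------------------------------------

def kappa_from_si(kappa_N_m2: float) -> float:
    """Flexural rigidity N·m² → pN·μm²  (1 N·m² = 1e24 pN·μm²)."""
    return kappa_N_m2 * 1e24


def xi_n_from_si(xi_N_s_m2: float) -> float:
    """Drag coefficient N·s/m² → pN·s/μm²  (1 N·s/m² = 1 pN·s/μm²)."""
    return xi_N_s_m2 * 1.0


def force_from_si(F_N: float) -> float:
    """Force N → pN."""
    return F_N * 1e12


def length_from_si(x_m: float) -> float:
    """Length m → μm."""
    return x_m * 1e6
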