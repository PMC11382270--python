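"""Tabular readers/writers and the validated pipeline configuration.

All on-disk formats are plain CSV with JSON sidecars.  Writers emit 17
significant digits so that write -> read round-trips are lossless for
doubles; readers check the header against the expected schema and name
the offending columns on mismatch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .dosy import GradientSeries
from .exchange_cest import ZSpectrum
from .relaxometry import DecaySeries, TemperatureSeries

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "read_decay_series",
    "write_decay_series",
    "read_temperature_series",
    "write_temperature_series",
    "read_zspectrum",
    "write_zspectrum",
    "read_gradient_series",
    "write_gradient_series",
    "read_viscometry",
    "write_viscometry",
    "PipelineConfig",
]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """CSV header does not match the expected schema."""


def read_table(path, schema: list[str]) -> pd.DataFrame:
    """Read a CSV and require its columns to equal ``schema`` exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    got = list(df.columns)
    if got != list(schema):
        missing = [c for c in schema if c not in got]
        extra = [c for c in got if c not in schema]
        raise SchemaError(
            f"{path.name}: header mismatch (missing columns {missing}, "
            f"unexpected columns {extra})")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(".json")


# -- decay curves -----------------------------------------------------------

def write_decay_series(d: DecaySeries, path) -> None:
    write_table(pd.DataFrame({"delay_s": d.abscissa, "intensity": d.intensities}), path)
    _sidecar(path).write_text(json.dumps(
        {"kind": d.kind, "noise_sd": d.noise_sd}, sort_keys=True))


def read_decay_series(path) -> DecaySeries:
    df = read_table(path, ["delay_s", "intensity"])
    meta = json.loads(_sidecar(path).read_text())
    return DecaySeries(abscissa=df["delay_s"].to_numpy(),
                       intensities=df["intensity"].to_numpy(),
                       kind=meta["kind"], noise_sd=meta.get("noise_sd"))


# -- temperature series -----------------------------------------------------

def write_temperature_series(ts: TemperatureSeries, path) -> None:
    write_table(pd.DataFrame({
        "temperature_K": ts.temperatures,
        "value": ts.values,
        "value_kind": [ts.kind] * ts.values.size,
    }), path)


def read_temperature_series(path, phi_dmso: float | None = None) -> TemperatureSeries:
    df = read_table(path, ["temperature_K", "value", "value_kind"])
    kinds = df["value_kind"].unique()
    if kinds.size != 1:
        raise SchemaError(f"{Path(path).name}: mixed value_kind entries {list(kinds)}")
    return TemperatureSeries(df["temperature_K"].to_numpy(), df["value"].to_numpy(),
                             kind=str(kinds[0]), phi_dmso=phi_dmso)


# -- Z-spectra --------------------------------------------------------------

def write_zspectrum(z: ZSpectrum, path) -> None:
    write_table(pd.DataFrame({"offset_ppm": z.offsets, "z_value": z.z_values}), path)
    _sidecar(path).write_text(json.dumps({
        "omega1_hz": z.omega1, "t_ex_s": z.t_ex, "carrier_mhz": z.carrier,
        "seed": z.seed, "noise_sd": z.noise_sd}, sort_keys=True))


def read_zspectrum(path) -> ZSpectrum:
    df = read_table(path, ["offset_ppm", "z_value"])
    meta = json.loads(_sidecar(path).read_text())
    return ZSpectrum(offsets=df["offset_ppm"].to_numpy(),
                     z_values=df["z_value"].to_numpy(),
                     omega1=meta["omega1_hz"], t_ex=meta["t_ex_s"],
                     carrier=meta["carrier_mhz"], seed=meta.get("seed"),
                     noise_sd=meta.get("noise_sd", 0.0))


# -- PFG attenuation --------------------------------------------------------

def write_gradient_series(g: GradientSeries, path) -> None:
    write_table(pd.DataFrame({"gradient_T_per_m": g.gradients,
                              "intensity": g.intensities}), path)
    _sidecar(path).write_text(json.dumps({
        "delta_s": g.delta, "big_delta_s": g.big_delta, "gamma": g.gamma,
        "noise_sd": g.noise_sd}, sort_keys=True))


def read_gradient_series(path) -> GradientSeries:
    df = read_table(path, ["gradient_T_per_m", "intensity"])
    meta = json.loads(_sidecar(path).read_text())
    return GradientSeries(gradients=df["gradient_T_per_m"].to_numpy(),
                          intensities=df["intensity"].to_numpy(),
                          delta=meta["delta_s"], big_delta=meta["big_delta_s"],
                          gamma=meta["gamma"], noise_sd=meta.get("noise_sd"))


# -- viscometry -------------------------------------------------------------

def write_viscometry(table: dict, path) -> None:
    write_table(pd.DataFrame(table["rows"]), path)
    _sidecar(path).write_text(json.dumps({
        "temperature_K": table["temperature_K"],
        "cell_constant_mm2_s2": table["cell_constant_mm2_s2"]}, sort_keys=True))


def read_viscometry(path) -> dict:
    df = read_table(path, ["phi_dmso", "efflux_time_s", "density_g_cm3"])
    meta = json.loads(_sidecar(path).read_text())
    return {"rows": df.to_dict("records"), **meta}


# -- configuration ----------------------------------------------------------

class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r_h_bounds: tuple[float, float] = (2.0, 20.0)
    exchange_enabled: bool = True
    exchange_p_E: float = 0.5
    exchange_delta_ppm: float = 2.3
    kex_log10_A_bounds: tuple[float, float] = (-2.0, 14.0)
    kex_ea_bounds_kj: tuple[float, float] = (1.0, 150.0)
    cest_flag_n_se: float = Field(3.0, gt=0)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str
    output_dir: str
    seed: int = 0
    generate_scenario: bool = False
    B0: float = 11.7
    dosy_temperature: float = 298.0
    viscosity_table: str | None = None   # path to a replacement calibration JSON
    fit: FitOptions = Field(default_factory=FitOptions)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
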