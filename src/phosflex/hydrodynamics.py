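"""Viscometry arithmetic, a binary D2O/DMSO-d6 viscosity model, and
Stokes-Einstein(-Debye) conversions between diffusion, tumbling and size.

The viscometry side is capillary (Ubbelohde) arithmetic: kinematic
viscosity nu = K*t from the cell constant and efflux time, and dynamic
viscosity eta = rho*nu.  Kinetic-energy and end-effect corrections are
omitted (negligible for long efflux times).

The mixture model is Vogel-Fulcher-Tammann (VFT) per endpoint solvent
with Grunberg-Nissan mixing of log-viscosity,

    ln eta(phi, T) = (1-phi) ln eta_w(T) + phi ln eta_d(T) + G phi (1-phi),

the minimal form that is smooth, decreasing in T at fixed phi, and
nonmonotonic in phi with an interior maximum, as water/DMSO mixtures are.
The packaged calibration table is an explicitly synthetic stand-in built
from literature-like endpoint values; swap in a measured table via
:meth:`ViscosityModel.from_json`.

Size conversions (stick boundary):

    d_H  = k_B T / (3 pi eta D)          (Stokes-Einstein, translation)
    tau_c = 4 pi eta r^3 / (3 k_B T)     (Stokes-Einstein-Debye, rotation)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .spin_physics import K_B

__all__ = [
    "MixtureComposition",
    "ViscosityModel",
    "kinematic_viscosity",
    "dynamic_viscosity",
    "mixture_viscosity",
    "stokes_einstein_diameter",
    "diffusion_from_diameter",
    "sed_rotational",
    "sed_radius",
]


@dataclass(frozen=True)
class MixtureComposition:
    """Binary solvent point: DMSO-d6 volume fraction and temperature (K)."""

    phi_dmso: float
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_dmso <= 1.0:
            raise ValueError(f"phi_dmso must be in [0, 1], got {self.phi_dmso}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _vft(T, eta0: float, B: float, T0: float):
    return eta0 * np.exp(B / (np.asarray(T, dtype=float) - T0))


@dataclass(frozen=True)
class ViscosityModel:
    """Binary-mixture dynamic viscosity eta(phi, T) in mPa s.

    Endpoint VFT curves plus one Grunberg-Nissan excess coefficient G.
    ``domain`` bounds (phi, T); evaluation outside raises (never silent
    extrapolation).
    """

    vft_d2o: tuple[float, float, float]
    vft_dmso: tuple[float, float, float]
    G: float
    phi_domain: tuple[float, float] = (0.0, 1.0)
    T_domain: tuple[float, float] = (270.0, 360.0)
    calibration_table: tuple = ()   # ((phi, T, eta_mPa_s), ...)

    @classmethod
    def from_dict(cls, d: dict) -> "ViscosityModel":
        table = ()
        cal = d.get("calibration_table_298K")
        if cal:
            table = tuple((p, 298.0, e) for p, e in zip(cal["phi"], cal["eta_mPa_s"]))
        model = cls(
            vft_d2o=(d["vft_d2o"]["eta0"], d["vft_d2o"]["B"], d["vft_d2o"]["T0"]),
            vft_dmso=(d["vft_dmso"]["eta0"], d["vft_dmso"]["B"], d["vft_dmso"]["T0"]),
            G=d["grunberg_nissan_G"],
            phi_domain=tuple(d["domain"]["phi"]),
            T_domain=tuple(d["domain"]["T"]),
            calibration_table=table,
        )
        model.check_calibration()
        return model

    def check_calibration(self, tol: float = 0.02) -> None:
        """Verify the model reproduces its calibration table within ``tol``."""
        for phi, T, eta_ref in self.calibration_table:
            eta = self.eta(phi, T)
            if abs(eta - eta_ref) > tol * eta_ref:
                raise ValueError(
                    f"viscosity model misses its calibration table at phi={phi}, "
                    f"T={T} K: model {eta:.4f} vs table {eta_ref:.4f} mPa s"
                )

    @classmethod
    def from_json(cls, path) -> "ViscosityModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "ViscosityModel":
        with resources.files("phosflex.data").joinpath("viscosity_d2o_dmso.json").open() as fh:
            return cls.from_dict(json.load(fh))

    def _check_domain(self, phi, T) -> None:
        phi = np.asarray(phi, dtype=float)
        T = np.asarray(T, dtype=float)
        if np.any(phi < self.phi_domain[0]) or np.any(phi > self.phi_domain[1]):
            raise ValueError(f"phi outside model domain {self.phi_domain}")
        if np.any(T < self.T_domain[0]) or np.any(T > self.T_domain[1]):
            raise ValueError(f"T outside model domain {self.T_domain} K")

    def eta(self, phi, T):
        """Dynamic viscosity (mPa s); raises outside the calibrated domain."""
        self._check_domain(phi, T)
        phi = np.asarray(phi, dtype=float)
        ln_w = np.log(_vft(T, *self.vft_d2o))
        ln_d = np.log(_vft(T, *self.vft_dmso))
        ln_eta = (1.0 - phi) * ln_w + phi * ln_d + self.G * phi * (1.0 - phi)
        out = np.exp(ln_eta)
        return float(out) if out.ndim == 0 else out

    def eta_pa_s(self, phi, T):
        """Dynamic viscosity in SI (Pa s)."""
        return self.eta(phi, T) * 1e-3


# ---------------------------------------------------------------------------
# Viscometry arithmetic
# ---------------------------------------------------------------------------

def kinematic_viscosity(K: float, t_efflux: float) -> float:
    """Capillary viscometry: nu = K * t (mm^2/s) from cell constant and efflux time."""
    if K <= 0 or t_efflux <= 0:
        raise ValueError("cell constant and efflux time must be positive")
    return K * t_efflux


def dynamic_viscosity(rho: float, nu: float) -> float:
    """eta = rho * nu; with rho in g/cm^3 and nu in mm^2/s the result is mPa s."""
    if rho <= 0 or nu <= 0:
        raise ValueError("density and kinematic viscosity must be positive")
    return rho * nu


def mixture_viscosity(model: ViscosityModel, comp: MixtureComposition) -> float:
    """Model viscosity (mPa s) at a composition/temperature point."""
    return float(model.eta(comp.phi_dmso, comp.temperature))


# ---------------------------------------------------------------------------
# Stokes-Einstein / Stokes-Einstein-Debye
# ---------------------------------------------------------------------------

def stokes_einstein_diameter(D: float, T: float, eta: float) -> float:
    """Hydrodynamic diameter d_H (Angstrom) from D (m^2/s), T (K), eta (Pa s)."""
    if D <= 0 or T <= 0 or eta <= 0:
        raise ValueError("D, T and eta must be positive")
    return K_B * T / (3.0 * np.pi * eta * D) * 1e10


def diffusion_from_diameter(d_h: float, T: float, eta: float) -> float:
    """Inverse of :func:`stokes_einstein_diameter`: D (m^2/s) from d_H (Angstrom)."""
    if d_h <= 0 or T <= 0 or eta <= 0:
        raise ValueError("d_H, T and eta must be positive")
    return K_B * T / (3.0 * np.pi * eta * d_h * 1e-10)


def sed_rotational(r: float, eta: float, T: float, *, slip: bool = False) -> float:
    """Rotational correlation time tau_c (s) for radius r (Angstrom), eta (Pa s), T (K).

    Stick boundary by default: tau_c = 4 pi eta r^3 / (3 k_B T).  The
    ``slip`` flag applies the common slip reduction factor (~0.163 of
    stick for a near-sphere) as an alternative convention.
    """
    if r <= 0 or eta <= 0 or T <= 0:
        raise ValueError("r, eta and T must be positive")
    tau = 4.0 * np.pi * eta * (r * 1e-10) ** 3 / (3.0 * K_B * T)
    return tau * 0.163 if slip else tau


def sed_radius(tau_c: float, eta: float, T: float, *, slip: bool = False) -> float:
    """Inverse of :func:`sed_rotational`: radius (Angstrom) from tau_c (s)."""
    if tau_c <= 0 or eta <= 0 or T <= 0:
        raise ValueError("tau_c, eta and T must be positive")
    tau = tau_c / 0.163 if slip else tau_c
    r3 = 3.0 * K_B * T * tau / (4.0 * np.pi * eta)
    return float(np.cbrt(r3)) * 1e10
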