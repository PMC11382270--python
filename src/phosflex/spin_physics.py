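"""Closed-form spin physics for :sup:`31`\\ P relaxometry.

Frequency arithmetic (Larmor/nutation), the Lorentzian spectral density,
dipolar + chemical-shift-anisotropy (CSA) relaxation rates for an
isotropically tumbling rigid rotor, exchange broadening of the transverse
rate, and the fast-exchange population-weighted chemical shift.

Conventions
-----------
* The spectral density carries the 2/5 normalisation inside
  ``J(omega) = (2/5) * tau_c / (1 + (omega*tau_c)**2)``; the dipolar and
  CSA prefactors below are the standard Solomon/Abragam forms written for
  that convention.
* Angular frequencies (rad/s) are internal; every public interface takes
  and returns Hz, ppm, Tesla, seconds and Kelvin.
* Motion is an isotropic rigid rotor with a single rotational correlation
  time ``tau_c`` — no model-free order parameters, no anisotropic
  diffusion tensor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "CONSTANTS",
    "NucleusSpec",
    "FieldSpec",
    "MotionState",
    "InteractionModel",
    "nucleus",
    "larmor_frequency",
    "nutation_frequency",
    "spectral_density",
    "relaxation_rates",
    "fast_exchange_broadening",
    "general_exchange_broadening",
    "observed_shift",
    "default_p31_interactions",
]


def _load_constants() -> dict:
    with resources.files("phosflex.data").joinpath("constants.json").open() as fh:
        return json.load(fh)


#: Versioned physical-constant table (SI units; gamma in rad T^-1 s^-1).
CONSTANTS: dict = _load_constants()

K_B: float = CONSTANTS["k_B"]
HBAR: float = CONSTANTS["hbar"]
MU0_OVER_4PI: float = CONSTANTS["mu0_over_4pi"]
GAS_CONSTANT: float = CONSTANTS["R"]


@dataclass(frozen=True)
class NucleusSpec:
    """A magnetic nucleus: gyromagnetic ratio (rad T^-1 s^-1) and label."""

    gamma: float
    label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma) or self.gamma == 0.0:
            raise ValueError(f"gamma must be finite and nonzero, got {self.gamma}")
        if not self.label:
            raise ValueError("nucleus label must be nonempty")


@dataclass(frozen=True)
class FieldSpec:
    """Static field B0 (T) and optional rf irradiation amplitude B1 (T)."""

    B0: float
    B1: float = 0.0

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError(f"B0 must be positive, got {self.B0}")
        if self.B1 < 0:
            raise ValueError(f"B1 must be nonnegative, got {self.B1}")


@dataclass(frozen=True)
class MotionState:
    """Isotropic rigid-rotor motion: tau_c (s), temperature (K), viscosity (Pa s)."""

    tau_c: float
    temperature: float = 298.0
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        for name in ("tau_c", "temperature", "viscosity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class InteractionModel:
    """Relaxation-active interactions of the observed nucleus.

    Parameters
    ----------
    csa_delta_sigma:
        CSA span (ppm, axially symmetric tensor).  Zero disables the CSA
        mechanism.
    dipolar_partners:
        Sequence of ``(partner NucleusSpec, effective distance in Angstrom)``
        heteronuclear dipolar contacts.
    """

    csa_delta_sigma: float = 0.0
    dipolar_partners: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not np.isfinite(self.csa_delta_sigma):
            raise ValueError("csa_delta_sigma must be finite")
        object.__setattr__(self, "dipolar_partners", tuple(self.dipolar_partners))
        for partner, r in self.dipolar_partners:
            if not isinstance(partner, NucleusSpec):
                raise TypeError("dipolar partner must be a NucleusSpec")
            if r <= 0:
                raise ValueError(f"dipolar distance must be positive, got {r}")

    @property
    def empty(self) -> bool:
        return self.csa_delta_sigma == 0.0 and len(self.dipolar_partners) == 0


def nucleus(label: str) -> NucleusSpec:
    """Look up a nucleus by label in the packaged constants table."""
    try:
        return NucleusSpec(gamma=CONSTANTS["gamma"][label], label=label)
    except KeyError as exc:
        raise KeyError(
            f"unknown nucleus {label!r}; known: {sorted(CONSTANTS['gamma'])}"
        ) from exc


def default_p31_interactions() -> InteractionModel:
    """Default 31P interaction inventory for a pyrophosphate-like site.

    CSA span 150 ppm plus two effective P-H dipolar contacts at 2.6 A,
    chosen to put R1 in the 0.5-2 s^-1 range observed for small
    phosphometabolites at 11.7 T.  A modelling default, not a measured
    quantity; override via configuration.
    """
    h = nucleus("1H")
    return InteractionModel(csa_delta_sigma=150.0, dipolar_partners=((h, 2.6), (h, 2.6)))


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def larmor_frequency(nuc: NucleusSpec, fld: FieldSpec, *, angular: bool = False) -> float:
    """Larmor frequency gamma*B0/(2 pi) in Hz (or gamma*B0 in rad/s if angular)."""
    if fld.B0 <= 0:
        raise ValueError("B0 must be positive")
    w = nuc.gamma * fld.B0
    return w if angular else w / (2.0 * np.pi)


def nutation_frequency(nuc: NucleusSpec, b1: float, *, angular: bool = False) -> float:
    """Nutation frequency gamma*B1/(2 pi) in Hz for rf amplitude b1 (T)."""
    if b1 < 0:
        raise ValueError("B1 must be nonnegative")
    w = nuc.gamma * b1
    return w if angular else w / (2.0 * np.pi)


def spectral_density(omega, tau_c: float):
    """Lorentzian spectral density J(omega) = (2/5) tau_c / (1 + (omega tau_c)^2).

    ``omega`` is angular (rad/s); scalar or array.  The 2/5 normalisation
    lives here, not in the relaxation prefactors.
    """
    if tau_c <= 0:
        raise ValueError(f"tau_c must be positive, got {tau_c}")
    omega = np.asarray(omega, dtype=float)
    j = 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)
    return float(j) if j.ndim == 0 else j


# ---------------------------------------------------------------------------
# Relaxation rates
# ---------------------------------------------------------------------------

def _dipolar_coupling(nuc_i: NucleusSpec, nuc_s: NucleusSpec, r_angstrom: float) -> float:
    """Dipolar coupling constant d = (mu0/4pi) hbar gamma_I gamma_S / r^3 (rad/s)."""
    r = r_angstrom * 1e-10
    return MU0_OVER_4PI * HBAR * abs(nuc_i.gamma) * abs(nuc_s.gamma) / r**3


def relaxation_rates(
    nuc: NucleusSpec,
    fld: FieldSpec,
    motion: MotionState,
    interactions: InteractionModel,
) -> tuple[float, float]:
    """Exchange-free (R1, R2) in s^-1 from CSA + heteronuclear dipolar terms.

    For each dipolar partner S at distance r (coupling d):

        R1 += (d^2/4) [ J(wI-wS) + 3 J(wI) + 6 J(wI+wS) ]
        R2 += (d^2/8) [ 4 J(0) + J(wI-wS) + 3 J(wI) + 6 J(wS) + 6 J(wI+wS) ]

    and for an axially symmetric CSA tensor with span ``delta_sigma``
    (c^2 = (wI*delta_sigma)^2 / 3):

        R1 += c^2 J(wI)
        R2 += (c^2/6) [ 4 J(0) + 3 J(wI) ]

    all with the 2/5-normalised Lorentzian J.
    """
    if interactions.empty:
        raise ValueError("interaction model is empty: nothing to relax the spin")
    tau = motion.tau_c
    w_i = nuc.gamma * fld.B0

    def J(w):  # noqa: N802 - conventional symbol
        return spectral_density(w, tau)

    r1 = 0.0
    r2 = 0.0
    if interactions.csa_delta_sigma:
        c2 = (w_i * interactions.csa_delta_sigma * 1e-6) ** 2 / 3.0
        r1 += c2 * J(w_i)
        r2 += (c2 / 6.0) * (4.0 * J(0.0) + 3.0 * J(w_i))
    for partner, r_ang in interactions.dipolar_partners:
        w_s = partner.gamma * fld.B0
        d2 = _dipolar_coupling(nuc, partner, r_ang) ** 2
        r1 += (d2 / 4.0) * (J(w_i - w_s) + 3.0 * J(w_i) + 6.0 * J(w_i + w_s))
        r2 += (d2 / 8.0) * (
            4.0 * J(0.0) + J(w_i - w_s) + 3.0 * J(w_i) + 6.0 * J(w_s) + 6.0 * J(w_i + w_s)
        )
    return r1, r2


# ---------------------------------------------------------------------------
# Exchange
# ---------------------------------------------------------------------------

def _delta_omega_rad(exchange, carrier_mhz: float) -> float:
    """Site shift difference in rad/s from ppm shifts and carrier (MHz)."""
    return 2.0 * np.pi * abs(exchange.delta_G - exchange.delta_E) * carrier_mhz


def fast_exchange_broadening(exchange, fld: FieldSpec, *, carrier_mhz: float | None = None) -> float:
    """Exchange contribution Rex = pG pE dOmega^2 / kex in the fast limit.

    Valid for kex well above the site shift separation dOmega (rad/s);
    see :func:`general_exchange_broadening` for the all-regime form.
    ``carrier_mhz`` defaults to the 31P Larmor frequency at ``fld.B0``.
    """
    if exchange.k_ex <= 0:
        raise ValueError("k_ex must be positive: the fast-exchange regime is undefined at k_ex=0")
    if carrier_mhz is None:
        carrier_mhz = larmor_frequency(nucleus("31P"), fld) / 1e6
    dw = _delta_omega_rad(exchange, carrier_mhz)
    return exchange.p_G * exchange.p_E * dw**2 / exchange.k_ex


def general_exchange_broadening(exchange, fld: FieldSpec, *, carrier_mhz: float | None = None) -> float:
    """All-regime two-site exchange broadening of the dominant line.

    Rex = pG pE dOmega^2 kex / (kex^2 + dOmega^2): reduces to
    pG pE dOmega^2 / kex for kex >> dOmega (fast exchange) and to
    pE kex for pG ~ 1, kex << dOmega (slow exchange); maximal at
    kex = dOmega (coalescence).
    """
    if exchange.k_ex < 0:
        raise ValueError("k_ex must be nonnegative")
    if exchange.k_ex == 0:
        return 0.0
    if carrier_mhz is None:
        carrier_mhz = larmor_frequency(nucleus("31P"), fld) / 1e6
    dw = _delta_omega_rad(exchange, carrier_mhz)
    return exchange.p_G * exchange.p_E * dw**2 * exchange.k_ex / (exchange.k_ex**2 + dw**2)


def observed_shift(populations: Sequence[float], shifts: Sequence[float]) -> float:
    """Fast-exchange observed shift: population-weighted mean of site shifts (ppm)."""
    p = np.asarray(populations, dtype=float)
    d = np.asarray(shifts, dtype=float)
    if p.shape != d.shape:
        raise ValueError("populations and shifts must have matching shapes")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"populations must be nonnegative and sum to 1, got sum={p.sum()}")
    return float(np.dot(p, d))
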