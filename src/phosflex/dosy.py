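"""Pulsed-field-gradient (DOSY) attenuation and diffusion fitting.

The signal attenuation for a rectangular gradient pair of strength g,
width delta, separation Delta and diffusion coefficient D is the
Stejskal-Tanner exponential

    psi(g, D) = exp(-D g^2 gamma^2 delta^2 (Delta - delta/3)).

Fitted D feeds the Stokes-Einstein relation for the hydrodynamic
diameter.  Stimulated-echo coherence-pathway corrections and shaped
gradient form factors are out of scope; units are SI internally with an
explicit flag for G/cm gradient input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import hydrodynamics as hyd
from .relaxometry import TruncatedDecayWarning, RelaxometryFitError
from .spin_physics import CONSTANTS

__all__ = [
    "GradientSeries",
    "DiffusionFit",
    "stejskal_tanner_attenuation",
    "fit_diffusion_coefficient",
    "hydrodynamic_diameter_from_dosy",
]

G_PER_CM_TO_T_PER_M = 1e-2


@dataclass(frozen=True)
class GradientSeries:
    """PFG attenuation series: gradients (T/m) and intensities.

    ``delta`` is the gradient pulse width (s), ``big_delta`` the diffusion
    delay (s), ``gamma`` the gyromagnetic ratio (rad T^-1 s^-1).  Pass
    ``gradient_unit='G/cm'`` to convert on construction.
    """

    gradients: np.ndarray
    intensities: np.ndarray
    delta: float
    big_delta: float
    gamma: float = CONSTANTS["gamma"]["31P"]
    noise_sd: float | None = None
    gradient_unit: str = "T/m"

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients, dtype=float)
        if self.gradient_unit == "G/cm":
            g = g * G_PER_CM_TO_T_PER_M
            object.__setattr__(self, "gradient_unit", "T/m")
        elif self.gradient_unit != "T/m":
            raise ValueError(f"unknown gradient unit {self.gradient_unit!r}")
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "gradients", g)
        object.__setattr__(self, "intensities", y)
        if g.ndim != 1 or g.size < 4:
            raise ValueError("need at least 4 gradient points")
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("gradients must be nonnegative and strictly increasing")
        if y.shape != g.shape:
            raise ValueError("intensities must match gradients in shape")
        if not 0 < self.delta < self.big_delta:
            raise ValueError("need 0 < delta < big_delta")


def stejskal_tanner_attenuation(g, D: float, delta: float, big_delta: float,
                                gamma: float = CONSTANTS["gamma"]["31P"]):
    """psi(g, D) = exp(-D g^2 gamma^2 delta^2 (Delta - delta/3)); g in T/m."""
    if D <= 0:
        raise ValueError("D must be positive")
    if not 0 < delta < big_delta:
        raise ValueError("need 0 < delta < big_delta")
    g = np.asarray(g, dtype=float)
    psi = np.exp(-D * g**2 * gamma**2 * delta**2 * (big_delta - delta / 3.0))
    return float(psi) if psi.ndim == 0 else psi


@dataclass(frozen=True)
class DiffusionFit:
    D: float                     # m^2/s
    amplitude: float
    covariance: np.ndarray       # order (D, amplitude)
    residuals: np.ndarray

    @property
    def D_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


def fit_diffusion_coefficient(series: GradientSeries) -> DiffusionFit:
    """Nonlinear least-squares Stejskal-Tanner fit for (D, amplitude).

    Warns when the deepest point retains more than 5% of the initial
    intensity (under-encoded decay).
    """
    g, y = series.gradients, series.intensities
    if y[-1] > 0.05 * y[0]:
        warnings.warn(
            f"attenuation truncated at {y[-1] / y[0]:.0%} of initial intensity "
            "(recommended: encode below 5%)", TruncatedDecayWarning, stacklevel=2)
    b = g**2 * series.gamma**2 * series.delta**2 * (series.big_delta - series.delta / 3.0)

    def model(b, d, m0):
        return m0 * np.exp(-d * b)

    pos = y > 0
    if pos.sum() >= 2:
        slope, inter = np.polyfit(b[pos], np.log(y[pos]), 1)
        d0 = max(-slope, 1e-14)
        m0 = float(np.exp(inter))
    else:
        d0, m0 = 1e-10, float(y[0])
    sigma = np.full_like(y, series.noise_sd) if series.noise_sd else None
    try:
        popt, pcov = curve_fit(model, b, y, p0=[d0, m0], maxfev=20000,
                               sigma=sigma, absolute_sigma=sigma is not None)
    except RuntimeError as exc:
        raise RelaxometryFitError(f"Stejskal-Tanner fit did not converge: {exc}") from exc
    d_fit, m_fit = popt
    if d_fit <= 0:
        raise RelaxometryFitError(f"nonphysical diffusion coefficient {d_fit:.3g}")
    return DiffusionFit(D=float(d_fit), amplitude=float(m_fit), covariance=pcov,
                        residuals=y - model(b, *popt))


def hydrodynamic_diameter_from_dosy(D: float, T: float, eta: float) -> float:
    """Stokes-Einstein hydrodynamic diameter (Angstrom) from fitted D (m^2/s)."""
    return hyd.stokes_einstein_diameter(D, T, eta)
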