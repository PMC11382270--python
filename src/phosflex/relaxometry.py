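"""Relaxation-decay fitting and temperature-series analysis.

Covers the longitudinal/transverse measurement side of the pipeline:

* inversion-recovery fits, ``M(t) = Minf * (1 - 2 a exp(-t/T1))``, with an
  imperfect-inversion amplitude ``a`` as a third parameter;
* monoexponential CPMG fits, ``M(t) = M0 exp(-t/T2)``;
* location of the R1(T) maximum (the tau_c * omega0 = 1 condition) on a
  discrete temperature grid;
* a global R1/R2 temperature-series fit for the hydrodynamic radius with
  an optional Arrhenius exchange-broadening term on R2;
* Curie-corrected integral ratios for dark-state detection: equilibrium
  magnetisation scales as 1/T, so I(T)*T relative to the coldest point is
  flat for a single fully visible species and falls when population
  leaks into an unobserved pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy import stats

from . import spin_physics as sp
from . import hydrodynamics as hyd

__all__ = [
    "DecaySeries",
    "TemperatureSeries",
    "ExchangePrior",
    "FitResult",
    "GlobalFitResult",
    "CurieResult",
    "fit_inversion_recovery",
    "fit_monoexponential_decay",
    "detect_r1_maximum",
    "global_relaxation_fit",
    "curie_corrected_ratio",
    "RelaxometryFitError",
    "TruncatedDecayWarning",
]


class RelaxometryFitError(RuntimeError):
    """Raised when a relaxation fit fails or returns a nonphysical estimate."""


class TruncatedDecayWarning(UserWarning):
    """Decay not sampled deep enough (last point above 5% of the first)."""


@dataclass(frozen=True)
class DecaySeries:
    """One relaxation decay: delay times (s) and intensities (a.u.)."""

    abscissa: np.ndarray
    intensities: np.ndarray
    kind: Literal["inversion_recovery", "cpmg"]
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "abscissa", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or t.size < 4:
            raise ValueError("need at least 4 delay points for a 3-parameter fit")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("abscissa must be nonnegative and strictly increasing")
        if y.shape != t.shape:
            raise ValueError("intensities must match abscissa in shape")
        if self.kind not in ("inversion_recovery", "cpmg"):
            raise ValueError(f"unknown decay kind {self.kind!r}")


@dataclass(frozen=True)
class TemperatureSeries:
    """Values (rates or integrals) on a strictly increasing temperature grid."""

    temperatures: np.ndarray
    values: np.ndarray
    kind: str = "R1"
    phi_dmso: float | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "values", v)
        if T.ndim != 1 or np.any(np.diff(T) <= 0):
            raise ValueError("temperatures must be 1-d and strictly increasing")
        if v.shape != T.shape:
            raise ValueError("values must match temperatures in shape")


@dataclass(frozen=True)
class FitResult:
    """Nonlinear least-squares estimates with covariance."""

    params: dict
    covariance: np.ndarray
    residuals: np.ndarray

    def se(self, name: str) -> float:
        idx = list(self.params).index(name)
        return float(np.sqrt(self.covariance[idx, idx]))


# ---------------------------------------------------------------------------
# Decay fits
# ---------------------------------------------------------------------------

def fit_inversion_recovery(d: DecaySeries) -> FitResult:
    """Three-parameter inversion-recovery fit M(t) = Minf (1 - 2 a exp(-t/T1)).

    ``a`` is the inversion efficiency (1 for a perfect 180 pulse).
    Returns params ``T1``, ``amplitude`` (Minf), ``inversion_efficiency``.
    """
    if d.kind != "inversion_recovery":
        raise ValueError("series kind must be 'inversion_recovery'")
    t, y = d.abscissa, d.intensities

    def model(t, minf, t1, a):
        return minf * (1.0 - 2.0 * a * np.exp(-t / t1))

    minf0 = float(y[-1]) if y[-1] != 0 else float(np.max(np.abs(y)))
    t10 = max(float(t[-1]) / 3.0, 1e-6)
    sigma = np.full_like(y, d.noise_sd) if d.noise_sd else None
    try:
        popt, pcov = curve_fit(model, t, y, p0=[minf0, t10, 1.0], maxfev=20000,
                               sigma=sigma, absolute_sigma=sigma is not None)
    except RuntimeError as exc:
        raise RelaxometryFitError(f"inversion-recovery fit did not converge: {exc}") from exc
    minf, t1, a = popt
    if t1 <= 0:
        raise RelaxometryFitError(
            f"nonphysical T1 estimate {t1:.3g} s (amplitude {minf:.3g}, alpha {a:.3g})"
        )
    resid = y - model(t, *popt)
    return FitResult(params={"T1": float(t1), "amplitude": float(minf),
                             "inversion_efficiency": float(a)},
                     covariance=_reorder_cov(pcov, [1, 0, 2]), residuals=resid)


def _reorder_cov(pcov: np.ndarray, order: list[int]) -> np.ndarray:
    return pcov[np.ix_(order, order)]


def fit_monoexponential_decay(d: DecaySeries) -> FitResult:
    """Monoexponential CPMG fit M(t) = M0 exp(-t/T2); params ``T2``, ``amplitude``.

    Warns (:class:`TruncatedDecayWarning`) when the decay is not sampled
    below 5% of its initial intensity; errors when intensities are
    negative beyond the stated noise floor.
    """
    if d.kind != "cpmg":
        raise ValueError("series kind must be 'cpmg'")
    t, y = d.abscissa, d.intensities
    floor = 3.0 * (d.noise_sd or 0.0)
    if np.any(y < -floor):
        raise ValueError("negative intensities beyond the noise floor in a CPMG decay")
    if y[-1] > 0.05 * y[0]:
        warnings.warn(
            f"decay truncated at {y[-1] / y[0]:.0%} of initial intensity "
            "(recommended: sample below 5%)", TruncatedDecayWarning, stacklevel=2)

    def model(t, m0, t2):
        return m0 * np.exp(-t / t2)

    with np.errstate(divide="ignore", invalid="ignore"):
        pos = y > 0
        slope0, inter0, *_ = stats.linregress(t[pos], np.log(y[pos]))
    t20 = -1.0 / slope0 if slope0 < 0 else float(t[-1])
    sigma = np.full_like(y, d.noise_sd) if d.noise_sd else None
    try:
        popt, pcov = curve_fit(model, t, y, p0=[np.exp(inter0), t20], maxfev=20000,
                               sigma=sigma, absolute_sigma=sigma is not None)
    except RuntimeError as exc:
        raise RelaxometryFitError(f"monoexponential fit did not converge: {exc}") from exc
    m0, t2 = popt
    if t2 <= 0:
        raise RelaxometryFitError(f"nonphysical T2 estimate {t2:.3g} s")
    resid = y - model(t, *popt)
    return FitResult(params={"T2": float(t2), "amplitude": float(m0)},
                     covariance=_reorder_cov(pcov, [1, 0]), residuals=resid)


# ---------------------------------------------------------------------------
# Temperature-series analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class R1MaxResult:
    T_max: float | None
    tau_c_at_max: float | None
    annotation: str


def detect_r1_maximum(ts: TemperatureSeries, larmor_hz: float) -> R1MaxResult:
    """Locate the R1(T) maximum; report tau_c(T_max) = 1/omega0 when found.

    Uses quadratic interpolation through the three points around the
    discrete argmax.  A monotone series is a valid outcome: decreasing
    means the maximum lies below the measured range (reachable by further
    cooling), increasing means it lies above ("cool side" of the
    condition omega0 * tau_c = 1).
    """
    if ts.temperatures.size < 5:
        raise ValueError("need at least 5 temperature points")
    T, v = ts.temperatures, ts.values
    i = int(np.argmax(v))
    if i == 0:
        return R1MaxResult(None, None, "monotone decreasing: maximum below measured range (warm side)")
    if i == v.size - 1:
        return R1MaxResult(None, None, "monotone increasing: maximum above measured range (cool side)")
    # parabola through (T[i-1..i+1], v[i-1..i+1])
    a, b, _ = np.polyfit(T[i - 1:i + 2], v[i - 1:i + 2], 2)
    t_max = float(-b / (2.0 * a)) if a < 0 else float(T[i])
    tau_c = 1.0 / (2.0 * np.pi * larmor_hz)
    return R1MaxResult(t_max, tau_c, "interior maximum")


@dataclass(frozen=True)
class ExchangePrior:
    """Configuration of the exchange term in the global R1/R2 fit.

    The transverse rate gains Rex(T) = pG pE dOmega^2 kex / (kex^2 +
    dOmega^2) with Arrhenius kex(T) = A exp(-Ea / R T).  ``delta_ppm`` is
    the site shift separation (fixed, default the printed 2.3 ppm span,
    to avoid degeneracy with the populations) and ``p_E`` the dark-pool
    population (fixed, default 0.5).
    """

    enabled: bool = True
    p_E: float = 0.5
    delta_ppm: float = 2.3
    log10_A_bounds: tuple[float, float] = (-2.0, 14.0)
    ea_bounds_kj: tuple[float, float] = (1.0, 150.0)


@dataclass(frozen=True)
class GlobalFitResult:
    r_H: float                       # Angstrom
    exchange_enabled: bool
    log10_A: float | None
    Ea_kj_mol: float | None
    residuals_r1: np.ndarray
    residuals_r2: np.ndarray
    cost: float
    cost_no_exchange: float
    warnings: tuple = ()

    def k_ex(self, T) -> np.ndarray:
        if not self.exchange_enabled:
            return np.zeros_like(np.asarray(T, dtype=float))
        return 10.0 ** self.log10_A * np.exp(-self.Ea_kj_mol * 1e3 / (sp.GAS_CONSTANT * np.asarray(T, dtype=float)))


def _model_rates(T: np.ndarray, r_h: float, phi: float, visc_model: hyd.ViscosityModel,
                 interactions: sp.InteractionModel, fld: sp.FieldSpec,
                 prior: ExchangePrior | None, log10_A: float | None, ea_kj: float | None):
    p31 = sp.nucleus("31P")
    carrier = sp.larmor_frequency(p31, fld) / 1e6
    r1 = np.empty_like(T)
    r2 = np.empty_like(T)
    for j, temp in enumerate(T):
        eta = visc_model.eta_pa_s(phi, temp)
        tau = hyd.sed_rotational(r_h, eta, temp)
        motion = sp.MotionState(tau_c=tau, temperature=temp, viscosity=eta)
        r1[j], r2[j] = sp.relaxation_rates(p31, fld, motion, interactions)
        if prior is not None and prior.enabled and log10_A is not None:
            kex = 10.0 ** log10_A * np.exp(-ea_kj * 1e3 / (sp.GAS_CONSTANT * temp))
            ex = sp_exchange(prior, kex)
            r2[j] += sp.general_exchange_broadening(ex, fld, carrier_mhz=carrier)
    return r1, r2


def sp_exchange(prior: ExchangePrior, kex: float):
    from .exchange_cest import TwoSiteExchange
    return TwoSiteExchange(p_G=1.0 - prior.p_E, p_E=prior.p_E, k_ex=kex,
                           delta_G=0.0, delta_E=prior.delta_ppm)


def global_relaxation_fit(
    r1_series: TemperatureSeries,
    r2_series: TemperatureSeries,
    visc_model: hyd.ViscosityModel,
    interactions: sp.InteractionModel,
    exchange_prior: ExchangePrior | None = None,
    *,
    phi_dmso: float | None = None,
    B0: float = 11.7,
    r_h_bounds: tuple[float, float] = (2.0, 20.0),
) -> GlobalFitResult:
    """Co-fit R1(T) and R2(T) for the hydrodynamic radius (+ optional exchange).

    The forward model maps r_H through the mixture viscosity and the
    Stokes-Einstein-Debye relation to tau_c(T), then through the CSA +
    dipolar rate expressions; exchange (when enabled) adds an Arrhenius
    broadening term to R2 only.  When enabling exchange improves the
    residual cost by less than 1%, the exchange term is judged
    non-identifiable and the exchange-free fit is returned with a warning.
    """
    if not np.array_equal(r1_series.temperatures, r2_series.temperatures):
        raise ValueError("R1 and R2 series must share one temperature grid")
    phi = phi_dmso if phi_dmso is not None else (r1_series.phi_dmso or 0.0)
    T = r1_series.temperatures
    lo, hi = visc_model.T_domain
    if T.min() < lo or T.max() > hi:
        raise ValueError(f"viscosity model does not cover the temperature grid [{T.min()}, {T.max()}] K")
    y = np.concatenate([r1_series.values, r2_series.values])
    fld = sp.FieldSpec(B0=B0)
    notes: list[str] = []

    def resid_free(params):
        r1m, r2m = _model_rates(T, params[0], phi, visc_model, interactions, fld, None, None, None)
        return np.concatenate([r1m, r2m]) - y

    r_h0 = 7.0
    sol_free = least_squares(resid_free, [r_h0], bounds=([r_h_bounds[0]], [r_h_bounds[1]]))
    cost_free = 2.0 * sol_free.cost

    use_exchange = exchange_prior is not None and exchange_prior.enabled
    if use_exchange:
        def resid_ex(params):
            r1m, r2m = _model_rates(T, params[0], phi, visc_model, interactions, fld,
                                    exchange_prior, params[1], params[2])
            return np.concatenate([r1m, r2m]) - y

        x0 = [float(sol_free.x[0]), 1.0, 20.0]
        lb = [r_h_bounds[0], exchange_prior.log10_A_bounds[0], exchange_prior.ea_bounds_kj[0]]
        ub = [r_h_bounds[1], exchange_prior.log10_A_bounds[1], exchange_prior.ea_bounds_kj[1]]
        sol_ex = least_squares(resid_ex, x0, bounds=(lb, ub))
        cost_ex = 2.0 * sol_ex.cost
        # maximum fitted exchange contribution across the grid
        kex_top = 10.0 ** sol_ex.x[1] * np.exp(-sol_ex.x[2] * 1e3 / (sp.GAS_CONSTANT * T))
        rex_top = np.array([
            sp.general_exchange_broadening(sp_exchange(exchange_prior, k), fld)
            for k in np.atleast_1d(kex_top)])
        if cost_free - cost_ex < 0.01 * cost_free or rex_top.max() < 0.01 * np.max(r2_series.values):
            notes.append("exchange term non-identifiable (<1% residual improvement "
                         "or negligible fitted Rex); set to zero")
            use_exchange = False
        else:
            n = T.size
            res = sol_ex.fun
            return GlobalFitResult(r_H=float(sol_ex.x[0]), exchange_enabled=True,
                                   log10_A=float(sol_ex.x[1]), Ea_kj_mol=float(sol_ex.x[2]),
                                   residuals_r1=res[:n], residuals_r2=res[n:],
                                   cost=cost_ex, cost_no_exchange=cost_free,
                                   warnings=tuple(notes))
    # exchange-free result; flag systematic misfit at high temperature:
    # data - model (= -residual) trending upward with T with a confidently
    # positive slope, and positive in the top temperature quartile
    res = sol_free.fun
    n = T.size
    r2_res = res[n:]
    top = T >= np.quantile(T, 0.75)
    trend = stats.linregress(T, -r2_res)
    if (trend.slope > 3.0 * trend.stderr) and np.mean(-r2_res[top]) > 0:
        notes.append("systematic positive R2 residuals at high temperature: "
                     "possible unmodelled exchange broadening")
    return GlobalFitResult(r_H=float(sol_free.x[0]), exchange_enabled=False,
                           log10_A=None, Ea_kj_mol=None,
                           residuals_r1=res[:n], residuals_r2=r2_res,
                           cost=cost_free, cost_no_exchange=cost_free,
                           warnings=tuple(notes))


# ---------------------------------------------------------------------------
# Curie-corrected integrals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurieResult:
    temperatures: np.ndarray
    ratios: np.ndarray
    slope: float            # per K
    slope_se: float
    dark_state_flag: bool


def curie_corrected_ratio(integrals: TemperatureSeries) -> CurieResult:
    """Curie-corrected integral ratios and a dark-state trend test.

    ratio_i = (I_i * T_i) / (I_ref * T_ref) with the coldest temperature
    as reference; a single fully visible species gives ratios of exactly 1
    at every temperature (magnetisation scales as 1/T).  The dark-state
    flag is raised when the linear trend of ratio vs T is negative with
    |slope| > 3 standard errors.
    """
    T, I = integrals.temperatures, integrals.values
    if T.size < 3:
        raise ValueError("need at least 3 temperatures")
    if np.any(I <= 0):
        raise ValueError("integrals must be strictly positive")
    corrected = I * T
    ratios = corrected / corrected[0]
    fit = stats.linregress(T, ratios)
    flag = bool(fit.slope < 0 and abs(fit.slope) > 3.0 * fit.stderr)
    return CurieResult(temperatures=T, ratios=ratios, slope=float(fit.slope),
                       slope_se=float(fit.stderr), dark_state_flag=flag)
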