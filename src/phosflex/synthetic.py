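"""Ground-truth scenario generator for the full observable set.

A scenario is an explicit three-state model of a small dinucleotide
exchanging between folded (F), semifolded (S) and unfolded (U)
conformers in a binary D2O/DMSO-d6 solvent.  Populations follow
Boltzmann weights with reduced free energies (units of RT) linear in the
DMSO volume fraction ``phi`` and temperature, calibrated so that water
at room temperature holds a 50/50 folded/unfolded balance while pure
DMSO is essentially all-unfolded; a per-composition stabilisation of the
semifolded state produces its population bump at the designated
compositions (a strictly linear-in-phi energy cannot).  Exchange
kinetics are Arrhenius; tumbling follows the mixture viscosity through
the Stokes-Einstein-Debye relation; detection noise is additive
Gaussian and fully seeded.

Every generated observable (relaxation temperature series, CEST
Z-spectra, DOSY attenuations, Curie integral series, viscometry tables)
is a deterministic function of (truth, seed), which is what makes full
parameter-recovery testing possible without real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import spin_physics as sp
from . import hydrodynamics as hyd
from .exchange_cest import TwoSiteExchange, ZSpectrum, simulate_zspectrum
from .dosy import GradientSeries, stejskal_tanner_attenuation
from .relaxometry import DecaySeries, TemperatureSeries

__all__ = [
    "PopulationParams",
    "NoiseSpec",
    "ScenarioTruth",
    "population_model",
    "generate_relaxation_series",
    "generate_zspectra",
    "generate_dosy_series",
    "generate_integral_series",
    "generate_decay_series",
    "generate_viscometry_table",
    "generate_scenario",
    "load_manifest",
]

DEFAULT_TEMPERATURES = tuple(float(t) for t in range(277, 344, 6))
DEFAULT_COMPOSITIONS = tuple(round(0.1 * i, 1) for i in range(11))
CEST_POWERS_HZ = (20.0, 30.0, 40.0, 50.0, 100.0, 150.0, 200.0)


@dataclass(frozen=True)
class PopulationParams:
    """Reduced free energies (units of RT): eps_X = a + b*phi + c*(T - 298).

    The unfolded state is the reference (eps_U = 0).  ``semifolded_offsets``
    maps designated compositions to an extra stabilisation subtracted from
    eps_S there.
    """

    a_F: float = 0.0
    b_F: float = 8.0
    c_F: float = -0.01
    a_S: float = 8.0
    b_S: float = 0.0
    c_S: float = 0.0
    semifolded_offsets: tuple = ((0.7, 7.5), (0.8, 7.5), (0.9, 7.5))


@dataclass(frozen=True)
class NoiseSpec:
    """Per-observable additive Gaussian noise levels (fraction of signal scale)."""

    relaxation: float = 0.01
    zspectrum: float = 0.005     # absolute, on M_z/M_0
    dosy: float = 0.01
    integrals: float = 0.01
    viscometry: float = 0.003


@dataclass(frozen=True)
class ScenarioTruth:
    """Full generative ground truth: the recovery target of every test."""

    compositions: tuple = DEFAULT_COMPOSITIONS
    temperatures: tuple = DEFAULT_TEMPERATURES
    r_U: float = 7.24            # rotational hydrodynamic radii, Angstrom
    r_F: float = 5.9
    r_S: float = 8.33
    d_trans_U: float = 10.0      # translational hydrodynamic diameters, Angstrom
    d_trans_F: float = 10.0
    d_trans_S: float = 11.5
    population_params: PopulationParams = field(default_factory=PopulationParams)
    k_ex_A: float = 8.55e3       # Arrhenius prefactor, s^-1
    k_ex_Ea_kj: float = 19.0     # activation energy, kJ/mol
    delta_U: float = -8.7        # site shifts, ppm
    delta_F: float = -13.3
    B0: float = 11.7             # T
    csa_delta_sigma: float = 150.0
    dipolar_distance: float = 2.6
    n_dipolar_partners: int = 2
    dark_fraction: float = 1.0   # share of the folded pool invisible to integration
    ion_binding: bool = False
    ion_radius_scale: float = 1.15
    ion_fold_stabilization: float = 2.0   # RT units subtracted from eps_F
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def interactions(self) -> sp.InteractionModel:
        h = sp.nucleus("1H")
        partners = tuple((h, self.dipolar_distance) for _ in range(self.n_dipolar_partners))
        return sp.InteractionModel(csa_delta_sigma=self.csa_delta_sigma,
                                   dipolar_partners=partners)

    def carrier_mhz(self) -> float:
        return sp.larmor_frequency(sp.nucleus("31P"), sp.FieldSpec(B0=self.B0)) / 1e6

    def k_ex(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        out = self.k_ex_A * np.exp(-self.k_ex_Ea_kj * 1e3 / (sp.GAS_CONSTANT * T))
        return float(out) if out.ndim == 0 else out

    def radii(self) -> tuple[float, float, float]:
        s = self.ion_radius_scale if self.ion_binding else 1.0
        return self.r_U * s, self.r_F * s, self.r_S * s

    def rng(self, *stream) -> np.random.Generator:
        """Deterministic child generator for a named sub-stream."""
        key = [int(self.seed)] + [int(round(1000 * float(x))) for x in stream]
        return np.random.default_rng(np.random.SeedSequence(key))


def _check_domain(truth: ScenarioTruth, phi: float, T: float) -> None:
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi={phi} outside [0, 1]")
    if not (min(truth.temperatures) - 1e-9 <= T <= max(truth.temperatures) + 1e-9):
        raise ValueError(f"T={T} K outside the scenario temperature range")


def population_model(truth: ScenarioTruth, phi: float, T: float) -> tuple[float, float, float]:
    """Three-state Boltzmann populations (p_U, p_F, p_S) at (phi, T)."""
    _check_domain(truth, phi, T)
    pp = truth.population_params
    eps_f = pp.a_F + pp.b_F * phi + pp.c_F * (T - 298.0)
    if truth.ion_binding:
        eps_f -= truth.ion_fold_stabilization
    eps_s = pp.a_S + pp.b_S * phi + pp.c_S * (T - 298.0)
    for comp, offset in pp.semifolded_offsets:
        if abs(phi - comp) < 1e-9:
            eps_s -= offset
    w = np.array([1.0, np.exp(-eps_f), np.exp(-eps_s)])
    p = w / w.sum()
    return float(p[0]), float(p[1]), float(p[2])


def _two_site(truth: ScenarioTruth, phi: float, T: float,
              r1_g: float = 1.0, r2_g: float = 2.0,
              r1_e: float | None = None, r2_e: float | None = None) -> TwoSiteExchange:
    """Reduce the three-state truth to the visible(U+S)/dark(F) two-site model."""
    p_u, p_f, p_s = population_model(truth, phi, T)
    p_g = p_u + p_s
    return TwoSiteExchange(p_G=p_g, p_E=p_f, k_ex=float(truth.k_ex(T)),
                           delta_G=truth.delta_U, delta_E=truth.delta_F,
                           R1_G=r1_g, R1_E=r1_e if r1_e is not None else r1_g,
                           R2_G=r2_g, R2_E=r2_e if r2_e is not None else r2_g)


def _base_rates(truth: ScenarioTruth, phi: float, T: float,
                visc: hyd.ViscosityModel) -> tuple[float, float, float]:
    """Exchange-free (R1, R2, tau_c) at the population-weighted radius."""
    p_u, p_f, p_s = population_model(truth, phi, T)
    r_u, r_f, r_s = truth.radii()
    r_eff = p_u * r_u + p_f * r_f + p_s * r_s
    eta = visc.eta_pa_s(phi, T)
    tau = hyd.sed_rotational(r_eff, eta, T)
    fld = sp.FieldSpec(B0=truth.B0)
    motion = sp.MotionState(tau_c=tau, temperature=T, viscosity=eta)
    r1, r2 = sp.relaxation_rates(sp.nucleus("31P"), fld, motion, truth.interactions())
    return r1, r2, tau


def generate_relaxation_series(
    truth: ScenarioTruth, phi: float,
    visc: hyd.ViscosityModel | None = None,
) -> tuple[TemperatureSeries, TemperatureSeries]:
    """Noisy R1(T) and R2(T) series at composition phi.

    R2 carries the exchange broadening of the visible line (general
    two-site form with the scenario's Arrhenius rate); R1 is exchange-free.
    """
    visc = visc or hyd.ViscosityModel.default()
    T = np.asarray(truth.temperatures, dtype=float)
    fld = sp.FieldSpec(B0=truth.B0)
    carrier = truth.carrier_mhz()
    r1 = np.empty_like(T)
    r2 = np.empty_like(T)
    for j, temp in enumerate(T):
        r1[j], r2[j], _ = _base_rates(truth, phi, temp, visc)
        ex = _two_site(truth, phi, temp)
        if ex.k_ex > 0 and ex.p_E > 0:
            r2[j] += sp.general_exchange_broadening(ex, fld, carrier_mhz=carrier)
    if truth.noise.relaxation > 0:
        rng = truth.rng(phi, 1)
        r1 = r1 * (1.0 + rng.normal(0.0, truth.noise.relaxation, r1.shape))
        r2 = r2 * (1.0 + rng.normal(0.0, truth.noise.relaxation, r2.shape))
    return (TemperatureSeries(T, r1, kind="R1", phi_dmso=phi),
            TemperatureSeries(T, r2, kind="R2", phi_dmso=phi))


def default_offset_grid(truth: ScenarioTruth, span: float = 40.0,
                        fine_halfwidth: float = 5.0, fine_step: float = 0.1,
                        coarse_step: float = 1.0) -> np.ndarray:
    """Offset grid (ppm): coarse over +-span, refined around both site shifts."""
    coarse = np.arange(-span, span + coarse_step / 2, coarse_step)
    fine = np.concatenate([
        np.arange(c - fine_halfwidth, c + fine_halfwidth + fine_step / 2, fine_step)
        for c in (truth.delta_U, truth.delta_F)
    ])
    return np.unique(np.round(np.concatenate([coarse, fine]), 6))


def generate_zspectra(truth: ScenarioTruth, phi: float, T: float,
                      omega1_list=CEST_POWERS_HZ, t_ex: float = 5.0,
                      offsets=None, visc: hyd.ViscosityModel | None = None) -> list[ZSpectrum]:
    """CEST Z-spectra at the stated powers for one (phi, T) condition."""
    visc = visc or hyd.ViscosityModel.default()
    r1, r2, _ = _base_rates(truth, phi, T, visc)
    ex = _two_site(truth, phi, T, r1_g=r1, r2_g=r2)
    if offsets is None:
        offsets = default_offset_grid(truth)
    out = []
    for i, w1 in enumerate(omega1_list):
        seed = int(truth.rng(phi, T, w1).integers(0, 2**31 - 1))
        out.append(simulate_zspectrum(ex, offsets, w1, t_ex, truth.carrier_mhz(),
                                      noise_sd=truth.noise.zspectrum, seed=seed))
    return out


def generate_dosy_series(truth: ScenarioTruth, phi: float, T: float = 298.0,
                         n_gradients: int = 16,
                         visc: hyd.ViscosityModel | None = None) -> GradientSeries:
    """PFG attenuation series at (phi, T) encoding the effective diameter.

    delta and Delta are drawn (seeded) from the 2.5-6 ms and 250-550 ms
    instrument ranges; the maximum gradient is set so the final point
    attenuates to ~3% of the initial intensity.
    """
    visc = visc or hyd.ViscosityModel.default()
    p_u, p_f, p_s = population_model(truth, phi, T)
    scale = truth.ion_radius_scale if truth.ion_binding else 1.0
    d_eff = (p_u * truth.d_trans_U + p_f * truth.d_trans_F + p_s * truth.d_trans_S) * scale
    eta = visc.eta_pa_s(phi, T)
    D = hyd.diffusion_from_diameter(d_eff, T, eta)
    rng = truth.rng(phi, T, 3)
    delta = rng.uniform(2.5e-3, 6e-3)
    big_delta = rng.uniform(250e-3, 550e-3)
    gamma = sp.CONSTANTS["gamma"]["31P"]
    g_max = np.sqrt(np.log(1.0 / 0.03) / (D * gamma**2 * delta**2 * (big_delta - delta / 3.0)))
    g = np.linspace(g_max / n_gradients, g_max, n_gradients)
    psi = stejskal_tanner_attenuation(g, D, delta, big_delta, gamma)
    if truth.noise.dosy > 0:
        psi = psi + rng.normal(0.0, truth.noise.dosy, psi.shape)
    return GradientSeries(gradients=g, intensities=psi, delta=delta,
                          big_delta=big_delta, gamma=gamma, noise_sd=truth.noise.dosy)


def generate_integral_series(truth: ScenarioTruth, phi: float) -> TemperatureSeries:
    """Visible-pool 1D integrals vs temperature (Curie 1/T times visibility).

    The folded pool (times ``dark_fraction``) is withheld from the
    integral: I(T) = (1 - dark_fraction * p_F) / T, in arbitrary units.
    """
    T = np.asarray([t for t in truth.temperatures if t >= 298.0], dtype=float)
    if T.size < 3:
        T = np.asarray(truth.temperatures[-4:], dtype=float)
    vals = np.empty_like(T)
    for j, temp in enumerate(T):
        _, p_f, _ = population_model(truth, phi, temp)
        vals[j] = (1.0 - truth.dark_fraction * p_f) / temp
    vals = vals / vals[0]
    if truth.noise.integrals > 0:
        rng = truth.rng(phi, 4)
        vals = vals * (1.0 + rng.normal(0.0, truth.noise.integrals, vals.shape))
    return TemperatureSeries(T, vals, kind="integral", phi_dmso=phi)


def generate_decay_series(truth: ScenarioTruth, phi: float, T: float,
                          kind: str = "inversion_recovery", n_points: int = 12,
                          visc: hyd.ViscosityModel | None = None) -> DecaySeries:
    """Raw decay curve (IR or CPMG) consistent with the scenario's rates."""
    visc = visc or hyd.ViscosityModel.default()
    r1, r2, _ = _base_rates(truth, phi, T, visc)
    fld = sp.FieldSpec(B0=truth.B0)
    ex = _two_site(truth, phi, T)
    if ex.k_ex > 0 and ex.p_E > 0:
        r2 += sp.general_exchange_broadening(ex, fld, carrier_mhz=truth.carrier_mhz())
    rng = truth.rng(phi, T, 5 if kind == "inversion_recovery" else 6)
    if kind == "inversion_recovery":
        t = np.linspace(1e-3, 5.0 / r1, n_points)
        y = 1.0 - 2.0 * np.exp(-t * r1)
    elif kind == "cpmg":
        t = np.linspace(np.log(1 / 0.98) / r2, np.log(1 / 0.03) / r2, n_points)
        y = np.exp(-t * r2)
    else:
        raise ValueError(f"unknown decay kind {kind!r}")
    sd = truth.noise.relaxation
    if sd > 0:
        y = y + rng.normal(0.0, sd, y.shape)
    return DecaySeries(abscissa=t, intensities=y, kind=kind, noise_sd=sd or None)


def generate_viscometry_table(truth: ScenarioTruth, T: float = 298.0,
                              K: float = 0.005,
                              visc: hyd.ViscosityModel | None = None) -> dict:
    """Synthetic Ubbelohde table: (phi, efflux time, density) per composition.

    Densities interpolate the endpoint solvent densities linearly; efflux
    times are chosen so that rho * K * t reproduces the model viscosity,
    plus seeded timing noise.
    """
    visc = visc or hyd.ViscosityModel.default()
    rng = truth.rng(7)
    rows = []
    for phi in truth.compositions:
        rho = 1.104 + (1.19 - 1.104) * phi      # g/cm^3, D2O -> DMSO-d6
        eta = visc.eta(phi, T)                  # mPa s
        t = eta / (rho * K)                     # s
        t *= 1.0 + rng.normal(0.0, truth.noise.viscometry)
        rows.append({"phi_dmso": phi, "efflux_time_s": t, "density_g_cm3": rho})
    return {"temperature_K": T, "cell_constant_mm2_s2": K, "rows": rows}


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def _truth_to_dict(truth: ScenarioTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["population_params"]["semifolded_offsets"] = [
        list(x) for x in truth.population_params.semifolded_offsets]
    return d


def truth_from_dict(d: dict) -> ScenarioTruth:
    d = dict(d)
    pp = dict(d.pop("population_params"))
    pp["semifolded_offsets"] = tuple(tuple(x) for x in pp["semifolded_offsets"])
    noise = NoiseSpec(**d.pop("noise"))
    d["compositions"] = tuple(d["compositions"])
    d["temperatures"] = tuple(d["temperatures"])
    return ScenarioTruth(population_params=PopulationParams(**pp), noise=noise, **d)


def generate_scenario(truth: ScenarioTruth, outdir, *,
                      cest_temperatures=(310.0, 323.0, 333.0, 343.0),
                      omega1_list=CEST_POWERS_HZ,
                      compositions=None) -> Path:
    """Write a full dataset bundle (CSV + JSON sidecars) and its manifest.

    Layout: ``scenario.json`` at the root; one ``phi_<value>/`` folder per
    composition with relaxation, integral, DOSY and Z-spectrum tables.
    Regenerating with the same truth (incl. seed) is byte-identical.
    """
    from . import io as pio
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comps = list(compositions if compositions is not None else truth.compositions)
    manifest = {"truth": _truth_to_dict(truth), "seed": truth.seed,
                "compositions": comps, "cest_temperatures": list(cest_temperatures)}
    (outdir / "scenario.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    pio.write_viscometry(generate_viscometry_table(truth), outdir / "viscometry.csv")
    for phi in comps:
        sub = outdir / f"phi_{phi:.1f}"
        sub.mkdir(exist_ok=True)
        r1s, r2s = generate_relaxation_series(truth, phi)
        pio.write_temperature_series(r1s, sub / "r1_series.csv")
        pio.write_temperature_series(r2s, sub / "r2_series.csv")
        pio.write_temperature_series(generate_integral_series(truth, phi),
                                     sub / "integrals.csv")
        dosy = generate_dosy_series(truth, phi)
        pio.write_gradient_series(dosy, sub / "dosy.csv")
        for T in cest_temperatures:
            zs = generate_zspectra(truth, phi, T, omega1_list=omega1_list)
            for z in zs:
                stem = f"zspectrum_T{T:.0f}_w{z.omega1:.0f}"
                pio.write_zspectrum(z, sub / f"{stem}.csv")
    return outdir


def load_manifest(bundle_dir) -> dict:
    """Read a bundle manifest back; ``truth`` is reconstructed."""
    with open(Path(bundle_dir) / "scenario.json") as fh:
        manifest = json.load(fh)
    manifest["truth"] = truth_from_dict(manifest["truth"])
    return manifest
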