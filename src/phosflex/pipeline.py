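"""End-to-end analysis pipeline over a dataset bundle.

Given a bundle directory (one folder per solvent composition holding
relaxation series, Curie integrals, a DOSY attenuation table and CEST
Z-spectra, as written by :func:`phosflex.synthetic.generate_scenario` or
assembled from measured tables in the same schemas), the pipeline runs
the full inference chain per composition:

1. R1(T) maximum location (the omega0 * tau_c = 1 condition);
2. global R1/R2 fit for the hydrodynamic radius, with an optional
   Arrhenius exchange term on R2;
3. Curie-corrected integral ratios and the dark-state trend flag;
4. CEST dip linewidth extraction per irradiation power and the
   FWHM/sqrt(R2) dispersion slope, flagged against a matched
   no-exchange reference;
5. DOSY diffusion fit and Stokes-Einstein hydrodynamic diameter.

When the bundle carries a ``scenario.json`` manifest the report also
compares recovered quantities with the generative truth.  Stage failures
are recorded per stage and the report is still written (partial), with
the overall status reflecting the failures.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np

from . import hydrodynamics as hyd
from . import io as pio
from . import relaxometry as rx
from . import spin_physics as sp
from .exchange_cest import (DipFitError, FlatSpectrumError, detect_exchange,
                            dispersion_statistic, extract_dip_fwhm,
                            no_exchange_reference)
from .dosy import fit_diffusion_coefficient, hydrodynamic_diameter_from_dosy
from .synthetic import load_manifest

logger = logging.getLogger("phosflex")

__all__ = ["run_pipeline", "report_hash"]

_ZSPEC_RE = re.compile(r"zspectrum_T(?P<T>[0-9.]+)_w(?P<w>[0-9.]+)\.csv$")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report_hash(report: dict) -> str:
    """Stable hash of a report (canonical JSON, floats rounded).

    Filesystem paths are excluded so that reruns into different output
    directories hash identically.
    """
    payload = {k: v for k, v in report.items() if k != "report_hash"}
    if "config" in payload:
        payload = dict(payload)
        payload["config"] = {k: v for k, v in payload["config"].items()
                             if k not in ("input_dir", "output_dir")}
    blob = json.dumps(_round_floats(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _analyze_composition(phi_dir: Path, phi: float, cfg: pio.PipelineConfig,
                         visc: hyd.ViscosityModel, truth_delta_ppm: float | None) -> dict:
    result: dict = {"phi_dmso": phi}
    fld = sp.FieldSpec(B0=cfg.B0)
    larmor_hz = sp.larmor_frequency(sp.nucleus("31P"), fld)
    interactions = sp.default_p31_interactions()

    r1s = pio.read_temperature_series(phi_dir / "r1_series.csv", phi_dmso=phi)
    r2s = pio.read_temperature_series(phi_dir / "r2_series.csv", phi_dmso=phi)

    # 1. R1 maximum
    rmax = rx.detect_r1_maximum(r1s, larmor_hz)
    result["r1_maximum"] = {"T_max_K": rmax.T_max, "tau_c_at_max_s": rmax.tau_c_at_max,
                            "annotation": rmax.annotation}

    # 2. global relaxation fit
    prior = rx.ExchangePrior(
        enabled=cfg.fit.exchange_enabled,
        p_E=cfg.fit.exchange_p_E,
        delta_ppm=truth_delta_ppm if truth_delta_ppm is not None else cfg.fit.exchange_delta_ppm,
        log10_A_bounds=cfg.fit.kex_log10_A_bounds,
        ea_bounds_kj=cfg.fit.kex_ea_bounds_kj,
    )
    gfit = rx.global_relaxation_fit(r1s, r2s, visc, interactions, prior,
                                    phi_dmso=phi, B0=cfg.B0,
                                    r_h_bounds=cfg.fit.r_h_bounds)
    result["global_fit"] = {
        "r_H_A": gfit.r_H, "exchange_enabled": gfit.exchange_enabled,
        "log10_A": gfit.log10_A, "Ea_kj_mol": gfit.Ea_kj_mol,
        "cost": gfit.cost, "cost_no_exchange": gfit.cost_no_exchange,
        "warnings": list(gfit.warnings),
    }

    # 3. Curie ratios
    curie = rx.curie_corrected_ratio(
        pio.read_temperature_series(phi_dir / "integrals.csv", phi_dmso=phi))
    result["curie"] = {"ratios": list(curie.ratios), "slope_per_K": curie.slope,
                       "slope_se": curie.slope_se, "dark_state": curie.dark_state_flag}

    # 4. CEST dispersion
    T_grid, r1_vals, r2_vals = r1s.temperatures, r1s.values, r2s.values
    cest = {}
    if any(phi_dir.glob("zspectrum_*.csv")):
        # representative rates at each CEST temperature by interpolation
        def rate_at(T, vals):
            return float(np.interp(T, T_grid, vals))
        groups = sorted({float(_ZSPEC_RE.search(f.name).group("T"))
                         for f in phi_dir.glob("zspectrum_*.csv")
                         if _ZSPEC_RE.search(f.name)})
        cest = {}
        for T in groups:
            sub = _analyze_cest_single(phi_dir, T, rate_at(T, r1_vals),
                                       rate_at(T, r2_vals), cfg.fit.cest_flag_n_se)
            cest[f"{T:g}"] = sub
    result["cest"] = cest

    # 5. DOSY
    dosy_path = phi_dir / "dosy.csv"
    if dosy_path.exists():
        gs = pio.read_gradient_series(dosy_path)
        dfit = fit_diffusion_coefficient(gs)
        eta = visc.eta_pa_s(phi, cfg.dosy_temperature)
        result["dosy"] = {
            "D_m2_s": dfit.D, "D_se": dfit.D_se,
            "eta_mPa_s": eta * 1e3,
            "d_H_A": hydrodynamic_diameter_from_dosy(dfit.D, cfg.dosy_temperature, eta),
        }
    return result


def _analyze_cest_single(phi_dir: Path, T: float, r1: float, r2: float, n_se: float) -> dict:
    files = sorted(f for f in phi_dir.glob(f"zspectrum_T{T:g}_*.csv"))
    series = []
    carrier = t_ex = None
    for f in files:
        z = pio.read_zspectrum(f)
        carrier, t_ex = z.carrier, z.t_ex
        try:
            fwhm, _ = extract_dip_fwhm(z, window_ppm=2.5)
        except (FlatSpectrumError, DipFitError) as exc:
            logger.warning("dip extraction failed for %s: %s", f.name, exc)
            continue
        series.append((z.omega1, fwhm))
    if len(series) < 3:
        return {"error": "fewer than 3 usable powers"}
    disp = dispersion_statistic(series, r2)
    ref = no_exchange_reference(r1, r2, [w for w, _ in series], t_ex, carrier)
    disp = detect_exchange(disp, ref, n_se=n_se)
    return {"omega1_hz": list(disp.omega1),
            "fwhm_over_sqrt_r2": list(disp.ratios),
            "slope": disp.slope, "slope_se": disp.slope_se,
            "reference_slope": disp.reference_slope,
            "exchange": disp.exchange_flag}


def _truth_comparison(manifest: dict, conditions: list[dict]) -> dict:
    truth = manifest["truth"]
    cmp: dict = {"r_U_truth_A": truth.r_U, "Ea_truth_kj_mol": truth.k_ex_Ea_kj}
    for cond in conditions:
        if abs(cond["phi_dmso"] - 1.0) < 1e-9 and "global_fit" in cond:
            r_fit = cond["global_fit"]["r_H_A"]
            cmp["r_U_recovered_A"] = r_fit
            cmp["r_U_rel_error"] = abs(r_fit - truth.r_U) / truth.r_U
    return cmp


def run_pipeline(cfg: pio.PipelineConfig) -> dict:
    """Run the full analysis over a bundle; returns the report dict.

    The report is also written to ``<output_dir>/report.json`` and
    ``report.md``.  Stage failures are captured per composition under
    ``errors`` and flip ``status`` to ``"partial"``.
    """
    in_dir = Path(cfg.input_dir)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.generate_scenario:
        from .synthetic import ScenarioTruth, generate_scenario
        if not (in_dir / "scenario.json").exists():
            generate_scenario(ScenarioTruth(seed=cfg.seed), in_dir)

    visc = (hyd.ViscosityModel.from_json(cfg.viscosity_table)
            if cfg.viscosity_table else hyd.ViscosityModel.default())

    manifest = None
    truth_delta = None
    if (in_dir / "scenario.json").exists():
        manifest = load_manifest(in_dir)
        truth_delta = abs(manifest["truth"].delta_U - manifest["truth"].delta_F)

    phi_dirs = sorted(in_dir.glob("phi_*"))
    if not phi_dirs:
        raise FileNotFoundError(f"no phi_* condition folders found under {in_dir}")

    report: dict = {"config": json.loads(cfg.model_dump_json()), "conditions": [],
                    "errors": [], "status": "ok"}
    for phi_dir in phi_dirs:
        phi = float(phi_dir.name.split("_", 1)[1])
        logger.info("analyzing composition phi=%.1f", phi)
        try:
            report["conditions"].append(
                _analyze_composition(phi_dir, phi, cfg, visc, truth_delta))
        except Exception as exc:   # stage-level capture, partial report
            logger.error("composition phi=%.1f failed: %s", phi, exc)
            report["errors"].append({"phi_dmso": phi, "error": str(exc)})
            report["status"] = "partial"
    if manifest is not None:
        report["truth_comparison"] = _truth_comparison(manifest, report["conditions"])
    report["report_hash"] = report_hash(report)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# phosflex pipeline report", "",
             f"status: **{report['status']}**  hash: `{report['report_hash'][:16]}`", "",
             "| phi | r_H (A) | T(R1max) K | exchange (CEST) | dark state | d_H (A) |",
             "|----:|--------:|-----------:|:---------------:|:----------:|--------:|"]
    for c in report["conditions"]:
        tmax = c["r1_maximum"]["T_max_K"]
        cest_flags = [v.get("exchange") for v in c.get("cest", {}).values()
                      if isinstance(v, dict) and "exchange" in v]
        cest = ("yes" if any(cest_flags) else "no") if cest_flags else "-"
        dosy = c.get("dosy", {})
        tmax_str = f"{tmax:.0f}" if tmax is not None else "-"
        lines.append(
            f"| {c['phi_dmso']:.1f} | {c['global_fit']['r_H_A']:.2f} | {tmax_str} | "
            f"{cest} | {'yes' if c['curie']['dark_state'] else 'no'} | "
            f"{dosy.get('d_H_A', float('nan')):.2f} |")
    for err in report["errors"]:
        lines.append(f"\n- ERROR at phi={err['phi_dmso']}: {err['error']}")
    return "\n".join(lines) + "\n"
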