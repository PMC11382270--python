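"""Decay fitting, temperature-series analysis, Curie-corrected integrals."""

import numpy as np
import pytest

from phosflex import hydrodynamics as hyd
from phosflex import spin_physics as sp
from phosflex.relaxometry import (DecaySeries, ExchangePrior, TemperatureSeries,
                                  TruncatedDecayWarning, curie_corrected_ratio,
                                  detect_r1_maximum, fit_inversion_recovery,
                                  fit_monoexponential_decay, global_relaxation_fit)
from phosflex.synthetic import NoiseSpec, ScenarioTruth, generate_relaxation_series


def ir_series(t1=2.0, alpha=1.0, minf=1.0, noise=0.0, rng=None, n=12):
    t = np.geomspace(0.05, 5 * t1, n)
    y = minf * (1 - 2 * alpha * np.exp(-t / t1))
    if noise:
        y = y + rng.normal(0, noise, t.size)
    return DecaySeries(t, y, kind="inversion_recovery", noise_sd=noise or None)


def cpmg_series(t2=0.5, m0=1.0, n=12, depth=0.03):
    t = np.linspace(t2 / 50, -t2 * np.log(depth), n)
    return DecaySeries(t, m0 * np.exp(-t / t2), kind="cpmg")


class TestInversionRecovery:
    def test_noiseless_exact_recovery(self):
        res = fit_inversion_recovery(ir_series(t1=2.0))
        assert res.params["T1"] == pytest.approx(2.0, rel=1e-9)

    def test_imperfect_inversion_recovered(self):
        res = fit_inversion_recovery(ir_series(t1=1.3, alpha=0.9))
        assert res.params["inversion_efficiency"] == pytest.approx(0.9, abs=1e-6)

    def test_ci_coverage_monte_carlo(self):
        # 95% CI should cover the true T1 in at least 93/100 replicates
        rng = np.random.default_rng(0)
        cover = 0
        for _ in range(100):
            res = fit_inversion_recovery(ir_series(t1=2.0, noise=0.01, rng=rng))
            if abs(res.params["T1"] - 2.0) <= 1.96 * res.se("T1"):
                cover += 1
        assert cover >= 93

    def test_scale_equivariance(self):
        d = ir_series(t1=0.7, alpha=0.95)
        scaled = DecaySeries(d.abscissa, 37.0 * d.intensities, kind=d.kind)
        r1 = fit_inversion_recovery(d)
        r2 = fit_inversion_recovery(scaled)
        assert r1.params["T1"] == pytest.approx(r2.params["T1"], rel=1e-8)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_inversion_recovery(cpmg_series())


class TestCpmg:
    def test_noiseless_exact_recovery(self):
        res = fit_monoexponential_decay(cpmg_series(t2=0.5))
        assert res.params["T2"] == pytest.approx(0.5, rel=1e-9)

    def test_agrees_with_loglinear_oracle(self):
        d = cpmg_series(t2=0.31, m0=2.5)
        res = fit_monoexponential_decay(d)
        slope, _ = np.polyfit(d.abscissa, np.log(d.intensities), 1)
        assert res.params["T2"] == pytest.approx(-1.0 / slope, rel=1e-9)

    def test_truncated_decay_warns_but_fits(self):
        d = cpmg_series(t2=0.5, depth=0.5)
        with pytest.warns(TruncatedDecayWarning):
            res = fit_monoexponential_decay(d)
        assert res.params["T2"] == pytest.approx(0.5, rel=1e-6)

    def test_negative_intensities_beyond_floor_rejected(self):
        t = np.linspace(0.01, 2, 8)
        y = np.exp(-t / 0.5)
        y[-1] = -0.3
        with pytest.raises(ValueError):
            fit_monoexponential_decay(DecaySeries(t, y, kind="cpmg", noise_sd=0.01))

    def test_scale_equivariance(self):
        d = cpmg_series(t2=0.9)
        scaled = DecaySeries(d.abscissa, 0.01 * d.intensities, kind="cpmg")
        assert (fit_monoexponential_decay(d).params["T2"]
                == pytest.approx(fit_monoexponential_decay(scaled).params["T2"], rel=1e-8))


class TestR1Maximum:
    def _forward_r1(self, p31, field, taus):
        inter = sp.InteractionModel(csa_delta_sigma=150.0)
        return np.array([sp.relaxation_rates(p31, field, sp.MotionState(tau_c=t), inter)[0]
                         for t in taus])

    def test_recovers_designed_maximum_temperature(self, p31, field):
        # tau_c(T) crosses 1/omega0 exactly at 320 K by construction
        w0 = sp.larmor_frequency(p31, field, angular=True)
        T = np.arange(280.0, 361.0, 5.0)
        taus = (1.0 / w0) * np.exp(0.03 * (320.0 - T))
        r1 = self._forward_r1(p31, field, taus)
        res = detect_r1_maximum(TemperatureSeries(T, r1, kind="R1"),
                                sp.larmor_frequency(p31, field))
        assert res.T_max == pytest.approx(320.0, abs=2.0)
        assert res.tau_c_at_max == pytest.approx(1.0 / w0, rel=1e-12)

    def test_monotone_decreasing_returns_none(self, p31, field):
        T = np.arange(280.0, 341.0, 10.0)
        res = detect_r1_maximum(TemperatureSeries(T, np.linspace(3, 1, T.size)),
                                sp.larmor_frequency(p31, field))
        assert res.T_max is None
        assert "below" in res.annotation

    def test_monotone_increasing_annotated_cool_side(self, p31, field):
        T = np.arange(280.0, 341.0, 10.0)
        res = detect_r1_maximum(TemperatureSeries(T, np.linspace(1, 3, T.size)),
                                sp.larmor_frequency(p31, field))
        assert res.T_max is None
        assert "cool side" in res.annotation

    def test_too_few_points_rejected(self, p31, field):
        with pytest.raises(ValueError):
            detect_r1_maximum(TemperatureSeries(np.array([280.0, 290, 300, 310]),
                                                np.array([1.0, 2, 2, 1])),
                              sp.larmor_frequency(p31, field))

    def test_consistent_with_sed_forward_model(self, visc_model, p31, field):
        # generate noiseless DMSO-like data; the detected maximum must sit
        # where omega0 * tau_c(T) = 1 under the generating truth
        truth = ScenarioTruth(seed=0, noise=NoiseSpec(relaxation=0.0))
        r1s, _ = generate_relaxation_series(truth, 1.0, visc=visc_model)
        res = detect_r1_maximum(r1s, sp.larmor_frequency(p31, field))
        assert res.T_max is not None
        w0 = sp.larmor_frequency(p31, field, angular=True)
        eta = visc_model.eta_pa_s(1.0, res.T_max)
        tau = hyd.sed_rotational(truth.r_U, eta, res.T_max)
        assert w0 * tau == pytest.approx(1.0, rel=0.05)


class TestGlobalFit:
    def test_exchange_free_radius_recovery(self, visc_model, interactions):
        truth = ScenarioTruth(seed=4)
        r1s, r2s = generate_relaxation_series(truth, 1.0, visc=visc_model)
        res = global_relaxation_fit(r1s, r2s, visc_model, interactions,
                                    ExchangePrior(enabled=False), phi_dmso=1.0)
        assert res.r_H == pytest.approx(truth.r_U, rel=0.05)

    def test_radius_recovery_median_error(self, visc_model, interactions):
        errs = []
        for seed in range(200):
            truth = ScenarioTruth(seed=seed)
            r1s, r2s = generate_relaxation_series(truth, 1.0, visc=visc_model)
            res = global_relaxation_fit(r1s, r2s, visc_model, interactions,
                                        ExchangePrior(enabled=False), phi_dmso=1.0)
            errs.append(abs(res.r_H - truth.r_U) / truth.r_U)
        assert np.median(errs) < 0.03

    def test_water_like_exchange_identified_and_ea_recovered(self, visc_model, interactions):
        truth = ScenarioTruth(seed=3)
        r1s, r2s = generate_relaxation_series(truth, 0.0, visc=visc_model)
        prior = ExchangePrior(enabled=True, p_E=0.5,
                              delta_ppm=abs(truth.delta_U - truth.delta_F))
        res = global_relaxation_fit(r1s, r2s, visc_model, interactions, prior,
                                    phi_dmso=0.0)
        assert res.exchange_enabled
        assert res.Ea_kj_mol == pytest.approx(truth.k_ex_Ea_kj, rel=0.15)
        # exchange-free component falls with T while total R2 rises at the top
        assert r2s.values[-1] > r2s.values[-4]

    def test_exchange_disabled_flags_high_t_residuals(self, visc_model, interactions):
        truth = ScenarioTruth(seed=3)
        r1s, r2s = generate_relaxation_series(truth, 0.0, visc=visc_model)
        res = global_relaxation_fit(r1s, r2s, visc_model, interactions,
                                    ExchangePrior(enabled=False), phi_dmso=0.0)
        assert any("systematic positive R2 residuals" in w for w in res.warnings)

    def test_exchange_term_zeroed_when_unidentifiable(self, visc_model, interactions):
        truth = ScenarioTruth(seed=5)
        r1s, r2s = generate_relaxation_series(truth, 1.0, visc=visc_model)
        prior = ExchangePrior(enabled=True, p_E=0.5, delta_ppm=4.6)
        res = global_relaxation_fit(r1s, r2s, visc_model, interactions, prior,
                                    phi_dmso=1.0)
        assert res.exchange_enabled is False
        assert any("non-identifiable" in w for w in res.warnings)

    def test_temperature_grid_mismatch_rejected(self, visc_model, interactions):
        truth = ScenarioTruth(seed=1)
        r1s, r2s = generate_relaxation_series(truth, 1.0, visc=visc_model)
        other = TemperatureSeries(r2s.temperatures + 1.0, r2s.values, kind="R2")
        with pytest.raises(ValueError):
            global_relaxation_fit(r1s, other, visc_model, interactions, None)


class TestCurie:
    def test_pure_curie_behavior_is_flat(self):
        T = np.arange(298.0, 344.0, 5.0)
        res = curie_corrected_ratio(TemperatureSeries(T, 100.0 / T, kind="integral"))
        np.testing.assert_allclose(res.ratios, 1.0, atol=1e-12)
        assert res.dark_state_flag is False

    def test_growing_dark_pool_flags_and_decreases(self):
        # invisible pool rising from 0 to 30% over the range
        T = np.arange(298.0, 344.0, 5.0)
        p_dark = np.linspace(0.0, 0.3, T.size)
        res = curie_corrected_ratio(TemperatureSeries(T, (1 - p_dark) / T,
                                                      kind="integral"))
        assert np.all(np.diff(res.ratios) < 0)
        assert res.dark_state_flag is True

    def test_constant_integrals_increase_without_flag(self):
        T = np.arange(298.0, 344.0, 5.0)
        res = curie_corrected_ratio(TemperatureSeries(T, np.full(T.size, 2.0),
                                                      kind="integral"))
        assert np.all(np.diff(res.ratios) > 0)
        assert res.dark_state_flag is False

    def test_nonpositive_integral_rejected(self):
        T = np.array([298.0, 310.0, 320.0])
        with pytest.raises(ValueError):
            curie_corrected_ratio(TemperatureSeries(T, np.array([1.0, 0.0, 1.0]),
                                                    kind="integral"))
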