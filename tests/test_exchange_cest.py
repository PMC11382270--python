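"""Bloch-McConnell propagation, dip extraction, and the dispersion diagnostic."""

import numpy as np
import pytest

from phosflex import spin_physics as sp
from phosflex.exchange_cest import (DipFitError, FlatSpectrumError, TwoSiteExchange,
                                    ZSpectrum, bloch_mcconnell_zmag, detect_exchange,
                                    dispersion_statistic, extract_dip_fwhm,
                                    no_exchange_reference, simulate_zspectrum)

CARRIER = 201.85


def single_site(r1=1.0, r2=3.0, shift=0.0):
    return TwoSiteExchange(1.0, 0.0, 0.0, shift, shift, R1_G=r1, R1_E=r1,
                           R2_G=r2, R2_E=r2)


class TestPropagator:
    @pytest.mark.parametrize("offset", [0.0, 0.2, 0.5, 2.0])
    def test_matches_cw_steady_state_oracle(self, offset):
        # closed-form single-site cw steady state
        r1, r2, w1_hz = 1.0, 3.0, 50.0
        z = bloch_mcconnell_zmag(single_site(r1, r2), offset, w1_hz, 200.0, CARRIER)
        dw = 2 * np.pi * offset * CARRIER
        w1 = 2 * np.pi * w1_hz
        expected = r1 * (r2**2 + dw**2) / (r1 * (r2**2 + dw**2) + w1**2 * r2)
        assert z == pytest.approx(expected, abs=1e-9)

    def test_no_irradiation_returns_equilibrium(self):
        for off in (-5.0, 0.0, 7.3):
            assert bloch_mcconnell_zmag(single_site(), off, 0.0, 5.0, CARRIER) == 1.0

    def test_far_off_resonance_unperturbed(self):
        ex = TwoSiteExchange(0.9, 0.1, 50.0, 0.0, 2.3, R1_G=1, R2_G=3, R1_E=1, R2_E=3)
        assert bloch_mcconnell_zmag(ex, 100.0, 20.0, 5.0, CARRIER) > 0.99

    def test_zmag_bounded_over_parameter_grid(self):
        offsets = np.linspace(-15, 15, 31)
        for kex in (0.0, 10.0, 1e3, 1e5):
            for w1 in (5.0, 50.0, 500.0):
                ex = TwoSiteExchange(0.7, 0.3, kex, -8.7, -13.3,
                                     R1_G=0.5, R2_G=2, R1_E=0.5, R2_E=2)
                z = simulate_zspectrum(ex, offsets, w1, 5.0, CARRIER)
                assert np.all(z.z_values >= -1 - 1e-9)
                assert np.all(z.z_values <= 1 + 1e-9)

    def test_zero_exchange_is_population_weighted_sum(self):
        offsets = np.linspace(-16, 0, 161)
        pg, pe = 0.7, 0.3
        ex = TwoSiteExchange(pg, pe, 0.0, -8.7, -13.3, R1_G=1, R2_G=2, R1_E=1, R2_E=2)
        z = simulate_zspectrum(ex, offsets, 40.0, 5.0, CARRIER)
        za = simulate_zspectrum(single_site(1, 2, -8.7), offsets, 40.0, 5.0, CARRIER)
        zb = simulate_zspectrum(single_site(1, 2, -13.3), offsets, 40.0, 5.0, CARRIER)
        combined = pg * za.z_values + pe * zb.z_values
        np.testing.assert_allclose(z.z_values, combined, atol=1e-8)

    def test_fast_exchange_dip_collapses_to_mean_shift(self):
        offsets = np.arange(-16, 0, 0.1)
        pg, pe = 0.6, 0.4
        dw = 2 * np.pi * abs(-8.7 - -13.3) * CARRIER
        ex = TwoSiteExchange(pg, pe, 120 * dw, -8.7, -13.3, R1_G=1, R2_G=2,
                             R1_E=1, R2_E=2)
        z = simulate_zspectrum(ex, offsets, 30.0, 5.0, CARRIER)
        center = offsets[np.argmin(z.z_values)]
        expected = pg * -8.7 + pe * -13.3
        assert abs(center - expected) <= 0.1 + 1e-9


class TestSimulate:
    def test_symmetric_spectrum_about_site_shift(self):
        offsets = np.linspace(-10, 10, 201)
        z = simulate_zspectrum(single_site(1, 2, 0.0), offsets, 50.0, 5.0, CARRIER)
        np.testing.assert_allclose(z.z_values, z.z_values[::-1], atol=1e-10)

    def test_paper_grid_point_count(self):
        offsets = np.arange(-40.0, 40.0 + 0.125, 0.25)
        assert offsets.size == 321
        z = simulate_zspectrum(single_site(), offsets, 20.0, 5.0, CARRIER)
        assert z.offsets.size == 321

    def test_seeded_noise_is_reproducible(self):
        offsets = np.linspace(-5, 5, 51)
        z1 = simulate_zspectrum(single_site(), offsets, 50.0, 5.0, CARRIER,
                                noise_sd=0.01, seed=7)
        z2 = simulate_zspectrum(single_site(), offsets, 50.0, 5.0, CARRIER,
                                noise_sd=0.01, seed=7)
        assert np.array_equal(z1.z_values, z2.z_values)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_zspectrum(single_site(), [0.0, 1.0], 50.0, 5.0, CARRIER,
                               noise_sd=-0.1)

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            simulate_zspectrum(single_site(), [], 50.0, 5.0, CARRIER)


class TestDipExtraction:
    def test_exact_lorentzian_recovered(self):
        x = np.arange(-10, 10, 0.05)
        w = 1.7
        y = 1 - 0.5 * (w / 2) ** 2 / ((x - 1.2) ** 2 + (w / 2) ** 2)
        z = ZSpectrum(x, y, omega1=50.0, t_ex=5.0, carrier=CARRIER)
        fwhm, center = extract_dip_fwhm(z)
        assert fwhm == pytest.approx(w * CARRIER, rel=1e-3)
        assert center == pytest.approx(1.2, abs=1e-6)

    def test_power_broadening_is_monotone(self):
        offsets = np.linspace(-20, 20, 401)
        widths = []
        for w1 in (20.0, 50.0, 100.0, 200.0):
            z = simulate_zspectrum(single_site(), offsets, w1, 5.0, CARRIER)
            widths.append(extract_dip_fwhm(z)[0])
        assert np.all(np.diff(widths) > 0)

    def test_width_monotone_in_r2(self):
        offsets = np.linspace(-20, 20, 401)
        widths = []
        for r2 in (1.0, 2.0, 4.0, 8.0):
            z = simulate_zspectrum(single_site(r2=r2), offsets, 50.0, 5.0, CARRIER)
            widths.append(extract_dip_fwhm(z)[0])
        assert np.all(np.diff(widths) > 0)

    def test_flat_spectrum_raises(self):
        x = np.linspace(-5, 5, 101)
        z = ZSpectrum(x, np.ones_like(x), omega1=50.0, t_ex=5.0, carrier=CARRIER)
        with pytest.raises(FlatSpectrumError):
            extract_dip_fwhm(z)


class TestDispersion:
    def test_equal_widths_give_zero_slope(self):
        d = dispersion_statistic([(20, 100.0), (50, 100.0), (100, 100.0)], 2.0)
        assert d.slope == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(d.ratios, 100.0 / np.sqrt(2.0))

    def test_too_few_powers_rejected(self):
        with pytest.raises(ValueError):
            dispersion_statistic([(20, 100.0), (50, 120.0)], 2.0)

    def test_duplicate_powers_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            dispersion_statistic([(20, 100.0), (20, 110.0), (20, 120.0)], 2.0)

    def test_nonpositive_r2_rejected(self):
        with pytest.raises(ValueError):
            dispersion_statistic([(20, 100.0), (50, 120.0), (100, 150.0)], 0.0)

    def test_no_exchange_slope_invariant_in_r2(self):
        # steady-state irradiation: FWHM/sqrt(R2) slope must not depend on R2
        powers = [20, 30, 40, 50, 100, 150, 200]
        results = []
        for j, r2 in enumerate((1.0, 2.0, 4.0)):
            series = []
            for k, w1 in enumerate(powers):
                width = np.sqrt((2 * np.pi * w1) ** 2 * r2 + r2**2) / (2 * np.pi) / CARRIER
                offs = np.linspace(-6 * width, 6 * width, 121)
                z = simulate_zspectrum(single_site(1.0, r2), offs, w1, 15.0, CARRIER,
                                       noise_sd=0.005, seed=100 * j + k)
                series.append((w1, extract_dip_fwhm(z)[0]))
            results.append(dispersion_statistic(series, r2))
        for a in range(3):
            for b in range(a + 1, 3):
                diff = abs(results[a].slope - results[b].slope)
                pooled = np.hypot(results[a].slope_se, results[b].slope_se)
                assert diff <= 2 * pooled

    def test_slope_increases_with_exchange_rate(self):
        powers = [20, 50, 100, 200]
        offsets = np.arange(-40, 40.01, 0.25)
        slopes = []
        for kex in (1e2, 1e3, 1e4):
            ex = TwoSiteExchange(0.9, 0.1, kex, 0.0, 2.3, R1_G=1, R2_G=2,
                                 R1_E=1, R2_E=2)
            series = []
            for w1 in powers:
                z = simulate_zspectrum(ex, offsets, w1, 5.0, CARRIER)
                series.append((w1, extract_dip_fwhm(z)[0]))
            slopes.append(dispersion_statistic(series, 2.0).slope)
        assert np.all(np.diff(slopes) > 0)

    def test_detect_exchange_flags_against_reference(self):
        # slow dark-state exchange (k_ex ~ 5 1/s, 50% dark pool) on the
        # instrument's power ladder; R2 is the measured (exchange-bearing)
        # transverse rate, as a CPMG experiment would report
        powers = [20, 30, 40, 50, 100, 150, 200]
        r1, r2_meas = 1.1, 2.7
        ref = no_exchange_reference(r1, r2_meas, powers, 5.0, CARRIER)
        ex = TwoSiteExchange(0.5, 0.5, 5.0, -8.7, -13.3, R1_G=r1, R2_G=1.4,
                             R1_E=r1, R2_E=1.4)
        fine = np.concatenate([np.arange(c - 5, c + 5.01, 0.1)
                               for c in (-8.7, -13.3)])
        offsets = np.unique(np.round(np.concatenate(
            [np.arange(-40, 40.5, 1.0), fine]), 6))
        series = []
        for w1 in powers:
            z = simulate_zspectrum(ex, offsets, w1, 5.0, CARRIER)
            series.append((w1, extract_dip_fwhm(z, window_ppm=2.5)[0]))
        d = detect_exchange(dispersion_statistic(series, r2_meas), ref)
        assert d.exchange_flag is True
        d0 = detect_exchange(ref, ref)
        assert d0.exchange_flag is False


class TestFastExchangeOracle:
    def test_rex_matches_bm_dip_width(self, field, carrier_mhz):
        # exchanging dip width vs single site carrying R2 + Rex(formula)
        offsets = np.linspace(-30, 32, 601)
        for kex in (1e4, 3e4):   # 3.4x and 10x the shift separation
            ex = TwoSiteExchange(0.5, 0.5, kex, 0.0, 2.3, R1_G=1, R2_G=2,
                                 R1_E=1, R2_E=2)
            rex = sp.fast_exchange_broadening(ex, field, carrier_mhz=CARRIER)
            z_bm = simulate_zspectrum(ex, offsets, 30.0, 20.0, CARRIER)
            z_eq = simulate_zspectrum(single_site(1.0, 2.0 + rex, 1.15),
                                      offsets, 30.0, 20.0, CARRIER)
            fw_bm = extract_dip_fwhm(z_bm)[0]
            fw_eq = extract_dip_fwhm(z_eq)[0]
            assert fw_eq == pytest.approx(fw_bm, rel=0.10)
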