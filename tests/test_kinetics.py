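"""Baseline rates, detailed balance, calcium transient, rate factors."""

import numpy as np
import pytest

import sarcvae as sv
from sarcvae.kinetics import (RateFactors, apply_rate_factors,
                              calcium_transient, crossbridge_forward_rates,
                              fit_calcium_transient, free_energies, pca,
                              reverse_rate, srx_rates, thin_filament_rates)
from sarcvae.params import (CalciumParams, ConfigurationError, KineticParams,
                            ThinFilamentParams)

KIN = KineticParams()
THIN = ThinFilamentParams()


class TestCrossbridgeRates:
    def test_attachment_prefactor_at_zero_strain(self):
        r = crossbridge_forward_rates(0.0, 10.0, 1.0, KIN)
        assert r["rx12"] == pytest.approx(7.2)

    def test_attachment_halves_at_ln2(self):
        r = crossbridge_forward_rates(np.log(2.0), 10.0, 1.0, KIN)
        assert r["rx12"] == pytest.approx(3.6)

    def test_powerstroke_tanh_saturation(self):
        lo = crossbridge_forward_rates(0.0, 100.0, 1.0, KIN)["rx23"]
        hi = crossbridge_forward_rates(100.0, 0.0, 1.0, KIN)["rx23"]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(2 * KIN.A)  # 1.6 1/ms

    def test_detachment_rate_constant(self):
        r = crossbridge_forward_rates(3.0, 3.0, 0.5, KIN)
        assert r["rx51"] == pytest.approx(KIN.H)

    def test_all_rates_finite_nonnegative_over_strain_grid(self):
        u_w = np.linspace(0, 500, 200)
        u_s = np.linspace(500, 0, 200)
        f_s = np.linspace(-30, 30, 200)
        r = crossbridge_forward_rates(u_w, u_s, f_s, KIN)
        for v in r.values():
            assert np.all(np.isfinite(v))
            assert np.all(v >= 0.0)
            assert np.all(v <= KIN.rate_ceiling)

    def test_adp_release_slows_under_load(self):
        loaded = crossbridge_forward_rates(1.0, 1.0, 10.0, KIN)["rx34"]
        slack = crossbridge_forward_rates(1.0, 1.0, -5.0, KIN)["rx34"]
        assert loaded < KIN.D < slack <= 2 * KIN.D


class TestDetailedBalance:
    def test_equal_free_energy_symmetric(self):
        assert reverse_rate(1.7, -2.0, -2.0) == pytest.approx(1.7)

    def test_boltzmann_convention(self):
        # r_ji = r_ij * exp(G_j - G_i): stationary p_j/p_i = exp(-(G_j-G_i))
        r_rev = reverse_rate(1.0, 0.0, 1.0)
        assert r_rev == pytest.approx(np.e)
        r_fwd, g_i, g_j = 2.0, -1.0, -3.0
        r_rev = reverse_rate(r_fwd, g_i, g_j)
        assert r_fwd / r_rev == pytest.approx(np.exp(g_i - g_j))

    def test_two_state_stationarity_matches_boltzmann(self):
        from sarcvae.markov import build_rate_matrix, steady_state_init
        g_i, g_j = -1.0, 0.5
        r_fwd = 0.8
        q = build_rate_matrix({(1, 2): r_fwd,
                               (2, 1): float(reverse_rate(r_fwd, g_i, g_j))},
                              n_states=2)
        pi = steady_state_init(q)
        assert pi[1] / pi[0] == pytest.approx(np.exp(-(g_j - g_i)), rel=1e-9)

    def test_free_energy_offsets(self):
        g1, g2, g3, g4 = free_energies(2.0, 5.0, KIN)
        assert g1 == pytest.approx(-2.3)
        assert g2 == pytest.approx(2.0 - 4.3)
        assert g3 == pytest.approx(5.0 - 18.6)
        assert g4 == pytest.approx(5.0 - 20.72)


class TestSRX:
    def test_baseline_rates_balance_at_low_calcium(self):
        rx16, rx61 = srx_rates(1e-12, KIN)
        assert rx16 == pytest.approx(0.05)       # 50 s^-1
        assert rx61 == pytest.approx(0.05, rel=1e-6)

    def test_hill_midpoint(self):
        _, rx61 = srx_rates(KIN.ca50, KIN)
        assert rx61 == pytest.approx((KIN.rx61_base + KIN.rx61_max) / 2)

    def test_monotone_in_calcium(self):
        ca = np.logspace(-9, -3, 50)
        _, rx61 = srx_rates(ca, KIN)
        assert np.all(np.diff(rx61) >= 0)


class TestThinFilament:
    def test_reverse_rates_from_printed_equilibrium_constants(self):
        r = thin_filament_rates(1e-6, False, THIN)
        assert r["rt21"] == pytest.approx(37650.0 / 260000.0)   # 0.14481
        assert r["rt32"] == pytest.approx(33.4 / 130.0)         # 0.25692
        assert r["rt43"] == pytest.approx(0.13 / 0.91)          # 0.14286
        assert r["rt14"] == 0.0

    def test_calcium_cancels_in_rt21(self):
        a = thin_filament_rates(1e-7, False, THIN)["rt21"]
        b = thin_filament_rates(1e-4, False, THIN)["rt21"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_equilibrium_constants_recovered(self):
        ca = 3.3e-7
        r = thin_filament_rates(ca, False, THIN)
        assert r["rt12"] / r["rt21"] == pytest.approx(THIN.Kt1_coeff * ca)
        assert r["rt23"] / r["rt32"] == pytest.approx(THIN.Kt2)
        assert r["rt34"] / r["rt43"] == pytest.approx(THIN.Kt3)

    def test_cooperativity_boosts_activating_forwards_only(self):
        ca = 1e-6
        off = thin_filament_rates(ca, False, THIN)
        on = thin_filament_rates(ca, True, THIN)
        for k in ("rt12", "rt23", "rt34"):
            assert on[k] == pytest.approx(100.0 * off[k])
        for k in ("rt21", "rt32", "rt43", "rt41"):
            assert on[k] == pytest.approx(off[k])


class TestCalciumTransient:
    def test_peak_at_anchored_systolic_value(self):
        p = CalciumParams()
        t_peak = p.t_p ** (1.0 / p.a)
        assert calcium_transient(t_peak, p) == pytest.approx(p.ca_sys)

    def test_bounded_between_anchors(self):
        p = CalciumParams()
        ca = calcium_transient(np.linspace(0, 1, 1000), p)
        assert np.all(ca >= p.ca_dia - 1e-18)
        assert np.all(ca <= p.ca_sys + 1e-18)
        assert pca(ca).max() <= p.pca_dia + 1e-9

    def test_symmetric_when_a_is_one(self):
        p = CalciumParams(a=1.0, t_p=0.4, w=0.1)
        left = calcium_transient(0.3, p)
        right = calcium_transient(0.5, p)
        assert left == pytest.approx(right, rel=1e-12)

    def test_shape_fit_round_trip(self):
        truth = CalciumParams(a=0.3, t_p=0.5, w=0.15)
        t = np.linspace(0, 1, 500)
        fitted = fit_calcium_transient(t, calcium_transient(t, truth))
        assert fitted.a == pytest.approx(truth.a, abs=1e-6)
        assert fitted.t_p == pytest.approx(truth.t_p, abs=1e-6)
        assert fitted.w == pytest.approx(truth.w, abs=1e-6)

    def test_inverted_anchors_rejected(self):
        with pytest.raises(ConfigurationError):
            CalciumParams(pca_dia=6.0, pca_sys=7.0)


class TestRateFactors:
    def test_identity(self):
        base = {"rx12": 7.2, "rt41": 0.77, "other": 3.0}
        assert apply_rate_factors(base, RateFactors()) == base

    def test_single_coordinate_scaling(self):
        scaled = apply_rate_factors({"rx16": 0.05, "rx12": 7.2},
                                    RateFactors(rx16=0.1))
        assert scaled["rx16"] == pytest.approx(0.005)  # 5 s^-1
        assert scaled["rx12"] == pytest.approx(7.2)

    def test_prior_corners_accepted_and_outside_rejected(self):
        RateFactors(rt12=0.1, rx34=100.0)
        with pytest.raises(ConfigurationError):
            RateFactors(rt12=0.099)
        with pytest.raises(ConfigurationError):
            RateFactors(rx12=-1.0)

    def test_log10_round_trip(self):
        f = RateFactors(rx12=3.0, rt34=0.2)
        again = RateFactors.from_array(10 ** f.log10_array())
        assert np.allclose(again.to_array(), f.to_array())
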