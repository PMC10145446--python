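import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from abzpbpk.errors import InvalidInputError
from abzpbpk.particles import (DLMParams, ParticleBin, WeibullPSD, bin_mass_mg,
                               discretize_psd, dissolution_rates_mg_h, dlm_rate,
                               fit_weibull, monodisperse_bins, psd_quantile,
                               radius_from_mass, shrinking_sphere_radius_cm)


class TestWeibullQuantiles:
    def test_measured_distribution_quantiles(self, abz_psd):
        # closed-form quantiles of the laser-diffraction fit
        assert psd_quantile(0.10, abz_psd) == pytest.approx(0.9490, abs=2e-3)
        assert psd_quantile(0.90, abz_psd) == pytest.approx(19.876, abs=2e-2)

    def test_scale_parameter_definition(self, abz_psd):
        p = 1.0 - np.exp(-1.0)
        assert psd_quantile(p, abz_psd) == pytest.approx(abz_psd.beta, rel=1e-12)

    @given(p=st.floats(1e-6, 1 - 1e-6), alpha=st.floats(0.3, 5.0), beta=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_quantile_and_cdf_are_mutual_inverses(self, p, alpha, beta):
        psd = WeibullPSD(alpha=alpha, beta=beta)
        d = psd_quantile(p, psd)
        assert psd.cdf(d) == pytest.approx(p, abs=1e-10)

    def test_probability_bounds_enforced(self, abz_psd):
        with pytest.raises(InvalidInputError):
            psd_quantile(0.0, abz_psd)
        with pytest.raises(InvalidInputError):
            psd_quantile(1.0, abz_psd)


class TestFitWeibull:
    def test_exact_self_consistency(self):
        truth = WeibullPSD(alpha=1.5, beta=10.0)
        d = [psd_quantile(p, truth) for p in (0.1, 0.5, 0.9)]
        fit = fit_weibull(*d)
        assert fit.alpha == pytest.approx(1.5, rel=1e-9)
        assert fit.beta == pytest.approx(10.0, rel=1e-9)

    def test_measured_quantiles_are_inconsistent_but_fit(self):
        # the printed d10/d50/d90 cannot all lie on one Weibull curve; the
        # log-domain regression returns the compromise
        fit = fit_weibull(0.95, 4.1, 22.0)
        assert fit.alpha == pytest.approx(0.975, abs=0.02)
        assert fit.beta == pytest.approx(8.11, abs=0.2)

    def test_exponential_quantile_ratio(self):
        # alpha = 1 makes the diameter distribution exponential
        truth = WeibullPSD(alpha=1.0, beta=7.0)
        d10, d90 = psd_quantile(0.1, truth), psd_quantile(0.9, truth)
        assert d90 / d10 == pytest.approx(np.log(0.1) / np.log(0.9), rel=1e-9)

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_weibull(4.0, 2.0, 22.0)


class TestDiscretization:
    def test_mass_conservation(self, abz_psd):
        bins = discretize_psd(abz_psd, 400.0, 1.2, n_bins=20)
        assert sum(b.mass_mg(1.2) for b in bins) == pytest.approx(400.0, rel=1e-12)

    def test_single_bin_sits_at_median(self, abz_psd):
        (b,) = discretize_psd(abz_psd, 10.0, 1.2, n_bins=1)
        assert b.r_cm * 2e4 == pytest.approx(psd_quantile(0.5, abz_psd), rel=1e-9)

    def test_monodisperse_count_matches_sphere_mass(self):
        (b,) = monodisperse_bins(5.0, 40.0, 1.2)
        m_particle = 1.2 * (4 / 3) * np.pi * (5e-4) ** 3 * 1000.0
        assert b.N == pytest.approx(40.0 / m_particle, rel=1e-12)

    def test_radius_mass_round_trip(self):
        m = bin_mass_mg(1e6, 3e-4, 1.2)
        assert radius_from_mass(m, 1e6, 1.2) == pytest.approx(3e-4, rel=1e-12)


class TestDLMRate:
    def test_equilibrium_rate_is_zero(self):
        b = ParticleBin(N=1e6, r_cm=5e-4, r0_cm=5e-4)
        assert dlm_rate(b, 0.01, 0.01, DLMParams()) == 0.0

    def test_single_particle_hand_value(self):
        # 4*pi*D*r*(r+h)/h * dC with r = h = 10 um, D = 1e-5, dC = 0.01
        params = DLMParams(D_eff_cm2_s=1e-5, h_cap_um=30.0)
        b = ParticleBin(N=1.0, r_cm=10e-4, r0_cm=10e-4)
        rate_mg_s = dlm_rate(b, 0.01, 0.0, params) / 3600.0
        assert rate_mg_s == pytest.approx(2.5133e-9, rel=1e-4)

    def test_layer_thickness_caps_at_30_um(self):
        params = DLMParams(D_eff_cm2_s=1e-5, h_cap_um=30.0)
        rate_60 = dlm_rate(1.0, 0.01, 0.0, params, r_cm=60e-4)
        # with h fixed at 30 um the rate is 4*pi*D*r*(r+30)/30
        expect = 4 * np.pi * 1e-5 * 60e-4 * (60e-4 + 30e-4) / 30e-4 * 0.01 * 3600
        assert rate_60 == pytest.approx(expect, rel=1e-9)

    def test_supersaturated_bulk_clamps_to_zero_by_default(self):
        b = ParticleBin(N=1e6, r_cm=5e-4, r0_cm=5e-4)
        assert dlm_rate(b, 0.01, 0.02, DLMParams()) == 0.0
        assert dlm_rate(b, 0.01, 0.02, DLMParams(), allow_negative=True) < 0.0


class TestShrinkingSphereOracle:
    def test_numerical_trajectory_matches_closed_form(self):
        """Monodisperse bin dissolving into a sink held at zero concentration.

        In the h_eff = r regime the adopted rate law has the analytic
        solution r^2 = r0^2 - 4 D S t / rho; the ODE integration must track
        it within 0.5%.
        """
        params = DLMParams(D_eff_cm2_s=8e-6, density_g_cm3=1.2, h_cap_um=30.0,
                           k_cap_per_h=1e9)  # cap lifted: pure rate law
        r0 = 10e-4  # 10 um
        S = 0.01
        (b,) = monodisperse_bins(10.0, 5.0, params.density_g_cm3)
        N = b.N

        def rhs(t, y):
            return [-float(dissolution_rates_mg_h(np.array([max(y[0], 0.0)]),
                                                  np.array([N]), S, 0.0, params)[0])]

        m0 = bin_mass_mg(N, r0, params.density_g_cm3)
        # stop before complete depletion; the analytic form is exact there
        t_half = 0.6 * (r0**2 * params.density_g_cm3 * 1000.0) / (4 * params.D_eff_cm2_s * S * 3600)
        ts = np.linspace(0.01 * t_half, t_half, 8)
        sol = solve_ivp(rhs, (0, t_half), [m0], t_eval=ts, rtol=1e-10, atol=1e-14)
        r_num = radius_from_mass(sol.y[0], N, params.density_g_cm3)
        r_exact = shrinking_sphere_radius_cm(ts, r0, S, params)
        assert np.all(np.abs(r_num - r_exact) / r_exact < 0.005)
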