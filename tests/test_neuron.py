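"""Neuronal membrane mechanisms: gating kinetics, channel/pump/
cotransporter fluxes, and their stoichiometric assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tridomain as td
from tridomain.neuron import (
    active_fluxes,
    ca_decay_flux,
    cotransporter_fluxes,
    gating_derivatives,
    gating_rates,
    leak_flux,
    pump_flux_neuron,
    total_neuronal_fluxes,
)
from tridomain.simulator import _reversal_potentials

F = 9.648e4


class TestGatingRates:
    def test_alpha_m_removable_singularity_limit(self):
        # at phi_msn = -46.9 mV the expression is 0/0; its limit is
        # 3.2e5 * 0.004 = 1280 per second
        r = gating_rates(-0.0469, -0.065, 0.01)
        assert r.alpha_m == pytest.approx(1280.0, rel=1e-10)

    def test_series_branch_matches_direct_evaluation(self):
        # just outside the series cutoff the two branches must agree
        for eps in (1.1e-4, 5e-4, 1e-3):
            u = eps
            direct = u / math.expm1(u)
            series = 1.0 - u / 2.0 + u * u / 12.0
            assert series == pytest.approx(direct, rel=1e-6)

    def test_beta_q_is_unity(self):
        assert gating_rates(-0.05, -0.05, 5.0).beta_q == 1.0

    def test_chi_and_alpha_q_vanish_at_activation_offset(self):
        # free Ca exactly at the offset: both terms zero
        r = gating_rates(-0.065, -0.065, 99.8e-6 / 0.01)
        assert r.chi == 0.0
        assert r.alpha_q == 0.0

    def test_chi_and_alpha_q_clamps(self):
        r = gating_rates(-0.065, -0.065, 1.0)  # very high Ca
        assert r.chi == 1.0
        assert r.alpha_q == 10.0

    def test_alpha_c_continuous_at_piecewise_boundary(self):
        lo = gating_rates(-0.065, -0.0100001, 0.01)
        hi = gating_rates(-0.065, -0.0099999, 0.01)
        assert lo.alpha_c == pytest.approx(hi.alpha_c, rel=1e-4)

    def test_resting_fixed_points_match_published_initial_gating(self):
        """The published initial gating values are the steady states of
        the rate functions at the published resting potentials."""
        r = gating_rates(-66.9e-3, -66.9e-3, 0.01)
        assert r.alpha_h / (r.alpha_h + r.beta_h) == pytest.approx(0.9993, abs=1e-4)
        assert r.alpha_n / (r.alpha_n + r.beta_n) == pytest.approx(0.0003, abs=3e-5)
        assert r.alpha_s / (r.alpha_s + r.beta_s) == pytest.approx(0.0077, abs=3e-4)
        assert r.alpha_c / (r.alpha_c + r.beta_c) == pytest.approx(0.0057, abs=3e-4)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        phi_s=st.floats(-0.15, 0.08),
        phi_d=st.floats(-0.15, 0.08),
        ca=st.floats(1e-4, 50.0),
    )
    def test_rates_nonnegative_and_chi_bounded(self, phi_s, phi_d, ca):
        r = gating_rates(phi_s, phi_d, ca)
        for name in ("alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n",
                     "beta_n", "alpha_s", "beta_s", "alpha_c", "beta_c",
                     "alpha_q", "beta_q"):
            assert getattr(r, name) >= 0.0, name
        assert 0.0 <= r.chi <= 1.0
        assert 0.0 <= r.m_inf <= 1.0
        assert 0.0 <= r.z_inf <= 1.0


class TestGatingDerivatives:
    def test_fixed_point(self):
        r = gating_rates(-0.05, -0.05, 0.02)
        gating = np.array([
            r.alpha_h / (r.alpha_h + r.beta_h),
            r.alpha_n / (r.alpha_n + r.beta_n),
            r.alpha_s / (r.alpha_s + r.beta_s),
            r.alpha_c / (r.alpha_c + r.beta_c),
            r.alpha_q / (r.alpha_q + r.beta_q),
            r.z_inf,
        ])
        assert np.allclose(gating_derivatives(gating, r), 0.0, atol=1e-10)

    def test_boundary_growth_rate(self):
        # dx/dt = alpha at x = 0
        r = gating_rates(-0.05, -0.05, 0.02)
        d = gating_derivatives(np.zeros(6), r)
        assert d[0] == pytest.approx(r.alpha_h)
        assert d[5] == pytest.approx(r.z_inf)


class TestFluxes:
    def test_leak_zero_at_reversal(self):
        assert leak_flux(1.0, -0.07, -0.07, 1.0) == 0.0

    def test_leak_hand_value(self):
        # 1 S/m2, 10 mV driving force, monovalent cation
        assert leak_flux(1.0, -0.06, -0.07, 1.0) == pytest.approx(
            1e-2 / 96480, rel=1e-4
        )

    def test_chloride_leak_sign(self):
        # phi_m > E_Cl: chloride enters the cell, flux negative
        assert leak_flux(1.0, -0.06, -0.08, -1.0) < 0

    def test_active_fluxes_zero_when_gates_closed(self, params):
        r = gating_rates(-0.06, -0.06, 0.01)
        act = active_fluxes(-0.06, -0.06, np.zeros(6), r, 0.054, -0.098,
                            0.124, -0.098, params.membrane)
        for name in ("DR", "Ca", "AHP", "C"):
            assert act[name] == 0.0

    def test_transient_na_hand_value(self, params):
        import dataclasses

        r = gating_rates(-0.06, -0.06, 0.01)
        r = dataclasses.replace(r, m_inf=0.5)
        gating = np.array([1.0, 0, 0, 0, 0, 0])  # h = 1
        act = active_fluxes(0.0, -0.06, gating, r, 0.1, -0.098, 0.124, -0.098,
                            params.membrane)
        # 300 * 0.25 * (-0.1) / F
        assert act["Na"] == pytest.approx(300 * 0.25 * (-0.1) / 96480, rel=1e-4)

    def test_pump_sigmoid_midpoints(self):
        rho = 1.87e-6
        assert pump_flux_neuron(25.0, 3.5, rho) == pytest.approx(rho / 4)

    def test_pump_positive_and_monotone(self):
        na = np.linspace(1.0, 60.0, 40)
        vals = [pump_flux_neuron(x, 3.5, 1.0) for x in na]
        assert vals[0] > 0
        assert np.all(np.diff(vals) > 0)
        ke = np.linspace(0.5, 12.0, 40)
        vals = [pump_flux_neuron(25.0, x, 1.0) for x in ke]
        assert np.all(np.diff(vals) > 0)

    def test_kcc2_zero_at_equal_products(self):
        j_kcc2, _ = cotransporter_fluxes(10, 100, 7, 140, 3.5, 200, 1e-7, 2e-7)
        # [K]n[Cl]n = 700, [K]e[Cl]e = 700
        assert j_kcc2 == pytest.approx(0.0, abs=1e-20)

    def test_nkcc1_gate_midpoint(self):
        # f(K_e = 16) = 1/2; concentrations chosen so the K/Cl log is 0
        # and the Na/Cl log is exactly 1
        _, j = cotransporter_fluxes(
            math.e, 16.0, 1.0, 1.0, 16.0, 1.0, 0.0, 2.0
        )
        assert j == pytest.approx(2.0 * 0.5 * 1.0, rel=1e-12)

    def test_cotransporters_require_positive_concentrations(self):
        with pytest.raises(ValueError):
            cotransporter_fluxes(0.0, 1, 1, 1, 1, 1, 1e-7, 1e-7)

    def test_ca_decay_zero_at_basal_and_linear(self, params):
        mem = params.membrane
        A_m = params.geometry.A_m
        assert ca_decay_flux(0.01, 1437e-18, mem, A_m) == 0.0
        j1 = ca_decay_flux(0.02, 1437e-18, mem, A_m)
        j2 = ca_decay_flux(0.03, 1437e-18, mem, A_m)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)
        # hand arithmetic: 75 * 0.01 * (1437e-18/616e-12)
        assert j1 == pytest.approx(75 * 0.01 * 1437e-18 / 616e-12, rel=1e-12)


class TestTotals:
    def test_totals_are_sum_of_constituents(self, post_state, rparams):
        c = post_state.concentrations
        E_sn, E_dn, _, _ = _reversal_potentials(c, rparams)
        phi_msn, phi_mdn = -66.9e-3, -66.9e-3
        tot = total_neuronal_fluxes(
            c, post_state.V, post_state.gating, phi_msn, phi_mdn, E_sn, E_dn, rparams
        )
        mem = rparams.membrane
        r = gating_rates(phi_msn, phi_mdn, c[3, 3])
        act = active_fluxes(phi_msn, phi_mdn, post_state.gating, r,
                            E_sn[0], E_sn[1], E_dn[3], E_dn[1], mem)
        j_pump = pump_flux_neuron(c[0, 0], c[1, 1], mem.rho_n)
        j_kcc2, j_nkcc1 = cotransporter_fluxes(
            c[0, 0], c[1, 0], c[2, 0], c[0, 1], c[1, 1], c[2, 1],
            mem.U_kcc2, mem.U_nkcc1,
        )
        j_cadec = ca_decay_flux(c[3, 0], post_state.V[0], mem, rparams.geometry.A_m)
        j_Na_expected = (
            leak_flux(mem.g_Na_leak_n, phi_msn, E_sn[0], 1.0) + act["Na"]
            + 3 * j_pump + j_nkcc1 - 2 * j_cadec
        )
        assert tot.soma[0] == pytest.approx(j_Na_expected, rel=1e-12)
        assert tot.soma[3] == pytest.approx(j_cadec, rel=1e-12)

    def test_all_mechanisms_off_gives_zero(self, post_state, params):
        import dataclasses

        zeroed = {f: 0.0 for f in (
            "g_Na_leak_n", "g_K_leak_n", "g_Cl_leak_n", "g_Na", "g_DR",
            "g_Ca", "g_AHP", "g_C", "rho_n", "U_kcc2", "U_nkcc1", "U_Ca_dec",
        )}
        p = td.build_default_parameters({"membrane": zeroed})
        c = post_state.concentrations
        E_sn, E_dn, _, _ = _reversal_potentials(c, p)
        tot = total_neuronal_fluxes(
            c, post_state.V, post_state.gating, -0.06, -0.06, E_sn, E_dn, p
        )
        assert np.allclose(tot.soma, 0.0) and np.allclose(tot.dendrite, 0.0)

    def test_resting_totals_small(self, post_state, rparams):
        """At the published resting state the pump balances the leaks:
        per-ion totals are small compared to their largest constituent."""
        c = post_state.concentrations
        E_sn, E_dn, _, _ = _reversal_potentials(c, rparams)
        tot = total_neuronal_fluxes(
            c, post_state.V, post_state.gating, -66.9e-3, -66.9e-3, E_sn, E_dn, rparams
        )
        mem = rparams.membrane
        j_pump = pump_flux_neuron(c[0, 0], c[1, 1], mem.rho_n)
        assert abs(tot.soma[0]) < 0.12 * 3 * j_pump  # Na
        assert abs(tot.soma[1]) < 0.12 * 2 * j_pump  # K

    def test_mechanism_net_charge_factors(self, post_state, rparams):
        """Pump moves +1 net charge per cycle; KCC2, NKCC1, and the
        Ca/Na exchanger are electroneutral."""
        z = rparams.z
        # stoichiometric vectors (Na, K, Cl, Ca) per unit mechanism flux
        stoich = {
            "pump": np.array([3.0, -2.0, 0.0, 0.0]),
            "kcc2": np.array([0.0, 1.0, 1.0, 0.0]),
            "nkcc1": np.array([1.0, 1.0, 2.0, 0.0]),
            "ca_dec": np.array([-2.0, 0.0, 0.0, 1.0]),
        }
        expected_charge = {"pump": 1.0, "kcc2": 0.0, "nkcc1": 0.0, "ca_dec": 0.0}
        for name, vec in stoich.items():
            assert z @ vec == pytest.approx(expected_charge[name])
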