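"""Right-hand-side assembly, integration invariants, and presets."""

import numpy as np
import pytest

import tridomain as td
from tridomain._kernel import make_kernel
from tridomain.simulator import SolverSettings, rhs
from tridomain.state import SystemState
from .conftest import make_random_state


class TestRhs:
    def test_resting_derivatives_small(self, params):
        """From the settled calibrated state the slow dynamics are at a
        fixed point: concentration drift rates are tiny everywhere.
        (Membrane potentials carry a sub-microvolt fast-mode offset with
        a ~0.1 ms relaxation time, so instantaneous dQ/dt is not a
        meaningful drift measure; the short-run stability test covers
        the potentials.)"""
        state = td.build_initial_state("calibrated", params)
        from tridomain.glia import resolve_kir_baseline

        p = resolve_kir_baseline(params, state)
        dy = rhs(0.0, state, p)
        dN = dy[:24].reshape(4, 6)
        # concentration drift below 1e-3 mM/s everywhere (the settled
        # state still carries the fast axial mode at this amplitude)
        assert np.max(np.abs(dN / state.V)) < 1e-3
        # the ECS potential-equivalent drift (layer charge balance) is slow
        dphi = p.constants.F * (p.z @ dN) / (p.membrane.c_m * p.geometry.A_m)
        assert abs(dphi[1]) < 0.05e-3 and abs(dphi[4]) < 0.05e-3

    def test_zeroed_mechanisms_and_symmetric_state_give_zero_rhs(self):
        zeroed = {f: 0.0 for f in (
            "g_Na_leak_n", "g_K_leak_n", "g_Cl_leak_n", "g_Na", "g_DR",
            "g_Ca", "g_AHP", "g_C", "rho_n", "U_kcc2", "U_nkcc1", "U_Ca_dec",
            "g_Na_leak_g", "g_Cl_leak_g", "g_K_IR", "rho_g", "G_n", "G_g",
        )}
        p = td.build_default_parameters({"membrane": zeroed})
        state = td.build_initial_state("post_calibrated", p)
        # zero net charge everywhere -> all potentials zero
        state.X = p.z @ state.N
        from tridomain.glia import resolve_kir_baseline

        p = resolve_kir_baseline(p, state)
        from tridomain.neuron import gating_rates

        r = gating_rates(0.0, 0.0, state.concentrations[3, 3])
        state.gating = np.array([
            r.alpha_h / (r.alpha_h + r.beta_h),
            r.alpha_n / (r.alpha_n + r.beta_n),
            r.alpha_s / (r.alpha_s + r.beta_s),
            r.alpha_c / (r.alpha_c + r.beta_c),
            r.alpha_q / (r.alpha_q + r.beta_q),
            r.z_inf,
        ])
        dy = rhs(0.0, state, p)
        # gating fixed points carry O(rate * eps) round-off (~1e-13/s)
        assert np.allclose(dy[24:30], 0.0, atol=1e-11)
        assert np.allclose(dy[:24], 0.0, atol=1e-30)
        assert np.allclose(dy[30:], 0.0, atol=1e-40)

    def test_kernel_matches_modular_rhs(self, post_state, rparams):
        """The fused scalar kernel and the module-composed right-hand
        side are the same function."""
        rng = np.random.default_rng(99)
        for _ in range(15):
            st = make_random_state(post_state, rparams, rng)
            kern = make_kernel(rparams, st.X, st.M)
            d_mod = rhs(0.0, st, rparams)
            d_fast = kern(0.0, st.to_vector())[0]
            assert np.all(np.isfinite(d_fast))
            scale = np.maximum(np.abs(d_mod), 1e-30)
            assert np.max(np.abs(d_mod - d_fast) / scale) < 1e-9

    def test_single_ion_oracle(self, post_state, rparams):
        """dN/dt for K+ matches an independently assembled evaluation of
        the conservation equations (flux x area bookkeeping coded from
        scratch here)."""
        rng = np.random.default_rng(5)
        st = make_random_state(post_state, rparams, rng)
        p = rparams
        geo, con = p.geometry, p.constants
        c = st.concentrations
        pot = td.solve_potentials(st, p)
        from tridomain.simulator import _reversal_potentials
        from tridomain.neuron import (
            gating_rates, active_fluxes, leak_flux, pump_flux_neuron,
            cotransporter_fluxes,
        )
        from tridomain.glia import kir_flux, glial_pump_flux

        E_sn, E_dn, E_sg, E_dg = _reversal_potentials(c, p)
        mem = p.membrane
        K = 1  # ion row

        # membrane fluxes, soma and dendrite, neuron
        def j_K_neuron(comp_i, comp_e, phi_m, E):
            r = gating_rates(pot.phi_msn, pot.phi_mdn, c[3, 3])
            act = active_fluxes(pot.phi_msn, pot.phi_mdn, st.gating, r,
                                E_sn[0], E_sn[1], E_dn[3], E_dn[1], mem)
            jl = leak_flux(mem.g_K_leak_n, phi_m, E[1], 1.0)
            jp = pump_flux_neuron(c[0, comp_i], c[1, comp_e], mem.rho_n)
            jk, jn = cotransporter_fluxes(
                c[0, comp_i], c[1, comp_i], c[2, comp_i],
                c[0, comp_e], c[1, comp_e], c[2, comp_e],
                mem.U_kcc2, mem.U_nkcc1,
            )
            j = jl - 2 * jp + jn + jk
            j += act["DR"] if comp_i == 0 else act["AHP"] + act["C"]
            return j

        j_msn = j_K_neuron(0, 1, pot.phi_msn, E_sn)
        j_mdn = j_K_neuron(3, 4, pot.phi_mdn, E_dn)
        j_msg = kir_flux(pot.phi_msg, E_sg[1], c[1, 1], mem) - 2 * glial_pump_flux(
            c[0, 2], c[1, 1], mem
        )
        j_mdg = kir_flux(pot.phi_mdg, E_dg[1], c[1, 4], mem) - 2 * glial_pump_flux(
            c[0, 5], c[1, 4], mem
        )
        ion = p.ions[K]
        j_in = td.axial_flux(ion, "neuron", c[K, 0], c[K, 3], pot.phi_sn, pot.phi_dn,
                             geo, con)
        j_e = td.axial_flux(ion, "ecs", c[K, 1], c[K, 4], pot.phi_se, pot.phi_de,
                            geo, con)
        j_ig = td.axial_flux(ion, "glia", c[K, 2], c[K, 5], pot.phi_sg, pot.phi_dg,
                             geo, con)
        A_m, A_i, A_e = geo.A_m, geo.A_i, geo.A_e
        expected = np.array([
            -j_msn * A_m - j_in * A_i,
            +j_msn * A_m - j_e * A_e + j_msg * A_m,
            -j_msg * A_m - j_ig * A_i,
            -j_mdn * A_m + j_in * A_i,
            +j_mdn * A_m + j_e * A_e + j_mdg * A_m,
            -j_mdg * A_m + j_ig * A_i,
        ])
        dy = rhs(0.0, st, p)
        got = dy[:24].reshape(4, 6)[K]
        assert np.allclose(got, expected, rtol=1e-10)

    def test_nonfinite_derivative_is_reported(self, post_state, rparams):
        st = post_state.copy()
        st.N[1, 1] = -st.N[1, 1]  # negative extracellular K+
        with np.errstate(invalid="ignore"), pytest.raises(Exception):
            rhs(0.0, st, rparams)


class TestRunInvariants:
    def test_conservation_under_stimulus(self, fig3_traj_3s):
        """Total amount of every species is constant through the run:
        the stimulus moves ions, it never creates them."""
        traj = fig3_traj_3s
        totals = traj.N.sum(axis=2)  # (n, 4)
        rel = np.abs(totals - totals[0]) / totals[0]
        assert rel.max() < 1e-9

    def test_total_volume_conserved(self, fig3_traj_3s):
        V_tot = fig3_traj_3s.V.sum(axis=1)
        assert np.abs(V_tot - V_tot[0]).max() / V_tot[0] < 1e-9

    def test_loop_closure_along_trajectory(self, fig3_traj_3s, rparams):
        from tridomain.electrodiffusion import current_densities

        traj = fig3_traj_3s
        geo = rparams.geometry
        for i in range(0, len(traj), 250):
            st = traj.state_at(i)
            cd = current_densities(st, rparams)
            scale = max(abs(geo.A_i * cd.i_in), abs(geo.A_e * cd.i_e),
                        abs(geo.A_i * cd.i_ig), 1e-30)
            assert abs(cd.loop_residual(geo)) < 1e-10 * scale

    def test_gating_stays_bounded(self, fig4_traj_10s):
        g = fig4_traj_10s.gating
        assert g.min() >= -1e-9
        assert g.max() <= 1.0 + 1e-9

    def test_times_strictly_increasing_and_success(self, resting_traj):
        assert resting_traj.success
        assert np.all(np.diff(resting_traj.t) > 0)

    def test_vectorized_potentials_match_solver(self, fig3_traj_3s, rparams):
        from tridomain.electrodiffusion import solve_potentials

        traj = fig3_traj_3s
        phi = traj.potentials()
        for i in range(0, len(traj), 500):
            pot = solve_potentials(traj.state_at(i), rparams)
            # summation-order differences only
            assert np.allclose(phi[i], pot.phi, rtol=1e-8, atol=1e-12)

    def test_synaptic_run_deterministic(self, params):
        proto = td.SynapseProtocol(target="soma", rate=200.0, t_start=0.1,
                                   t_stop=0.5, seed=11)
        settings = SolverSettings(output_stride=1e-3)
        a = td.run(proto, (0.0, 0.5), settings, params)
        b = td.run(proto, (0.0, 0.5), settings, params)
        assert np.array_equal(a.N, b.N)

    def test_refinement_stability(self, params):
        """Halving the maximal step moves the first spikes by less than
        a millisecond."""
        proto = td.InjectionProtocol("K", "soma", 150e-12, 1.0, 8.0)
        fine = SolverSettings(max_step=5e-5, output_stride=2e-4)
        coarse = SolverSettings(max_step=1e-4, output_stride=2e-4)
        t_end = 1.3
        tr_a = td.run(proto, (0.0, t_end), coarse, params)
        tr_b = td.run(proto, (0.0, t_end), fine, params)
        sp_a = td.detect_spikes(tr_a.t, tr_a.membrane_potentials()[:, 0])
        sp_b = td.detect_spikes(tr_b.t, tr_b.membrane_potentials()[:, 0])
        n = min(len(sp_a), len(sp_b), 5)
        assert n >= 1
        assert np.max(np.abs(sp_a[:n] - sp_b[:n])) < 1e-3


class TestPresetsAndIO:
    def test_presets_match_protocol_descriptions(self):
        presets = td.protocol_presets()
        fig3 = presets["fig3"]
        assert fig3.protocol.species == "K"
        assert fig3.protocol.target == "soma"
        assert fig3.protocol.I_stim == pytest.approx(22e-12)
        assert (fig3.protocol.t_on, fig3.protocol.t_off) == (1.0, 600.0)
        fig4 = presets["fig4"]
        assert fig4.protocol.I_stim == pytest.approx(150e-12)
        assert fig4.protocol.t_off == 8.0
        fig7 = presets["fig7B"]
        assert fig7.protocol.rate == 300.0
        assert fig7.protocol.target == "soma"

    def test_injection_sweep_grid(self):
        protos = td.injection_sweep("Na", "dendrite")
        assert all(p.species == "Na" and p.target == "dendrite" for p in protos)
        amps = [p.I_stim for p in protos]
        assert np.all(np.diff(amps) > 0)

    def test_trajectory_roundtrip_hdf5(self, resting_traj, tmp_path):
        path = tmp_path / "traj.h5"
        resting_traj.save_hdf5(path)
        back = td.Trajectory.load_hdf5(path)
        assert np.array_equal(back.N, resting_traj.N)
        assert np.array_equal(back.t, resting_traj.t)

    def test_trajectory_csv_has_units_header(self, resting_traj, tmp_path):
        path = tmp_path / "traj.csv"
        resting_traj.save_csv(path)
        first = path.read_text().splitlines()[0]
        assert first.startswith("#") and "units" in first

    def test_dataframe_columns(self, resting_traj):
        df = resting_traj.to_dataframe()
        assert "c_K_se" in df.columns
        assert "phi_msn" in df.columns
        assert len(df) == len(resting_traj)
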