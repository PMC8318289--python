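"""Fused scalar right-hand-side kernel.

This is a performance path: it evaluates exactly the same model as the
modular :func:`tridomain.simulator.rhs` (which composes the
electrodiffusion, neuron, glia, and volume modules) but in one flat
function using plain Python floats, which cuts the per-call overhead by
roughly an order of magnitude.  Equivalence of the two paths is asserted
in the test suite on randomized states.

On an invalid state (nonpositive volume or concentration entering a
logarithm) the kernel returns an all-NaN derivative instead of raising,
which makes the adaptive integrator shrink its step and terminate with a
failure record rather than crash mid-run.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet

__all__ = ["make_kernel"]

_NAN36 = np.full(36, np.nan)


def _exprel_inv(u: float) -> float:
    # u/(e^u - 1) with a series branch through the removable singularity
    # and saturation branches where exp would over/underflow
    if -1e-4 < u < 1e-4:
        return 1.0 - u / 2.0 + u * u / 12.0
    if u > 700.0:
        return 0.0  # u e^-u below double-precision underflow
    if u < -700.0:
        return -u
    return u / math.expm1(u)


def make_kernel(params: ParameterSet, X, M):
    """Build ``kernel(t, y) -> (dy, aux)`` for fixed parameters/residuals.

    ``aux`` is ``(phi_msn, phi_mdn, E_Na_sn, E_K_sn, E_Ca_sn, E_Na_dn,
    E_K_dn, E_Ca_dn)``, the quantities synaptic stimulus corrections
    need.  The Kir baseline in ``params`` must be resolved (not NaN).
    """
    con, geo, mem = params.constants, params.geometry, params.membrane
    if math.isnan(mem.E_K_basal):
        raise ValueError("Kir baseline unresolved; apply resolve_kir_baseline first")
    F, RT = con.F, con.RT
    psifac = RT / F
    dx, A_m, A_i, A_e = geo.dx, geo.A_m, geo.A_i, geo.A_e
    li2, le2 = geo.lambda_i**2, geo.lambda_e**2
    D_Na, D_K, D_Cl, D_Ca = (float(d) for d in params.D)
    g_Ca_frac = params.ions[3].gamma
    qfac = mem.c_m * A_m
    X0, X1, X2, X3, X4, X5 = (float(x) for x in X)
    M0, M1, M2, M3, M4, M5 = (float(m) for m in M)
    GnRT, GgRT = mem.G_n * RT, mem.G_g * RT

    g_Na_leak_n, g_K_leak_n, g_Cl_leak_n = mem.g_Na_leak_n, mem.g_K_leak_n, mem.g_Cl_leak_n
    g_Na, g_DR, g_CaCh, g_AHP, g_C = mem.g_Na, mem.g_DR, mem.g_Ca, mem.g_AHP, mem.g_C
    rho_n, U_kcc2, U_nkcc1, U_Ca_dec = mem.rho_n, mem.U_kcc2, mem.U_nkcc1, mem.U_Ca_dec
    Ca_basal = mem.Ca_n_basal
    g_Na_leak_g, g_Cl_leak_g, g_K_IR, rho_g = (
        mem.g_Na_leak_g, mem.g_Cl_leak_g, mem.g_K_IR, mem.rho_g
    )
    Na_thr15 = mem.Na_g_threshold**1.5
    K_thr = mem.K_e_threshold
    K_e_b, E_K_b = mem.K_e_basal, mem.E_K_basal
    kir_c1 = 1.0 + math.exp(18.4 / 42.4)
    kir_c2 = 1.0 + math.exp(-(118.6 + E_K_b * 1000.0) / 44.1)

    # axial coefficient bundles (per ion)
    dif_n = (D_Na / li2 / dx, D_K / li2 / dx, D_Cl / li2 / dx, D_Ca * g_Ca_frac / li2 / dx)
    dif_e = (D_Na / le2 / dx, D_K / le2 / dx, D_Cl / le2 / dx, D_Ca / le2 / dx)
    fld_n = tuple(
        D * z * F / (li2 * RT * dx) for D, z in ((D_Na, 1), (D_K, 1), (D_Cl, -1), (D_Ca, 2))
    )
    fld_e = tuple(
        D * z * F / (le2 * RT * dx) for D, z in ((D_Na, 1), (D_K, 1), (D_Cl, -1), (D_Ca, 2))
    )
    sgf_n = F * F / (RT * li2)
    sgf_e = F * F / (RT * le2)
    idf_n = F / (li2 * dx)
    idf_e = F / (le2 * dx)
    exp, log = math.exp, math.log

    def kernel(t: float, y: np.ndarray):
        try:
            return _eval(t, y)
        except (OverflowError, ValueError):
            # wildly unphysical trial state (e.g. huge exponent); signal
            # the integrator to back off
            return _NAN36, None

    def _eval(t: float, y: np.ndarray):
        yl = y.tolist()
        (
            Na_sn, Na_se, Na_sg, Na_dn, Na_de, Na_dg,
            K_sn, K_se, K_sg, K_dn, K_de, K_dg,
            Cl_sn, Cl_se, Cl_sg, Cl_dn, Cl_de, Cl_dg,
            Ca_sn, Ca_se, Ca_sg, Ca_dn, Ca_de, Ca_dg,
            h, n_g, s_g, c_g, q_g, z_g,
            V_sn, V_se, V_sg, V_dn, V_de, V_dg,
        ) = yl
        if min(V_sn, V_se, V_sg, V_dn, V_de, V_dg) <= 0.0:
            return _NAN36, None
        # concentrations (mM)
        cNa_sn = Na_sn / V_sn; cNa_se = Na_se / V_se; cNa_sg = Na_sg / V_sg
        cNa_dn = Na_dn / V_dn; cNa_de = Na_de / V_de; cNa_dg = Na_dg / V_dg
        cK_sn = K_sn / V_sn; cK_se = K_se / V_se; cK_sg = K_sg / V_sg
        cK_dn = K_dn / V_dn; cK_de = K_de / V_de; cK_dg = K_dg / V_dg
        cCl_sn = Cl_sn / V_sn; cCl_se = Cl_se / V_se; cCl_sg = Cl_sg / V_sg
        cCl_dn = Cl_dn / V_dn; cCl_de = Cl_de / V_de; cCl_dg = Cl_dg / V_dg
        cCa_sn = Ca_sn / V_sn; cCa_se = Ca_se / V_se
        cCa_dn = Ca_dn / V_dn; cCa_de = Ca_de / V_de

        if (
            min(
                cNa_sn, cNa_se, cNa_sg, cNa_dn, cNa_de, cNa_dg,
                cK_sn, cK_se, cK_sg, cK_dn, cK_de, cK_dg,
                cCl_sn, cCl_se, cCl_sg, cCl_dn, cCl_de, cCl_dg,
                cCa_sn, cCa_se, cCa_dn, cCa_de,
            )
            <= 0.0
        ):
            return _NAN36, None

        # net compartment charges (C) including static residuals
        Q_sn = F * (Na_sn + K_sn - Cl_sn + 2.0 * Ca_sn - X0)
        Q_se = F * (Na_se + K_se - Cl_se + 2.0 * Ca_se - X1)
        Q_sg = F * (Na_sg + K_sg - Cl_sg - X2)
        Q_dn = F * (Na_dn + K_dn - Cl_dn + 2.0 * Ca_dn - X3)
        Q_dg = F * (Na_dg + K_dg - Cl_dg - X5)

        phi_mdn = Q_dn / qfac
        phi_mdg = Q_dg / qfac
        phi_msn = Q_sn / qfac
        phi_msg = Q_sg / qfac

        # gamma-weighted mean concentrations (neuron) / plain means
        bNa_n = (cNa_dn + cNa_sn) / 2.0
        bK_n = (cK_dn + cK_sn) / 2.0
        bCl_n = (cCl_dn + cCl_sn) / 2.0
        bCa_n = g_Ca_frac * (cCa_dn + cCa_sn) / 2.0
        bNa_e = (cNa_de + cNa_se) / 2.0
        bK_e = (cK_de + cK_se) / 2.0
        bCl_e = (cCl_de + cCl_se) / 2.0
        bCa_e = (cCa_de + cCa_se) / 2.0
        bNa_g = (cNa_dg + cNa_sg) / 2.0
        bK_g = (cK_dg + cK_sg) / 2.0
        bCl_g = (cCl_dg + cCl_sg) / 2.0

        sig_n = sgf_n * (D_Na * bNa_n + D_K * bK_n + D_Cl * bCl_n + 4.0 * D_Ca * bCa_n)
        sig_e = sgf_e * (D_Na * bNa_e + D_K * bK_e + D_Cl * bCl_e + 4.0 * D_Ca * bCa_e)
        sig_g = sgf_n * (D_Na * bNa_g + D_K * bK_g + D_Cl * bCl_g)

        idiff_n = -idf_n * (
            D_Na * (cNa_dn - cNa_sn) + D_K * (cK_dn - cK_sn)
            - D_Cl * (cCl_dn - cCl_sn) + 2.0 * D_Ca * g_Ca_frac * (cCa_dn - cCa_sn)
        )
        idiff_e = -idf_e * (
            D_Na * (cNa_de - cNa_se) + D_K * (cK_de - cK_se)
            - D_Cl * (cCl_de - cCl_se) + 2.0 * D_Ca * (cCa_de - cCa_se)
        )
        idiff_g = -idf_n * (
            D_Na * (cNa_dg - cNa_sg) + D_K * (cK_dg - cK_sg) - D_Cl * (cCl_dg - cCl_sg)
        )

        phi_se = (
            -dx * A_i * idiff_n
            + A_i * sig_n * (phi_mdn - phi_msn)
            - dx * A_i * idiff_g
            + A_i * sig_g * (phi_mdg - phi_msg)
            - dx * A_e * idiff_e
        ) / (A_e * sig_e + A_i * sig_n + A_i * sig_g)
        phi_sn = phi_msn + phi_se
        phi_sg = phi_msg + phi_se
        phi_dn = phi_mdn
        phi_dg = phi_mdg

        # axial flux densities, soma -> dendrite positive
        dphi_n = (phi_dn - phi_sn) / dx
        dphi_e = (0.0 - phi_se) / dx
        dphi_g = (phi_dg - phi_sg) / dx
        jNa_in = -dif_n[0] * (cNa_dn - cNa_sn) - fld_n[0] * bNa_n * dx * dphi_n
        jK_in = -dif_n[1] * (cK_dn - cK_sn) - fld_n[1] * bK_n * dx * dphi_n
        jCl_in = -dif_n[2] * (cCl_dn - cCl_sn) - fld_n[2] * bCl_n * dx * dphi_n
        jCa_in = -dif_n[3] * (cCa_dn - cCa_sn) - fld_n[3] * bCa_n * dx * dphi_n
        jNa_e = -dif_e[0] * (cNa_de - cNa_se) - fld_e[0] * bNa_e * dx * dphi_e
        jK_e = -dif_e[1] * (cK_de - cK_se) - fld_e[1] * bK_e * dx * dphi_e
        jCl_e = -dif_e[2] * (cCl_de - cCl_se) - fld_e[2] * bCl_e * dx * dphi_e
        jCa_e = -dif_e[3] * (cCa_de - cCa_se) - fld_e[3] * bCa_e * dx * dphi_e
        jNa_ig = -dif_n[0] * (cNa_dg - cNa_sg) - fld_n[0] * bNa_g * dx * dphi_g
        jK_ig = -dif_n[1] * (cK_dg - cK_sg) - fld_n[1] * bK_g * dx * dphi_g
        jCl_ig = -dif_n[2] * (cCl_dg - cCl_sg) - fld_n[2] * bCl_g * dx * dphi_g

        # reversal potentials (V)
        E_Na_sn = psifac * log(cNa_se / cNa_sn)
        E_K_sn = psifac * log(cK_se / cK_sn)
        E_Cl_sn = -psifac * log(cCl_se / cCl_sn)
        E_Na_dn = psifac * log(cNa_de / cNa_dn)
        E_K_dn = psifac * log(cK_de / cK_dn)
        E_Cl_dn = -psifac * log(cCl_de / cCl_dn)
        E_Ca_sn = 0.5 * psifac * log(cCa_se / (g_Ca_frac * cCa_sn))
        E_Ca_dn = 0.5 * psifac * log(cCa_de / (g_Ca_frac * cCa_dn))
        E_Na_sg = psifac * log(cNa_se / cNa_sg)
        E_K_sg = psifac * log(cK_se / cK_sg)
        E_Cl_sg = -psifac * log(cCl_se / cCl_sg)
        E_Na_dg = psifac * log(cNa_de / cNa_dg)
        E_K_dg = psifac * log(cK_de / cK_dg)
        E_Cl_dg = -psifac * log(cCl_de / cCl_dg)

        # gating rates (1/s)
        phi_1 = phi_msn + 0.0469
        alpha_m = 1280.0 * _exprel_inv(-phi_1 / 0.004)
        phi_2 = phi_msn + 0.0199
        beta_m = 1400.0 * _exprel_inv(phi_2 / 0.005)
        m_inf = alpha_m / (alpha_m + beta_m)
        alpha_h = 128.0 * exp((-0.043 - phi_msn) / 0.018)
        beta_h = 4000.0 / (1.0 + exp(-(phi_msn + 0.02) / 0.005))
        alpha_n = 80.0 * _exprel_inv(-(phi_msn + 0.0249) / 0.005)
        beta_n = 250.0 * exp(-(phi_msn + 0.04) / 0.04)
        alpha_s = 1600.0 / (1.0 + exp(-72.0 * (phi_mdn - 0.005)))
        beta_s = 100.0 * _exprel_inv((phi_mdn + 0.0089) / 0.005)
        z_inf = 1.0 / (1.0 + exp((phi_mdn + 0.03) / 0.001))
        phi_9 = phi_mdn + 0.0535
        if phi_mdn <= -0.01:
            alpha_c = 52.7 * exp((phi_mdn + 0.05) / 0.011 - phi_9 / 0.027)
            beta_c = max(2000.0 * exp(-phi_9 / 0.027) - alpha_c, 0.0)
        else:
            alpha_c = 2000.0 * exp(-phi_9 / 0.027)
            beta_c = 0.0
        free_Ca = g_Ca_frac * cCa_dn
        chi = (free_Ca - 99.8e-6) / 2.5e-4
        chi = 0.0 if chi < 0.0 else (1.0 if chi > 1.0 else chi)
        alpha_q = 2e4 * (free_Ca - 99.8e-6)
        alpha_q = 0.0 if alpha_q < 0.0 else (10.0 if alpha_q > 10.0 else alpha_q)

        # neuronal membrane fluxes (mol/(m^2 s)), outward positive
        j_pump_s = rho_n / (1.0 + exp((25.0 - cNa_sn) / 3.0)) / (1.0 + exp(3.5 - cK_se))
        j_pump_d = rho_n / (1.0 + exp((25.0 - cNa_dn) / 3.0)) / (1.0 + exp(3.5 - cK_de))
        lg_kcl_s = log(cK_sn * cCl_sn / (cK_se * cCl_se))
        lg_kcl_d = log(cK_dn * cCl_dn / (cK_de * cCl_de))
        j_kcc2_s = U_kcc2 * lg_kcl_s
        j_kcc2_d = U_kcc2 * lg_kcl_d
        j_nkcc1_s = (
            U_nkcc1 / (1.0 + exp(16.0 - cK_se))
            * (lg_kcl_s + log(cNa_sn * cCl_sn / (cNa_se * cCl_se)))
        )
        j_nkcc1_d = (
            U_nkcc1 / (1.0 + exp(16.0 - cK_de))
            * (lg_kcl_d + log(cNa_dn * cCl_dn / (cNa_de * cCl_de)))
        )
        j_cadec_s = U_Ca_dec * (cCa_sn - Ca_basal) * V_sn / A_m
        j_cadec_d = U_Ca_dec * (cCa_dn - Ca_basal) * V_dn / A_m

        j_Na_act = g_Na * m_inf * m_inf * h * (phi_msn - E_Na_sn) / F
        j_DR = g_DR * n_g * (phi_msn - E_K_sn) / F
        j_Ca_act = g_CaCh * s_g * s_g * z_g * (phi_mdn - E_Ca_dn) / (2.0 * F)
        j_AHP = g_AHP * q_g * (phi_mdn - E_K_dn) / F
        j_C = g_C * c_g * chi * (phi_mdn - E_K_dn) / F

        jNa_msn = (
            g_Na_leak_n * (phi_msn - E_Na_sn) / F + j_Na_act
            + 3.0 * j_pump_s + j_nkcc1_s - 2.0 * j_cadec_s
        )
        jK_msn = (
            g_K_leak_n * (phi_msn - E_K_sn) / F + j_DR
            - 2.0 * j_pump_s + j_nkcc1_s + j_kcc2_s
        )
        jCl_msn = -g_Cl_leak_n * (phi_msn - E_Cl_sn) / F + 2.0 * j_nkcc1_s + j_kcc2_s
        jCa_msn = j_cadec_s
        jNa_mdn = (
            g_Na_leak_n * (phi_mdn - E_Na_dn) / F
            + 3.0 * j_pump_d + j_nkcc1_d - 2.0 * j_cadec_d
        )
        jK_mdn = (
            g_K_leak_n * (phi_mdn - E_K_dn) / F + j_AHP + j_C
            - 2.0 * j_pump_d + j_nkcc1_d + j_kcc2_d
        )
        jCl_mdn = -g_Cl_leak_n * (phi_mdn - E_Cl_dn) / F + 2.0 * j_nkcc1_d + j_kcc2_d
        jCa_mdn = j_Ca_act + j_cadec_d

        # glial membrane fluxes
        na15_s = cNa_sg**1.5
        na15_d = cNa_dg**1.5
        j_pump_gs = rho_g * na15_s / (na15_s + Na_thr15) * cK_se / (cK_se + K_thr)
        j_pump_gd = rho_g * na15_d / (na15_d + Na_thr15) * cK_de / (cK_de + K_thr)
        f_kir_s = (
            (cK_se / K_e_b)
            * kir_c1 / (1.0 + exp(((phi_msg - E_K_sg) * 1000.0 + 18.5) / 42.5))
            * kir_c2 / (1.0 + exp(-(118.6 + phi_msg * 1000.0) / 44.1))
        )
        f_kir_d = (
            (cK_de / K_e_b)
            * kir_c1 / (1.0 + exp(((phi_mdg - E_K_dg) * 1000.0 + 18.5) / 42.5))
            * kir_c2 / (1.0 + exp(-(118.6 + phi_mdg * 1000.0) / 44.1))
        )
        jNa_msg = g_Na_leak_g * (phi_msg - E_Na_sg) / F + 3.0 * j_pump_gs
        jK_msg = g_K_IR * f_kir_s * (phi_msg - E_K_sg) / F - 2.0 * j_pump_gs
        jCl_msg = -g_Cl_leak_g * (phi_msg - E_Cl_sg) / F
        jNa_mdg = g_Na_leak_g * (phi_mdg - E_Na_dg) / F + 3.0 * j_pump_gd
        jK_mdg = g_K_IR * f_kir_d * (phi_mdg - E_K_dg) / F - 2.0 * j_pump_gd
        jCl_mdg = -g_Cl_leak_g * (phi_mdg - E_Cl_dg) / F

        # volume dynamics (baseline-corrected osmolarity deviations)
        dev_sn = (Na_sn + K_sn + Cl_sn + Ca_sn) / V_sn - M0
        dev_se = (Na_se + K_se + Cl_se + Ca_se) / V_se - M1
        dev_sg = (Na_sg + K_sg + Cl_sg) / V_sg - M2
        dev_dn = (Na_dn + K_dn + Cl_dn + Ca_dn) / V_dn - M3
        dev_de = (Na_de + K_de + Cl_de + Ca_de) / V_de - M4
        dev_dg = (Na_dg + K_dg + Cl_dg) / V_dg - M5
        dV_sn = -GnRT * (dev_se - dev_sn)
        dV_sg = -GgRT * (dev_se - dev_sg)
        dV_dn = -GnRT * (dev_de - dev_dn)
        dV_dg = -GgRT * (dev_de - dev_dg)

        dy = np.array(
            [
                # Na
                -jNa_msn * A_m - jNa_in * A_i,
                +jNa_msn * A_m - jNa_e * A_e + jNa_msg * A_m,
                -jNa_msg * A_m - jNa_ig * A_i,
                -jNa_mdn * A_m + jNa_in * A_i,
                +jNa_mdn * A_m + jNa_e * A_e + jNa_mdg * A_m,
                -jNa_mdg * A_m + jNa_ig * A_i,
                # K
                -jK_msn * A_m - jK_in * A_i,
                +jK_msn * A_m - jK_e * A_e + jK_msg * A_m,
                -jK_msg * A_m - jK_ig * A_i,
                -jK_mdn * A_m + jK_in * A_i,
                +jK_mdn * A_m + jK_e * A_e + jK_mdg * A_m,
                -jK_mdg * A_m + jK_ig * A_i,
                # Cl
                -jCl_msn * A_m - jCl_in * A_i,
                +jCl_msn * A_m - jCl_e * A_e + jCl_msg * A_m,
                -jCl_msg * A_m - jCl_ig * A_i,
                -jCl_mdn * A_m + jCl_in * A_i,
                +jCl_mdn * A_m + jCl_e * A_e + jCl_mdg * A_m,
                -jCl_mdg * A_m + jCl_ig * A_i,
                # Ca (no glial Ca fluxes; glial amounts stay exactly zero)
                -jCa_msn * A_m - jCa_in * A_i,
                +jCa_msn * A_m - jCa_e * A_e,
                0.0,
                -jCa_mdn * A_m + jCa_in * A_i,
                +jCa_mdn * A_m + jCa_e * A_e,
                0.0,
                # gating
                alpha_h * (1.0 - h) - beta_h * h,
                alpha_n * (1.0 - n_g) - beta_n * n_g,
                alpha_s * (1.0 - s_g) - beta_s * s_g,
                alpha_c * (1.0 - c_g) - beta_c * c_g,
                alpha_q * (1.0 - q_g) - beta_q_const * q_g,
                z_inf - z_g,
                # volumes
                dV_sn,
                -(dV_sn + dV_sg),
                dV_sg,
                dV_dn,
                -(dV_dn + dV_dg),
                dV_dg,
            ]
        )
        aux = (phi_msn, phi_mdn, E_Na_sn, E_K_sn, E_Ca_sn, E_Na_dn, E_K_dn, E_Ca_dn)
        return dy, aux

    beta_q_const = 1.0
    return kernel
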