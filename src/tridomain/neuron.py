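"""Neuronal membrane mechanisms.

A two-compartment (soma + dendrite) neuron in the Pinsky-Rinzel style,
formulated in fluxes (mol/(m^2 s)) rather than currents so that ion
bookkeeping is explicit.  The soma carries transient Na+ and delayed
rectifier K+ channels; the dendrite carries a voltage-gated Ca2+ channel,
a voltage-gated afterhyperpolarization K+ channel, and a Ca2+-activated
K+ channel.  Both compartments carry Na+/K+/Cl- leaks, a 3Na+/2K+ pump,
KCC2 and NKCC1 cotransporters, and a 2Na+/Ca2+ exchanger that mediates
Ca2+ decay toward its basal level.

All voltages are in V, concentrations in mM, rates in 1/s.  Gating
variables: m (instantaneous, m_inf only), h, n (soma); s, c, q, z
(dendrite); z relaxes with a fixed 1 s time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import MembraneParams, ParameterSet

__all__ = [
    "GatingRates",
    "NeuronalFluxes",
    "gating_rates",
    "gating_derivatives",
    "leak_flux",
    "active_fluxes",
    "pump_flux_neuron",
    "cotransporter_fluxes",
    "ca_decay_flux",
    "total_neuronal_fluxes",
]

#: |u| below which x/(e^x - 1) switches to its series expansion.  The
#: expression has a removable singularity at u = 0 that falls at
#: physiological voltages; naive evaluation yields 0/0 there.
_SERIES_CUTOFF = 1e-4


def _exprel_inv(u: float) -> float:
    """u / (exp(u) - 1), continuous through u = 0, saturating where the
    exponential would over/underflow."""
    if abs(u) < _SERIES_CUTOFF:
        return 1.0 - u / 2.0 + u * u / 12.0
    if u > 700.0:
        return 0.0
    if u < -700.0:
        return -u
    return u / np.expm1(u)


@dataclass(frozen=True)
class GatingRates:
    """Voltage- and Ca-dependent rate constants (1/s) and steady states."""

    alpha_m: float
    beta_m: float
    m_inf: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    alpha_s: float
    beta_s: float
    alpha_c: float
    beta_c: float
    alpha_q: float
    beta_q: float
    z_inf: float
    tau_z: float
    chi: float


def gating_rates(phi_msn: float, phi_mdn: float, Ca_dn: float, gamma_Ca: float = 0.01) -> GatingRates:
    """All gating rate constants at the given membrane potentials and
    total dendritic Ca2+ concentration.

    Parameters
    ----------
    phi_msn, phi_mdn : float
        Somatic and dendritic membrane potentials (V).
    Ca_dn : float
        Total dendritic intracellular Ca2+ concentration (mM); only the
        free fraction ``gamma_Ca * Ca_dn`` drives the Ca2+-activated
        K+ conductance and the afterhyperpolarization activation.
    """
    # soma: transient Na+ (m, h) and delayed rectifier K+ (n)
    phi_1 = phi_msn + 0.0469
    alpha_m = 1280.0 * _exprel_inv(-phi_1 / 0.004)
    phi_2 = phi_msn + 0.0199
    beta_m = 1400.0 * _exprel_inv(phi_2 / 0.005)
    m_inf = alpha_m / (alpha_m + beta_m)

    alpha_h = 128.0 * np.exp((-0.043 - phi_msn) / 0.018)
    phi_3 = phi_msn + 0.02
    beta_h = 4000.0 / (1.0 + np.exp(-phi_3 / 0.005))

    phi_4 = phi_msn + 0.0249
    alpha_n = 80.0 * _exprel_inv(-phi_4 / 0.005)
    phi_5 = phi_msn + 0.04
    beta_n = 250.0 * np.exp(-phi_5 / 0.04)

    # dendrite: Ca2+ channel (s, z), K-C (c, chi), K-AHP (q)
    alpha_s = 1600.0 / (1.0 + np.exp(-72.0 * (phi_mdn - 0.005)))
    phi_6 = phi_mdn + 0.0089
    beta_s = 100.0 * _exprel_inv(phi_6 / 0.005)

    phi_7 = phi_mdn + 0.03
    z_inf = 1.0 / (1.0 + np.exp(phi_7 / 0.001))

    phi_9 = phi_mdn + 0.0535
    if phi_mdn <= -0.01:
        phi_8 = phi_mdn + 0.05
        alpha_c = 52.7 * np.exp(phi_8 / 0.011 - phi_9 / 0.027)
        # the two branch expressions agree analytically at the boundary;
        # guard the O(eps) rounding mismatch there
        beta_c = max(2000.0 * np.exp(-phi_9 / 0.027) - alpha_c, 0.0)
    else:
        alpha_c = 2000.0 * np.exp(-phi_9 / 0.027)
        beta_c = 0.0

    free_Ca = gamma_Ca * Ca_dn
    # clamped: below the activation offset both the K-C coupling factor
    # and the AHP activation rate are zero, keeping rates nonnegative and
    # gates within [0, 1]
    chi = min(max((free_Ca - 99.8e-6) / 2.5e-4, 0.0), 1.0)
    alpha_q = min(max(2e4 * (free_Ca - 99.8e-6), 0.0), 10.0)
    beta_q = 1.0

    return GatingRates(
        alpha_m=float(alpha_m),
        beta_m=float(beta_m),
        m_inf=float(m_inf),
        alpha_h=float(alpha_h),
        beta_h=float(beta_h),
        alpha_n=float(alpha_n),
        beta_n=float(beta_n),
        alpha_s=float(alpha_s),
        beta_s=float(beta_s),
        alpha_c=float(alpha_c),
        beta_c=float(beta_c),
        alpha_q=float(alpha_q),
        beta_q=beta_q,
        z_inf=float(z_inf),
        tau_z=1.0,
        chi=float(chi),
    )


def gating_derivatives(gating: np.ndarray, rates: GatingRates) -> np.ndarray:
    """Time derivatives of (h, n, s, c, q, z).

    dx/dt = alpha (1 - x) - beta x for the first five; z relaxes to its
    voltage-dependent steady state with tau_z = 1 s.
    """
    h, n, s, c, q, z = gating
    return np.array(
        [
            rates.alpha_h * (1.0 - h) - rates.beta_h * h,
            rates.alpha_n * (1.0 - n) - rates.beta_n * n,
            rates.alpha_s * (1.0 - s) - rates.beta_s * s,
            rates.alpha_c * (1.0 - c) - rates.beta_c * c,
            rates.alpha_q * (1.0 - q) - rates.beta_q * q,
            (rates.z_inf - z) / rates.tau_z,
        ]
    )


def leak_flux(g_leak: float, phi_m: float, E_k: float, z_k: float, F: float = 9.648e4) -> float:
    """Passive flux density g (phi_m - E)/(F z), mol/(m^2 s), efflux
    positive for cations."""
    return g_leak * (phi_m - E_k) / (F * z_k)


def active_fluxes(
    phi_msn: float,
    phi_mdn: float,
    gating: np.ndarray,
    rates: GatingRates,
    E_Na_sn: float,
    E_K_sn: float,
    E_Ca_dn: float,
    E_K_dn: float,
    mem: MembraneParams,
    F: float = 9.648e4,
) -> dict[str, float]:
    """Per-channel active flux densities (mol/(m^2 s)).

    Soma: transient Na+ (m_inf^2 h) and delayed rectifier K+ (n).
    Dendrite: Ca2+ (s^2 z), afterhyperpolarization K+ (q), and
    Ca-activated K+ (c * chi).
    """
    h, n, s, c, q, z = gating
    j_Na = mem.g_Na * rates.m_inf**2 * h * (phi_msn - E_Na_sn) / F
    j_DR = mem.g_DR * n * (phi_msn - E_K_sn) / F
    j_Ca = mem.g_Ca * s**2 * z * (phi_mdn - E_Ca_dn) / (2.0 * F)
    j_AHP = mem.g_AHP * q * (phi_mdn - E_K_dn) / F
    j_C = mem.g_C * c * rates.chi * (phi_mdn - E_K_dn) / F
    return {"Na": j_Na, "DR": j_DR, "Ca": j_Ca, "AHP": j_AHP, "C": j_C}


def pump_flux_neuron(Na_n: float, K_e: float, rho_n: float) -> float:
    """3Na+/2K+ pump flux density (mol/(m^2 s)), sigmoidal in the
    intraneuronal Na+ and extracellular K+ concentrations (mM).

    Enters the per-ion totals as +3j on Na+ and -2j on K+ (one net
    elementary charge extruded per cycle).
    """
    return rho_n / (1.0 + np.exp((25.0 - Na_n) / 3.0)) / (1.0 + np.exp(3.5 - K_e))


def cotransporter_fluxes(
    Na_n: float,
    K_n: float,
    Cl_n: float,
    Na_e: float,
    K_e: float,
    Cl_e: float,
    U_kcc2: float,
    U_nkcc1: float,
) -> tuple[float, float]:
    """Electroneutral cotransporter flux densities (j_kcc2, j_nkcc1).

    KCC2 moves 1 K+ and 1 Cl- outward per unit flux; NKCC1 moves
    1 Na+, 1 K+, and 2 Cl- (its flux is gated by a sigmoid in the
    extracellular K+ concentration with midpoint 16 mM).
    """
    if min(Na_n, K_n, Cl_n, Na_e, K_e, Cl_e) <= 0:
        raise ValueError("cotransporter fluxes require positive concentrations")
    log_kcl = np.log(K_n * Cl_n / (K_e * Cl_e))
    log_nacl = np.log(Na_n * Cl_n / (Na_e * Cl_e))
    j_kcc2 = U_kcc2 * log_kcl
    f_K = 1.0 / (1.0 + np.exp(16.0 - K_e))
    j_nkcc1 = U_nkcc1 * f_K * (log_kcl + log_nacl)
    return float(j_kcc2), float(j_nkcc1)


def ca_decay_flux(Ca_n: float, V_n: float, mem: MembraneParams, A_m: float) -> float:
    """Ca2+ decay flux density via the 2Na+/Ca2+ exchanger (mol/(m^2 s)).

    Proportional to the deviation of the total intracellular Ca2+
    concentration from its basal value, scaled by the current
    volume-to-membrane-area ratio; enters totals as +1 on Ca2+ and -2 on
    Na+ (electroneutral exchange).
    """
    return mem.U_Ca_dec * (Ca_n - mem.Ca_n_basal) * V_n / A_m


@dataclass(frozen=True)
class NeuronalFluxes:
    """Per-compartment, per-ion neuronal membrane flux densities
    (mol/(m^2 s)), outward positive.  Rows: Na, K, Cl, Ca; columns:
    soma, dendrite."""

    soma: np.ndarray  # (4,)
    dendrite: np.ndarray  # (4,)


def total_neuronal_fluxes(
    conc: np.ndarray,
    V: np.ndarray,
    gating: np.ndarray,
    phi_msn: float,
    phi_mdn: float,
    E_soma: np.ndarray,
    E_dend: np.ndarray,
    params: ParameterSet,
    rates: GatingRates | None = None,
) -> NeuronalFluxes:
    """Sum all neuronal membrane mechanisms into per-ion totals.

    Parameters
    ----------
    conc : ndarray (4, 6)
        All compartment concentrations (mM).
    V : ndarray (6,)
        Compartment volumes (m^3).
    gating : ndarray (6,)
        (h, n, s, c, q, z).
    E_soma, E_dend : ndarray (4,)
        Reversal potentials (V) for Na, K, Cl, Ca at the soma and
        dendrite membranes.
    """
    mem = params.membrane
    F = params.constants.F
    gamma_Ca = params.ions[3].gamma
    if rates is None:
        rates = gating_rates(phi_msn, phi_mdn, conc[3, 3], gamma_Ca)

    act = active_fluxes(
        phi_msn, phi_mdn, gating, rates, E_soma[0], E_soma[1], E_dend[3], E_dend[1], mem, F
    )

    out = []
    for comp_i, comp_e, phi_m, E in ((0, 1, phi_msn, E_soma), (3, 4, phi_mdn, E_dend)):
        Na_n, K_n, Cl_n, Ca_n = conc[:, comp_i]
        Na_e, K_e, Cl_e = conc[0, comp_e], conc[1, comp_e], conc[2, comp_e]
        j_leak_Na = leak_flux(mem.g_Na_leak_n, phi_m, E[0], 1.0, F)
        j_leak_K = leak_flux(mem.g_K_leak_n, phi_m, E[1], 1.0, F)
        j_leak_Cl = leak_flux(mem.g_Cl_leak_n, phi_m, E[2], -1.0, F)
        j_pump = pump_flux_neuron(Na_n, K_e, mem.rho_n)
        j_kcc2, j_nkcc1 = cotransporter_fluxes(
            Na_n, K_n, Cl_n, Na_e, K_e, Cl_e, mem.U_kcc2, mem.U_nkcc1
        )
        j_cadec = ca_decay_flux(Ca_n, V[comp_i], mem, params.geometry.A_m)
        j_Na = j_leak_Na + 3.0 * j_pump + j_nkcc1 - 2.0 * j_cadec
        j_K = j_leak_K - 2.0 * j_pump + j_nkcc1 + j_kcc2
        j_Cl = j_leak_Cl + 2.0 * j_nkcc1 + j_kcc2
        j_Ca = j_cadec
        out.append(np.array([j_Na, j_K, j_Cl, j_Ca]))

    soma, dend = out
    soma[0] += act["Na"]
    soma[1] += act["DR"]
    dend[1] += act["AHP"] + act["C"]
    dend[3] += act["Ca"]
    return NeuronalFluxes(soma=soma, dendrite=dend)
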