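"""Glial (astrocytic) membrane mechanisms.

The glial domain represents the astrocytic syncytium available to the
tissue unit.  Each glial compartment carries Na+ and Cl- leaks, an
inward-rectifying K+ (Kir) channel whose conductance grows with
extracellular K+ and with hyperpolarization, and a 3Na+/2K+ pump with
Hill-type Na+ dependence.  The same mechanism set acts in both layers;
the glial domain carries no Ca2+.

The Kir baseline constants (basal extracellular K+ and the corresponding
K+ reversal potential) are fixed at run start from the chosen initial
condition.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .parameters import MembraneParams, ParameterSet

__all__ = [
    "GlialFluxes",
    "kir_flux",
    "glial_pump_flux",
    "total_glial_fluxes",
    "resolve_kir_baseline",
]


def resolve_kir_baseline(params: ParameterSet, state) -> ParameterSet:
    """Fix the Kir baseline constants from an initial state.

    ``K_e_basal`` becomes the soma-layer ECS K+ concentration and
    ``E_K_basal`` its glial Nernst potential.  No-op if ``E_K_basal`` is
    already set (not NaN), so explicit overrides win.
    """
    if not math.isnan(params.membrane.E_K_basal):
        return params
    kb = getattr(state, "kir_baseline", None)
    if kb is not None:
        K_e, E_b = kb
    else:
        c = state.concentrations
        K_e, K_g = float(c[1, 1]), float(c[1, 2])
        if K_e <= 0 or K_g <= 0:
            raise ValueError("Kir baseline requires positive K+ concentrations")
        E_b = params.constants.psifac * math.log(K_e / K_g)
    mem = dataclasses.replace(params.membrane, K_e_basal=K_e, E_K_basal=E_b)
    return params.replace(membrane=mem)


def kir_conductance_factor(phi_mg: float, E_K_g: float, K_e: float, mem: MembraneParams) -> float:
    """Dimensionless Kir gating factor.

    Product of the extracellular-K+ ratio against baseline and two
    sigmoidal factors (evaluated in mV) that shut the channel on
    depolarization relative to the K+ reversal potential.
    """
    dphi_mV = (phi_mg - E_K_g) * 1000.0
    f = (
        (K_e / mem.K_e_basal)
        * (1.0 + np.exp(18.4 / 42.4)) / (1.0 + np.exp((dphi_mV + 18.5) / 42.5))
        * (1.0 + np.exp(-(118.6 + mem.E_K_basal * 1000.0) / 44.1))
        / (1.0 + np.exp(-(118.6 + phi_mg * 1000.0) / 44.1))
    )
    return float(f)


def kir_flux(
    phi_mg: float, E_K_g: float, K_e: float, mem: MembraneParams, F: float = 9.648e4
) -> float:
    """Inward-rectifier K+ flux density (mol/(m^2 s)), outward positive."""
    if K_e <= 0:
        raise ValueError("Kir flux requires a positive extracellular K+ concentration")
    f = kir_conductance_factor(phi_mg, E_K_g, K_e, mem)
    return mem.g_K_IR * f * (phi_mg - E_K_g) / F


def glial_pump_flux(Na_g: float, K_e: float, mem: MembraneParams) -> float:
    """Glial 3Na+/2K+ pump flux density (mol/(m^2 s)).

    Hill-type (exponent 1.5) in intraglial Na+ and Michaelis-type in
    extracellular K+; nonnegative for nonnegative concentrations.
    Enters totals as +3j on Na+ and -2j on K+.
    """
    na15 = Na_g**1.5
    return (
        mem.rho_g
        * na15 / (na15 + mem.Na_g_threshold**1.5)
        * K_e / (K_e + mem.K_e_threshold)
    )


@dataclass(frozen=True)
class GlialFluxes:
    """Per-ion glial membrane flux densities (mol/(m^2 s)), outward
    positive.  Rows: Na, K, Cl, Ca (Ca identically zero)."""

    soma: np.ndarray
    dendrite: np.ndarray


def total_glial_fluxes(
    conc: np.ndarray,
    phi_msg: float,
    phi_mdg: float,
    E_soma_g: np.ndarray,
    E_dend_g: np.ndarray,
    params: ParameterSet,
) -> GlialFluxes:
    """Sum the glial membrane mechanisms into per-ion totals.

    Parameters
    ----------
    conc : ndarray (4, 6)
        All compartment concentrations (mM).
    E_soma_g, E_dend_g : ndarray (4,)
        Glial reversal potentials (V) for Na, K, Cl (plain Nernst,
        gamma = 1) at each layer; the Ca entry is unused.
    """
    mem = params.membrane
    F = params.constants.F
    out = []
    for comp_g, comp_e, phi_m, E in ((2, 1, phi_msg, E_soma_g), (5, 4, phi_mdg, E_dend_g)):
        Na_g = conc[0, comp_g]
        K_e = conc[1, comp_e]
        j_leak_Na = mem.g_Na_leak_g * (phi_m - E[0]) / F
        j_leak_Cl = mem.g_Cl_leak_g * (phi_m - E[2]) / (-F)
        j_kir = kir_flux(phi_m, E[1], K_e, mem, F)
        j_pump = glial_pump_flux(Na_g, K_e, mem)
        out.append(
            np.array([j_leak_Na + 3.0 * j_pump, j_kir - 2.0 * j_pump, j_leak_Cl, 0.0])
        )
    return GlialFluxes(soma=out[0], dendrite=out[1])
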