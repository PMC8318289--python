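"""Axial electrodiffusive fluxes, current densities, conductivities, and
the per-step algebraic solution of all six compartment potentials.

The unit consists of two layers (soma, dendrite) times three domains
(neuron, ECS, glia).  Axial transport within each domain follows the
Nernst-Planck flux density: a Fickian term driven by the concentration
gradient and a field-driven term proportional to the mean concentration
and the potential gradient.  The six compartment potentials are never
state variables: they are recovered algebraically from the ion amounts at
every right-hand-side evaluation via the capacitor relations of the four
cellular compartments, the grounded dendrite-layer ECS, and closure of
the axial current loop (the charge anti-symmetry constraint).

Sign conventions, stated once: the axial positive direction is
soma -> dendrite; transmembrane positive direction is outward (efflux
positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import Geometry, IonSpec, ParameterSet, PhysicalConstants
from .state import SystemState

__all__ = [
    "PotentialSet",
    "CurrentDensities",
    "nernst_potential",
    "axial_flux",
    "conductivity",
    "diffusion_current_density",
    "solve_potentials",
    "current_densities",
]

_DOMAINS = ("neuron", "ecs", "glia")


def _gamma_lambda(domain: str, params: ParameterSet) -> tuple[np.ndarray, float]:
    """Mobile fraction vector and tortuosity for a domain."""
    if domain == "neuron":
        return params.gamma_n, params.geometry.lambda_i
    if domain == "glia":
        return np.ones(4), params.geometry.lambda_i
    if domain == "ecs":
        return np.ones(4), params.geometry.lambda_e
    raise ValueError(f"domain must be one of {_DOMAINS}, got {domain!r}")


@dataclass(frozen=True)
class PotentialSet:
    """Six compartment potentials plus the four membrane potentials (V).

    ``phi`` is ordered as ``COMPARTMENTS``; the dendrite-layer ECS is the
    reference (phi_de = 0).
    """

    phi: np.ndarray

    @property
    def phi_sn(self) -> float:
        return float(self.phi[0])

    @property
    def phi_se(self) -> float:
        return float(self.phi[1])

    @property
    def phi_sg(self) -> float:
        return float(self.phi[2])

    @property
    def phi_dn(self) -> float:
        return float(self.phi[3])

    @property
    def phi_de(self) -> float:
        return float(self.phi[4])

    @property
    def phi_dg(self) -> float:
        return float(self.phi[5])

    @property
    def phi_msn(self) -> float:
        return float(self.phi[0] - self.phi[1])

    @property
    def phi_mdn(self) -> float:
        return float(self.phi[3])

    @property
    def phi_msg(self) -> float:
        return float(self.phi[2] - self.phi[1])

    @property
    def phi_mdg(self) -> float:
        return float(self.phi[5])

    @property
    def membrane(self) -> np.ndarray:
        """(phi_msn, phi_mdn, phi_msg, phi_mdg) as an array."""
        return np.array([self.phi_msn, self.phi_mdn, self.phi_msg, self.phi_mdg])


@dataclass(frozen=True)
class CurrentDensities:
    """Axial current densities (A/m^2) and conductivities (S/m) per domain.

    ``i = i_diff + i_field`` holds term by term for each domain.
    """

    i_in: float
    i_e: float
    i_ig: float
    i_diff_in: float
    i_diff_e: float
    i_diff_ig: float
    sigma_n: float
    sigma_e: float
    sigma_g: float

    @property
    def i_field_in(self) -> float:
        return self.i_in - self.i_diff_in

    @property
    def i_field_e(self) -> float:
        return self.i_e - self.i_diff_e

    @property
    def i_field_ig(self) -> float:
        return self.i_ig - self.i_diff_ig

    def loop_residual(self, geometry: Geometry) -> float:
        """Axial current-loop closure residual A_i(i_in + i_ig) + A_e i_e,
        in A; zero (to round-off) for any solved potential set."""
        return geometry.A_i * (self.i_in + self.i_ig) + geometry.A_e * self.i_e


def nernst_potential(
    ion: IonSpec,
    conc_out: float,
    conc_in: float,
    constants: PhysicalConstants | None = None,
    gamma: float | None = None,
) -> float:
    """Reversal potential E = RT/(zF) ln(c_out / (gamma c_in)) in V.

    ``gamma`` is the intracellular mobile (free) fraction; it defaults to
    the ion's intraneuronal value and must be passed as 1.0 for glial
    membranes, where all ions are free.
    """
    if constants is None:
        constants = PhysicalConstants()
    if gamma is None:
        gamma = ion.gamma
    eff_in = gamma * conc_in
    if conc_out <= 0 or eff_in <= 0:
        raise ValueError(
            f"Nernst potential of {ion.name} undefined for concentrations "
            f"out={conc_out}, gamma*in={eff_in}"
        )
    return constants.psifac / ion.z * np.log(conc_out / eff_in)


def axial_flux(
    ion: IonSpec,
    domain: str,
    conc_s: float,
    conc_d: float,
    phi_s: float,
    phi_d: float,
    geometry: Geometry | None = None,
    constants: PhysicalConstants | None = None,
) -> float:
    """Axial (soma-layer -> dendrite-layer) flux density of one ion,
    mol/(m^2 s).

    The flux is the sum of a Fickian term driven by the concentration
    difference and a field-driven term proportional to the mean
    concentration; the intraneuronal mobile fraction gamma enters both
    terms in the neuron domain only.
    """
    if geometry is None:
        geometry = Geometry()
    if constants is None:
        constants = PhysicalConstants()
    gamma = ion.gamma if domain == "neuron" else 1.0
    if domain == "ecs":
        lam = geometry.lambda_e
    elif domain in ("neuron", "glia"):
        lam = geometry.lambda_i
    else:
        raise ValueError(f"domain must be one of {_DOMAINS}, got {domain!r}")
    cbar = gamma * (conc_d + conc_s) / 2.0
    diff = -ion.D / lam**2 * gamma * (conc_d - conc_s) / geometry.dx
    field = (
        -ion.D * ion.z * constants.F / (lam**2 * constants.RT)
        * cbar * (phi_d - phi_s) / geometry.dx
    )
    return diff + field


def conductivity(
    domain: str,
    conc_s: np.ndarray,
    conc_d: np.ndarray,
    params: ParameterSet,
) -> float:
    """Domain conductivity sigma = F^2/(RT lambda^2) sum_k D_k z_k^2 cbar_k
    (S/m), with cbar the gamma-weighted mean of the two layer
    concentrations (gamma-weighting in the neuron domain only)."""
    gamma, lam = _gamma_lambda(domain, params)
    c = params.constants
    cbar = gamma * (np.asarray(conc_d) + np.asarray(conc_s)) / 2.0
    return float(c.F**2 / (c.RT * lam**2) * np.sum(params.D * params.z**2 * cbar))


def diffusion_current_density(
    domain: str,
    conc_s: np.ndarray,
    conc_d: np.ndarray,
    params: ParameterSet,
) -> float:
    """Diffusive part of the axial current density,
    i_diff = -F/(lambda^2 dx) sum_k D_k z_k gamma_k (c_d - c_s), in A/m^2."""
    gamma, lam = _gamma_lambda(domain, params)
    c = params.constants
    g = params.geometry
    grad = gamma * (np.asarray(conc_d) - np.asarray(conc_s))
    return float(-c.F / (lam**2 * g.dx) * np.sum(params.D * params.z * grad))


def solve_potentials(state: SystemState, params: ParameterSet) -> PotentialSet:
    """Solve the six compartment potentials algebraically from the state.

    The dendrite-layer ECS is grounded; the four cellular potentials
    follow from the capacitor relation Q/(c_m A_m) with Q the net
    compartment charge including the static residual; and the soma-layer
    ECS potential closes the axial current loop so that
    A_i(i_in + i_ig) = -A_e i_e holds exactly.
    """
    if np.any(state.V <= 0):
        raise ValueError("volumes must be positive to solve potentials")
    c = state.concentrations
    geo = params.geometry
    con = params.constants
    qfac = params.membrane.c_m * geo.A_m  # capacitance (F)
    Q = con.F * state.charge_amounts()  # net charge per compartment (C)

    phi_dn = Q[3] / qfac
    phi_dg = Q[5] / qfac
    phi_msn_q = Q[0] / qfac
    phi_msg_q = Q[2] / qfac

    sig_n = conductivity("neuron", c[:, 0], c[:, 3], params)
    sig_e = conductivity("ecs", c[:, 1], c[:, 4], params)
    sig_g = conductivity("glia", c[:, 2], c[:, 5], params)
    i_diff_in = diffusion_current_density("neuron", c[:, 0], c[:, 3], params)
    i_diff_e = diffusion_current_density("ecs", c[:, 1], c[:, 4], params)
    i_diff_ig = diffusion_current_density("glia", c[:, 2], c[:, 5], params)

    denom = geo.A_e * sig_e + geo.A_i * sig_n + geo.A_i * sig_g
    if denom <= 0:
        raise ValueError("degenerate state: total axial conductance is zero")
    num = (
        -geo.dx * geo.A_i * i_diff_in
        + geo.A_i * sig_n * (phi_dn - phi_msn_q)
        - geo.dx * geo.A_i * i_diff_ig
        + geo.A_i * sig_g * (phi_dg - phi_msg_q)
        - geo.dx * geo.A_e * i_diff_e
    )
    phi_se = num / denom
    phi = np.array(
        [phi_msn_q + phi_se, phi_se, phi_msg_q + phi_se, phi_dn, 0.0, phi_dg]
    )
    return PotentialSet(phi)


def current_densities(
    state: SystemState, params: ParameterSet, potentials: PotentialSet | None = None
) -> CurrentDensities:
    """Total and diffusive axial current densities and conductivities for
    the three domains, evaluated at the solved potentials."""
    if potentials is None:
        potentials = solve_potentials(state, params)
    c = state.concentrations
    geo = params.geometry
    phi = potentials.phi

    out = {}
    for name, (s_idx, d_idx), domain in (
        ("in", (0, 3), "neuron"),
        ("e", (1, 4), "ecs"),
        ("ig", (2, 5), "glia"),
    ):
        sig = conductivity(domain, c[:, s_idx], c[:, d_idx], params)
        i_diff = diffusion_current_density(domain, c[:, s_idx], c[:, d_idx], params)
        i_field = -sig * (phi[d_idx] - phi[s_idx]) / geo.dx
        out[name] = (i_diff + i_field, i_diff, sig)

    return CurrentDensities(
        i_in=out["in"][0],
        i_e=out["e"][0],
        i_ig=out["ig"][0],
        i_diff_in=out["in"][1],
        i_diff_e=out["e"][1],
        i_diff_ig=out["ig"][1],
        sigma_n=out["in"][2],
        sigma_e=out["e"][2],
        sigma_g=out["ig"][2],
    )
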