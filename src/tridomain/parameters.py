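"""Model constants and parameter bundles.

All quantities are SI (m, s, mol, V, A, Pa) except ion concentrations,
which are stored as mol/m^3 and therefore numerically equal to mM.  Pump,
cotransporter, and gating expressions take mM-valued arguments, so no
conversion is needed anywhere inside the model; conversion happens only at
I/O boundaries.

The default values describe a "unit" of layered brain tissue: one
two-compartment neuron (soma layer + dendrite layer), the extracellular
space (ECS) it has at its disposal, and the astrocytic (glial) buffering
surrounding it, with initial neuron/ECS/glia volume fractions 0.4/0.2/0.4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "ION_NAMES",
    "ConfigurationError",
    "PhysicalConstants",
    "Geometry",
    "IonSpec",
    "MembraneParams",
    "ParameterSet",
    "build_default_parameters",
]

#: Compartment ordering used throughout: soma-layer neuron / ECS / glia,
#: then dendrite-layer neuron / ECS / glia.
COMPARTMENTS = ("sn", "se", "sg", "dn", "de", "dg")

#: Ion ordering used throughout.
ION_NAMES = ("Na", "K", "Cl", "Ca")

SN, SE, SG, DN, DE, DG = range(6)
NA, K, CL, CA = range(4)


class ConfigurationError(ValueError):
    """Raised for invalid parameter overrides or unphysical configuration."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature and physical constants.

    Attributes
    ----------
    F : float
        Faraday constant (C/mol).
    R : float
        Gas constant (J/(mol K)).
    T : float
        Absolute temperature (K).
    """

    F: float = 9.648e4
    R: float = 8.314
    T: float = 309.14

    def __post_init__(self) -> None:
        for name in ("F", "R", "T"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"physical constant {name} must be > 0")

    @property
    def RT(self) -> float:
        return self.R * self.T

    @property
    def psifac(self) -> float:
        """Thermal voltage RT/F (V)."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class Geometry:
    """Geometry of the six-compartment unit.

    Attributes
    ----------
    dx : float
        Distance between the soma and dendrite layers (m).
    alpha : float
        Intracellular coupling strength; A_i = alpha * A_m.
    A_m : float
        Membrane area of each cellular compartment (m^2).
    A_e : float
        Extracellular cross-section area for axial fluxes (m^2).
    lambda_i, lambda_e : float
        Intracellular and extracellular tortuosities.
    V0 : ndarray, shape (6,)
        Initial compartment volumes (m^3), ordered as COMPARTMENTS.
    """

    dx: float = 667e-6
    alpha: float = 2.0
    A_m: float = 616e-12
    A_e: float = 308e-13
    lambda_i: float = 3.2
    lambda_e: float = 1.6
    V0: np.ndarray = field(
        default_factory=lambda: np.array(
            [1437e-18, 718.5e-18, 1437e-18, 1437e-18, 718.5e-18, 1437e-18]
        )
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "V0", np.asarray(self.V0, dtype=float))
        if self.V0.shape != (6,):
            raise ConfigurationError("V0 must have one volume per compartment (6,)")
        for name in ("dx", "alpha", "A_m", "A_e", "lambda_i", "lambda_e"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"geometry field {name} must be > 0")
        if np.any(self.V0 <= 0):
            raise ConfigurationError("initial volumes must be > 0")

    @property
    def A_i(self) -> float:
        """Intracellular cross-section area, alpha * A_m (m^2)."""
        return self.alpha * self.A_m


@dataclass(frozen=True)
class IonSpec:
    """One ion species: valence, diffusion constant, and the intraneuronal
    mobile fraction gamma (buffering; gamma applies in the neuron only)."""

    name: str
    z: int
    D: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ION_NAMES:
            raise ConfigurationError(f"unknown ion species {self.name!r}")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigurationError(f"gamma for {self.name} must be in (0, 1]")
        if self.D < 0:
            raise ConfigurationError(f"diffusion constant for {self.name} must be >= 0")


DEFAULT_IONS = (
    IonSpec("Na", 1, 1.33e-9, 1.0),
    IonSpec("K", 1, 1.96e-9, 1.0),
    IonSpec("Cl", -1, 2.03e-9, 1.0),
    IonSpec("Ca", 2, 0.71e-9, 0.01),
)


@dataclass(frozen=True)
class MembraneParams:
    """Membrane capacitance, conductances, pump/cotransporter strengths,
    and water permeabilities.

    Conductances are S/m^2, pump/cotransporter strengths mol/(m^2 s),
    U_Ca_dec 1/s, water permeabilities m^3/(Pa s), concentrations mM.
    """

    c_m: float = 3e-2
    # neuronal leaks and active channels
    g_Na_leak_n: float = 0.246
    g_K_leak_n: float = 0.245
    g_Cl_leak_n: float = 1.0
    g_Na: float = 300.0
    g_DR: float = 150.0
    g_Ca: float = 118.0
    g_AHP: float = 8.0
    g_C: float = 150.0
    # neuronal pump, cotransporters, Ca handling
    rho_n: float = 1.87e-6
    U_kcc2: float = 1.49e-7
    U_nkcc1: float = 2.33e-7
    U_Ca_dec: float = 75.0
    Ca_n_basal: float = 0.01
    # glial membrane
    g_Na_leak_g: float = 1.0
    g_Cl_leak_g: float = 0.5
    g_K_IR: float = 16.96
    rho_g: float = 1.12e-6
    Na_g_threshold: float = 10.0
    K_e_threshold: float = 1.5
    # Kir baseline (set from the chosen initial condition at run start)
    K_e_basal: float = 3.5
    E_K_basal: float = float("nan")
    # osmotic water permeabilities
    G_n: float = 2e-23
    G_g: float = 5e-23

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if f_.name == "E_K_basal":
                continue
            if v < 0:
                raise ConfigurationError(f"membrane parameter {f_.name} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter bundle for the tri-domain model."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    geometry: Geometry = field(default_factory=Geometry)
    ions: tuple[IonSpec, ...] = DEFAULT_IONS
    membrane: MembraneParams = field(default_factory=MembraneParams)

    def __post_init__(self) -> None:
        names = tuple(ion.name for ion in self.ions)
        if names != ION_NAMES:
            raise ConfigurationError(
                f"ions must be exactly {ION_NAMES} in order, got {names}"
            )

    # -- convenience arrays over the fixed ion ordering (cached; treat as
    # read-only) ---------------------------------------------------------
    @cached_property
    def z(self) -> np.ndarray:
        """Charge numbers, shape (4,)."""
        return np.array([ion.z for ion in self.ions], dtype=float)

    @cached_property
    def D(self) -> np.ndarray:
        """Diffusion constants (m^2/s), shape (4,)."""
        return np.array([ion.D for ion in self.ions])

    @cached_property
    def gamma_n(self) -> np.ndarray:
        """Intraneuronal mobile fractions, shape (4,)."""
        return np.array([ion.gamma for ion in self.ions])

    def replace(self, **sections) -> "ParameterSet":
        """Return a copy with whole sections replaced."""
        return dataclasses.replace(self, **sections)


_SECTION_TYPES = {
    "constants": PhysicalConstants,
    "geometry": Geometry,
    "membrane": MembraneParams,
}


def build_default_parameters(overrides: dict | None = None) -> ParameterSet:
    """Build the default parameter bundle, optionally overriding fields.

    Parameters
    ----------
    overrides : dict, optional
        Nested mapping ``{section: {field: value}}`` with sections
        ``constants``, ``geometry``, ``membrane``, and ``ions``.  The
        ``ions`` section maps species name to a mapping with any of
        ``z``, ``D``, ``gamma``.  Unknown sections, fields, or species
        raise :class:`ConfigurationError`.

    Returns
    -------
    ParameterSet
    """
    params = ParameterSet()
    if not overrides:
        return params

    sections: dict = {}
    for section, values in overrides.items():
        if section == "ions":
            specs = list(DEFAULT_IONS)
            for name, fields_ in values.items():
                if name not in ION_NAMES:
                    raise ConfigurationError(f"unknown ion species {name!r}")
                idx = ION_NAMES.index(name)
                valid = {"z", "D", "gamma"}
                bad = set(fields_) - valid
                if bad:
                    raise ConfigurationError(
                        f"unknown ion field(s) {sorted(bad)} for species {name}"
                    )
                specs[idx] = dataclasses.replace(specs[idx], **fields_)
            sections["ions"] = tuple(specs)
        elif section in _SECTION_TYPES:
            cls = _SECTION_TYPES[section]
            valid = {f_.name for f_ in dataclasses.fields(cls)}
            bad = set(values) - valid
            if bad:
                raise ConfigurationError(
                    f"unknown field(s) {sorted(bad)} in section {section!r}"
                )
            sections[section] = cls(**values)
        else:
            raise ConfigurationError(f"unknown configuration section {section!r}")
    return ParameterSet(**sections)


def load_parameters(path) -> ParameterSet:
    """Load a ParameterSet from a YAML key-value configuration file.

    The file holds flat sections (``constants``, ``geometry``,
    ``membrane``, ``ions``); unspecified keys fall back to the defaults.
    """
    import yaml

    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ConfigurationError("configuration file must contain a mapping")
    return build_default_parameters(overrides)
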