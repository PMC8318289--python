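"""System state: ion amounts, volumes, gating variables, and the static
residual charges/osmolytes that pin the initial membrane potentials and
zero the initial osmotic gradients.

The ODE state vector is ordered ion amounts (ion-major, 4 x 6), then the
six gating variables (h, n, s, c, q, z), then the six volumes -- 36
entries total.  Residual charges and osmolytes are static bookkeeping
quantities computed once at initialization; they are never integrated and
never read from file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    COMPARTMENTS,
    ION_NAMES,
    ConfigurationError,
    ParameterSet,
    build_default_parameters,
)

__all__ = [
    "GATING_NAMES",
    "INITIAL_CONDITIONS",
    "SystemState",
    "build_initial_state",
    "compute_residual_charges",
    "compute_residual_osmolytes",
    "tune_leak_conductance",
    "tune_kcc2_strength",
    "derive_chloride_concentration",
]

#: Gating-variable ordering in the state vector.
GATING_NAMES = ("h", "n", "s", "c", "q", "z")

# Initial membrane potentials (V), concentrations (mM), and gating values
# for the two shipped initial conditions.  The "pre_calibrated" column is
# the state assembled from the two predecessor models; "post_calibrated"
# is the resting state the combined model settles into after a long
# calibration run and is the default for all simulations.  Values are the
# published rounded ones; sub-mV discrepancies against full-precision
# calibration output may follow.
INITIAL_CONDITIONS: dict[str, dict] = {
    "pre_calibrated": {
        "phi_mn0": -67.7e-3,
        "phi_mg0": -83.6e-3,
        "concentrations": {
            "Na": {"n": 16.9, "e": 144.622, "g": 15.189},
            "K": {"n": 139.5, "e": 3.082, "g": 99.959},
            "Cl": {"n": 6.7412, "e": 133.71, "g": 5.145},
            "Ca": {"n": 0.01, "e": 1.1, "g": 0.0},
        },
        "gating": {"h": 0.999, "n": 0.0003, "s": 0.007, "c": 0.005, "q": 0.011, "z": 1.0},
    },
    "post_calibrated": {
        "phi_mn0": -66.9e-3,
        "phi_mg0": -83.9e-3,
        "concentrations": {
            "Na": {"n": 18.7, "e": 142.3, "g": 14.5},
            "K": {"n": 138.1, "e": 3.5, "g": 101.2},
            "Cl": {"n": 7.1, "e": 131.9, "g": 5.7},
            "Ca": {"n": 0.01, "e": 1.1, "g": 0.0},
        },
        "gating": {"h": 0.9993, "n": 0.0003, "s": 0.0077, "c": 0.0057, "q": 0.0117, "z": 1.0},
    },
}


@dataclass
class SystemState:
    """Amounts of substance, volumes, gating variables, and static residuals.

    Attributes
    ----------
    N : ndarray, shape (4, 6)
        Amount of substance of each ion in each compartment (mol), ions
        ordered as ``ION_NAMES``, compartments as ``COMPARTMENTS``.
    V : ndarray, shape (6,)
        Compartment volumes (m^3).
    gating : ndarray, shape (6,)
        Gating variables (h, n, s, c, q, z), each in [0, 1].
    X : ndarray, shape (6,)
        Static residual charge amounts (mol); charge number -1, immobile.
    M : ndarray, shape (6,)
        Static residual osmolyte concentrations (mol/m^3); uncharged,
        immobile, used as the per-compartment osmotic baseline.
    """

    N: np.ndarray
    V: np.ndarray
    gating: np.ndarray
    X: np.ndarray = field(default_factory=lambda: np.zeros(6))
    M: np.ndarray = field(default_factory=lambda: np.zeros(6))
    #: optional (K_e_basal, E_K_basal) pinned for the glial Kir channel;
    #: None means "derive from this state's own composition"
    kir_baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.gating = np.asarray(self.gating, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.N.shape != (4, 6):
            raise ValueError("N must have shape (4, 6)")
        if self.V.shape != (6,) or self.gating.shape != (6,):
            raise ValueError("V and gating must have shape (6,)")

    @property
    def concentrations(self) -> np.ndarray:
        """Ion concentrations N/V (mol/m^3 == mM), shape (4, 6)."""
        return self.N / self.V

    def charge_amounts(self) -> np.ndarray:
        """Net charge per compartment in mol of elementary charge,
        sum_k z_k N_k - X (the residual species carries z = -1)."""
        z = np.array([1.0, 1.0, -1.0, 2.0])
        return z @ self.N - self.X

    def copy(self) -> "SystemState":
        return SystemState(
            self.N.copy(), self.V.copy(), self.gating.copy(), self.X.copy(),
            self.M.copy(), self.kir_baseline,
        )

    # -- flat ODE vector -------------------------------------------------
    def to_vector(self) -> np.ndarray:
        """Flatten to the 36-element ODE vector (N ion-major, gating, V)."""
        return np.concatenate([self.N.ravel(), self.gating, self.V])

    @classmethod
    def from_vector(cls, y: np.ndarray, template: "SystemState") -> "SystemState":
        """Rebuild a state from an ODE vector, carrying the template's
        static residuals."""
        y = np.asarray(y, dtype=float)
        return cls(
            y[:24].reshape(4, 6).copy(),
            y[30:36].copy(),
            y[24:30].copy(),
            template.X.copy(),
            template.M.copy(),
            template.kir_baseline,
        )


def compute_residual_charges(
    state: SystemState,
    params: ParameterSet,
    phi_mn0: float | tuple[float, float],
    phi_mg0: float | tuple[float, float],
) -> np.ndarray:
    """Static residual charge amounts X per compartment (mol).

    X is chosen so that, at t = 0, each cellular membrane separates a
    charge Q from -Q matching the target membrane potentials, and the
    whole system is exactly electroneutral.  The residual species has
    charge number -1 and zero mobility, representing impermeant anionic
    macromolecules; a negative amount would be unphysical and raises
    :class:`ConfigurationError`.

    Parameters
    ----------
    state : SystemState
        Initial state with ion amounts installed.
    phi_mn0, phi_mg0 : float or (float, float)
        Target initial neuronal and glial membrane potentials (V); a
        scalar applies identically in both layers, a pair gives
        (soma-layer, dendrite-layer) values.
    """
    z = params.z
    qfac = params.membrane.c_m * params.geometry.A_m / params.constants.F
    pn = (phi_mn0, phi_mn0) if np.isscalar(phi_mn0) else tuple(phi_mn0)
    pg = (phi_mg0, phi_mg0) if np.isscalar(phi_mg0) else tuple(phi_mg0)
    # target net charge (mol) per compartment: neuron phi_mn, glia
    # phi_mg, ECS the balancing -(phi_mn + phi_mg), per layer
    targets = np.array(
        [pn[0], -(pn[0] + pg[0]), pg[0], pn[1], -(pn[1] + pg[1]), pg[1]]
    )
    X = z @ state.N - targets * qfac
    if np.any(X < 0):
        bad = COMPARTMENTS[int(np.argmin(X))]
        raise ConfigurationError(
            f"negative residual charge amount in compartment {bad}: "
            "the requested initial state is unphysical"
        )
    return X


def compute_residual_osmolytes(state: SystemState, params: ParameterSet) -> np.ndarray:
    """Static residual osmolyte concentrations M per compartment (mol/m^3).

    M equals each compartment's initial total ionic osmolar concentration,
    so the baseline-corrected osmotic driving force (see
    :mod:`tridomain.volumes`) is exactly zero at t = 0.
    """
    return state.N.sum(axis=0) / state.V


def build_initial_state(
    condition: str = "post_calibrated",
    params: ParameterSet | None = None,
    concentrations: dict | None = None,
    install_residuals: bool = True,
) -> SystemState:
    """Assemble the initial six-compartment state.

    Parameters
    ----------
    condition : str
        ``"pre_calibrated"`` or ``"post_calibrated"`` (the default used
        for all standard simulations).
    params : ParameterSet, optional
        Parameter bundle; defaults are built if omitted.
    concentrations : dict, optional
        Higher-precision replacement for the shipped initial
        concentrations, same nested structure as
        ``INITIAL_CONDITIONS[condition]`` (any subset of keys).
    install_residuals : bool
        Compute the static residual charges and osmolytes (the normal
        case).  Disable only for low-level testing.

    Notes
    -----
    For the two published columns, soma- and dendrite-layer compartments
    of the same domain are initialized identically; the ``"calibrated"``
    state carries the (slightly layer-asymmetric) settled composition at
    full precision.  Glial compartments carry no calcium.
    """
    if params is None:
        params = build_default_parameters()
    if condition == "calibrated":
        table = _calibrated_table()
    elif condition in INITIAL_CONDITIONS:
        table = INITIAL_CONDITIONS[condition]
    else:
        raise ConfigurationError(
            "condition must be one of "
            f"{sorted(INITIAL_CONDITIONS) + ['calibrated']}, got {condition!r}"
        )
    conc_table = {k: dict(v) for k, v in table["concentrations"].items()}
    gating_table = dict(table["gating"])
    phi_mn0 = table["phi_mn0"]
    phi_mg0 = table["phi_mg0"]
    if concentrations:
        for key, val in concentrations.items():
            if key == "phi_mn0":
                phi_mn0 = val
            elif key == "phi_mg0":
                phi_mg0 = val
            elif key == "gating":
                gating_table.update(val)
            elif key in conc_table:
                conc_table[key].update(val)
            else:
                raise ConfigurationError(f"unknown initial-condition key {key!r}")

    V0 = params.geometry.V0.copy()
    N = np.empty((4, 6))
    for i, ion in enumerate(ION_NAMES):
        row = conc_table[ion]
        if "n" in row:  # per-domain values, identical layers
            per_comp = [row["n"], row["e"], row["g"]] * 2
        else:  # per-compartment values
            per_comp = [row[comp] for comp in COMPARTMENTS]
        N[i] = np.asarray(per_comp) * V0
    if np.any(N < 0):
        raise ConfigurationError("initial concentrations must be >= 0")

    gating = np.array([gating_table[g] for g in GATING_NAMES])
    state = SystemState(N, V0, gating)
    kb = table.get("kir_baseline")
    if kb is not None:
        state.kir_baseline = (float(kb["K_e_basal"]), float(kb["E_K_basal"]))
    else:
        c = state.concentrations
        state.kir_baseline = (
            float(c[1, 1]),
            params.constants.psifac * math.log(c[1, 1] / c[1, 2]),
        )
    if install_residuals:
        state.X = compute_residual_charges(state, params, phi_mn0, phi_mg0)
        state.M = compute_residual_osmolytes(state, params)
    return state


_calibrated_cache: dict | None = None


def _calibrated_table() -> dict:
    """Load the packaged full-precision calibrated resting state.

    Generated by ``scripts/calibrate.py``: the model's own settled
    resting state after a long unstimulated relaxation with water
    permeabilities zeroed, the same procedure that produced the published
    post-calibrated column.
    """
    global _calibrated_cache
    if _calibrated_cache is None:
        import importlib.resources
        import json

        path = importlib.resources.files("tridomain").joinpath(
            "data/calibrated_state.json"
        )
        with path.open() as fh:
            _calibrated_cache = json.load(fh)
        for key in ("phi_mn0", "phi_mg0"):
            _calibrated_cache[key] = tuple(_calibrated_cache[key])
    return _calibrated_cache


# ---------------------------------------------------------------------------
# Calibration-tuning formulas.  The shipped default conductances and
# cotransporter strength are the *outputs* of these procedures (their
# inputs are steady-state values of the predecessor neuron model and are
# not re-derived here); the formulas are provided as utilities for users
# retuning the model to other baseline compositions.
# ---------------------------------------------------------------------------


def tune_leak_conductance(g_old: float, E_old: float, E_new: float, phi_m: float) -> float:
    """Rescale a leak conductance so the leak current at rest is unchanged
    when the reversal potential moves from E_old to E_new.

    Solves g_new (phi_m - E_new) = g_old (phi_m - E_old) for g_new.
    """
    if phi_m == E_new:
        raise ZeroDivisionError("phi_m equals E_new: leak current cannot be matched")
    return g_old * (phi_m - E_old) / (phi_m - E_new)


def tune_kcc2_strength(
    U_old: float,
    K_n_old: float,
    Cl_n_old: float,
    K_e_old: float,
    Cl_e_old: float,
    K_n_new: float,
    Cl_n_new: float,
    K_e_new: float,
    Cl_e_new: float,
) -> float:
    """Rescale the K+/Cl- cotransporter strength so its resting flux is
    unchanged under new baseline concentrations.

    Solves U_new ln(r_new) = U_old ln(r_old) with
    r = [K+]_n [Cl-]_n / ([K+]_e [Cl-]_e).
    """
    r_old = (K_n_old * Cl_n_old) / (K_e_old * Cl_e_old)
    r_new = (K_n_new * Cl_n_new) / (K_e_new * Cl_e_new)
    if r_old <= 0 or r_new <= 0:
        raise ValueError("concentration ratios must be positive")
    if r_new == 1.0:
        raise ZeroDivisionError("new-state concentration ratio is 1: scaling undefined")
    return U_old * math.log(r_old) / math.log(r_new)


def derive_chloride_concentration(Cl_e_new: float, Cl_e_old: float, Cl_n_old: float) -> float:
    """Intracellular Cl- concentration preserving the Cl- reversal
    potential under a new extracellular Cl- concentration (mM).

    From equality of the Nernst potentials (equal gamma and T cancel):
    Cl_n_new = Cl_n_old * Cl_e_new / Cl_e_old.
    """
    if min(Cl_e_new, Cl_e_old, Cl_n_old) <= 0:
        raise ValueError("concentrations must be positive")
    return Cl_n_old * Cl_e_new / Cl_e_old
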