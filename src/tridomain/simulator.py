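"""Right-hand-side assembly and time integration.

The ODE state vector has 36 entries: the 24 ion amounts (ion-major over
the six compartments), the six gating variables (h, n, s, c, q, z), and
the six volumes.  Potentials are recovered algebraically inside every
right-hand-side evaluation; they are never integrated.

Integration uses an adaptive embedded Runge-Kutta 3(2) pair
(``scipy.integrate.solve_ivp``) with the maximal step size capped at
1e-4 s by default.  Because amounts and volumes are tiny in SI units, the
step-size cap -- not the error tolerances -- is the effective accuracy
control, which keeps the integrator marching at the cap through quiescent
stretches and resolves action potentials at a tenth of a millisecond.
Ion amounts and total volume are conserved exactly by construction of the
right-hand side, independent of step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import glia as _glia
from . import neuron as _neuron
from ._kernel import make_kernel
from .electrodiffusion import solve_potentials
from .parameters import COMPARTMENTS, ION_NAMES, ParameterSet, build_default_parameters
from .state import GATING_NAMES, SystemState, build_initial_state
from .stimulus import (
    InjectionProtocol,
    SynapseProtocol,
    injection_rates,
    synaptic_currents,
)
from .volumes import volume_derivatives

__all__ = [
    "SolverSettings",
    "Trajectory",
    "NonFiniteDerivativeError",
    "rhs",
    "run",
    "protocol_presets",
]


class NonFiniteDerivativeError(RuntimeError):
    """The right-hand side produced a nonfinite derivative."""


@dataclass(frozen=True)
class SolverSettings:
    """Integrator configuration.

    ``max_step`` is the effective accuracy control (default 1e-4 s; use
    1e-5 s for high-resolution physiological sweep runs).
    ``output_stride`` sets the sampling interval of the returned
    trajectory (1 ms default resolves action potentials; use ~100 ms for
    long pathological runs to bound memory).
    """

    method: str = "RK23"
    max_step: float = 1e-4
    rtol: float = 1e-6
    atol: float = 1e-9
    output_stride: float = 1e-3


@dataclass
class Trajectory:
    """Sampled simulation output.

    Attributes
    ----------
    t : ndarray (n,)
        Sample times (s), strictly increasing.
    N : ndarray (n, 4, 6)
        Ion amounts (mol).
    gating : ndarray (n, 6)
        Gating variables.
    V : ndarray (n, 6)
        Volumes (m^3).
    X, M : ndarray (6,)
        Static residual charge amounts (mol) and osmolyte concentrations
        (mol/m^3) of the run.
    """

    t: np.ndarray
    N: np.ndarray
    gating: np.ndarray
    V: np.ndarray
    X: np.ndarray
    M: np.ndarray
    params: ParameterSet
    success: bool = True
    message: str = ""
    kir_baseline: tuple[float, float] | None = None
    _phi_cache: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.t)

    def state_at(self, i: int) -> SystemState:
        """Reconstruct the full SystemState at sample index i."""
        return SystemState(
            self.N[i].copy(), self.V[i].copy(), self.gating[i].copy(),
            self.X.copy(), self.M.copy(), self.kir_baseline,
        )

    @property
    def concentrations(self) -> np.ndarray:
        """Ion concentrations (mM), shape (n, 4, 6)."""
        return self.N / self.V[:, None, :]

    def potentials(self) -> np.ndarray:
        """All six compartment potentials per sample (V), shape (n, 6).

        Vectorized evaluation of the same algebraic solve performed
        inside the right-hand side.
        """
        if self._phi_cache is not None and len(self._phi_cache) == len(self.t):
            return self._phi_cache
        p = self.params
        geo, con = p.geometry, p.constants
        z, D, gam = p.z, p.D, p.gamma_n
        c = self.concentrations  # (n, 4, 6)
        qfac = p.membrane.c_m * geo.A_m
        Q = con.F * (np.tensordot(self.N, z, axes=(1, 0)) - self.X)  # (n, 6)

        def sig_idiff(s, d, gamma, lam):
            cbar = gamma * (c[:, :, d] + c[:, :, s]) / 2.0
            sig = con.F**2 / (con.RT * lam**2) * (cbar @ (D * z**2))
            grad = gamma * (c[:, :, d] - c[:, :, s])
            idiff = -con.F / (lam**2 * geo.dx) * (grad @ (D * z))
            return sig, idiff

        sig_n, idiff_n = sig_idiff(0, 3, gam, geo.lambda_i)
        sig_e, idiff_e = sig_idiff(1, 4, 1.0, geo.lambda_e)
        sig_g, idiff_g = sig_idiff(2, 5, 1.0, geo.lambda_i)

        phi_dn = Q[:, 3] / qfac
        phi_dg = Q[:, 5] / qfac
        phi_msn_q = Q[:, 0] / qfac
        phi_msg_q = Q[:, 2] / qfac
        num = (
            -geo.dx * geo.A_i * idiff_n
            + geo.A_i * sig_n * (phi_dn - phi_msn_q)
            - geo.dx * geo.A_i * idiff_g
            + geo.A_i * sig_g * (phi_dg - phi_msg_q)
            - geo.dx * geo.A_e * idiff_e
        )
        phi_se = num / (geo.A_e * sig_e + geo.A_i * sig_n + geo.A_i * sig_g)
        phi = np.column_stack(
            [phi_msn_q + phi_se, phi_se, phi_msg_q + phi_se, phi_dn,
             np.zeros(len(phi_se)), phi_dg]
        )
        self._phi_cache = phi
        return phi

    def membrane_potentials(self) -> np.ndarray:
        """(phi_msn, phi_mdn, phi_msg, phi_mdg) per sample (V), (n, 4)."""
        phi = self.potentials()
        return np.column_stack(
            [phi[:, 0] - phi[:, 1], phi[:, 3], phi[:, 2] - phi[:, 1], phi[:, 5]]
        )

    # -- I/O -------------------------------------------------------------
    def to_dataframe(self):
        """Columnar view: time, concentrations, volumes, gating, and
        potentials (one row per sample)."""
        import pandas as pd

        data = {"t": self.t}
        conc = self.concentrations
        for i, ion in enumerate(ION_NAMES):
            for j, comp in enumerate(COMPARTMENTS):
                data[f"c_{ion}_{comp}"] = conc[:, i, j]
        for j, comp in enumerate(COMPARTMENTS):
            data[f"V_{comp}"] = self.V[:, j]
        for j, g in enumerate(GATING_NAMES):
            data[f"gate_{g}"] = self.gating[:, j]
        phi = self.potentials()
        for j, comp in enumerate(COMPARTMENTS):
            data[f"phi_{comp}"] = phi[:, j]
        mem = self.membrane_potentials()
        for j, name in enumerate(("phi_msn", "phi_mdn", "phi_msg", "phi_mdg")):
            data[name] = mem[:, j]
        return pd.DataFrame(data)

    _CSV_UNITS = (
        "# units: t s; c_* mM; V_* m^3; gate_* dimensionless; phi_* V\n"
    )

    def save_csv(self, path) -> None:
        """Write the trajectory as CSV with a units header line."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(self._CSV_UNITS)
            df.to_csv(fh, index=False)

    def save_hdf5(self, path) -> None:
        """Write the raw state arrays to an HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["units"] = "t: s, N: mol, V: m^3, X: mol, M: mol/m^3"
            for name in ("t", "N", "gating", "V", "X", "M"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load_hdf5(cls, path, params: ParameterSet | None = None) -> "Trajectory":
        import h5py

        if params is None:
            params = build_default_parameters()
        with h5py.File(path, "r") as f:
            return cls(
                t=f["t"][...], N=f["N"][...], gating=f["gating"][...],
                V=f["V"][...], X=f["X"][...], M=f["M"][...], params=params,
            )


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

_COMPONENT_NAMES = (
    [f"N_{ion}_{comp}" for ion in ION_NAMES for comp in COMPARTMENTS]
    + [f"gate_{g}" for g in GATING_NAMES]
    + [f"V_{comp}" for comp in COMPARTMENTS]
)


def _reversal_potentials(c: np.ndarray, params: ParameterSet):
    """Reversal potentials (V) at the four membranes.

    Returns (E_soma_n, E_dend_n, E_soma_g, E_dend_g), each shape (4,);
    the glial Ca entry is 0 (no glial Ca flux exists)."""
    psifac = params.constants.psifac
    z = params.z
    gam = params.gamma_n
    E_sn = psifac / z * np.log(c[:, 1] / (gam * c[:, 0]))
    E_dn = psifac / z * np.log(c[:, 4] / (gam * c[:, 3]))
    E_sg = np.zeros(4)
    E_dg = np.zeros(4)
    E_sg[:3] = psifac / z[:3] * np.log(c[:3, 1] / c[:3, 2])
    E_dg[:3] = psifac / z[:3] * np.log(c[:3, 4] / c[:3, 5])
    return E_sn, E_dn, E_sg, E_dg


def _axial_fluxes(c: np.ndarray, phi: np.ndarray, params: ParameterSet):
    """Per-ion axial flux densities (j_in, j_e, j_ig), each (4,)."""
    geo = params.geometry
    con = params.constants
    D, z, gam = params.D, params.z, params.gamma_n
    out = []
    for s, d, gamma, lam in (
        (0, 3, gam, geo.lambda_i),
        (1, 4, 1.0, geo.lambda_e),
        (2, 5, 1.0, geo.lambda_i),
    ):
        cbar = gamma * (c[:, d] + c[:, s]) / 2.0
        diff = -D / lam**2 * gamma * (c[:, d] - c[:, s]) / geo.dx
        fieldt = -D * z * con.F / (lam**2 * con.RT) * cbar * (phi[d] - phi[s]) / geo.dx
        out.append(diff + fieldt)
    return out


def rhs(
    t: float,
    state: SystemState,
    params: ParameterSet,
    protocol: InjectionProtocol | SynapseProtocol | None = None,
    spike_trains: dict[int, np.ndarray] | None = None,
    check_finite: bool = True,
) -> np.ndarray:
    """Full right-hand side, returned as the flat 36-element derivative.

    Order of evaluation: (1) solve the potentials algebraically, (2)
    membrane and axial fluxes, (3) ion-conservation ODEs with area
    weighting, (4) gating derivatives, (5) volume derivatives, (6)
    stimulus corrections last.
    """
    if math.isnan(params.membrane.E_K_basal):
        params = _glia.resolve_kir_baseline(params, state)
    p = params
    geo = p.geometry
    c = state.N / state.V
    pot = solve_potentials(state, p)
    phi = pot.phi
    phi_msn, phi_mdn, phi_msg, phi_mdg = pot.phi_msn, pot.phi_mdn, pot.phi_msg, pot.phi_mdg

    E_sn, E_dn, E_sg, E_dg = _reversal_potentials(c, p)
    rates = _neuron.gating_rates(phi_msn, phi_mdn, c[3, 3], p.ions[3].gamma)
    jn = _neuron.total_neuronal_fluxes(
        c, state.V, state.gating, phi_msn, phi_mdn, E_sn, E_dn, p, rates
    )
    jg = _glia.total_glial_fluxes(c, phi_msg, phi_mdg, E_sg, E_dg, p)
    j_in, j_e, j_ig = _axial_fluxes(c, phi, p)

    A_m, A_i, A_e = geo.A_m, geo.A_i, geo.A_e
    dN = np.empty((4, 6))
    dN[:, 0] = -jn.soma * A_m - j_in * A_i
    dN[:, 1] = +jn.soma * A_m - j_e * A_e + jg.soma * A_m
    dN[:, 2] = -jg.soma * A_m - j_ig * A_i
    dN[:, 3] = -jn.dendrite * A_m + j_in * A_i
    dN[:, 4] = +jn.dendrite * A_m + j_e * A_e + jg.dendrite * A_m
    dN[:, 5] = -jg.dendrite * A_m + j_ig * A_i

    dgating = _neuron.gating_derivatives(state.gating, rates)
    dV = volume_derivatives(state, p)

    if protocol is not None:
        if isinstance(protocol, InjectionProtocol):
            dN += injection_rates(protocol, t, p.constants.F)
        elif isinstance(protocol, SynapseProtocol):
            if spike_trains is None:
                spike_trains = protocol.spike_trains()
            F = p.constants.F
            phi_by = {0: phi_msn, 3: phi_mdn}
            E_by = {0: (E_sn[0], E_sn[1], E_sn[3]), 3: (E_dn[0], E_dn[1], E_dn[3])}
            for comp, spikes in spike_trains.items():
                I_Na, I_K, I_Ca = synaptic_currents(
                    t, spikes, phi_by[comp], *E_by[comp], protocol
                )
                for k, I, zk in ((0, I_Na, 1.0), (1, I_K, 1.0), (3, I_Ca, 2.0)):
                    r = I / (F * zk)
                    dN[k, comp] -= r
                    dN[k, comp + 1] += r
        else:
            raise TypeError(f"unknown protocol type {type(protocol).__name__}")

    dy = np.concatenate([dN.ravel(), dgating, dV])
    if check_finite and not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        raise NonFiniteDerivativeError(
            f"nonfinite derivative in component {_COMPONENT_NAMES[bad]} at t={t:.6f} s"
        )
    return dy


# ---------------------------------------------------------------------------
# Integration driver
# ---------------------------------------------------------------------------


def run(
    protocol: InjectionProtocol | SynapseProtocol | None = None,
    t_span: tuple[float, float] = (0.0, 10.0),
    settings: SolverSettings | None = None,
    params: ParameterSet | None = None,
    initial_state: SystemState | None = None,
    condition: str = "calibrated",
) -> Trajectory:
    """Integrate the model and return a sampled trajectory.

    Parameters
    ----------
    protocol : InjectionProtocol | SynapseProtocol | None
        Stimulus; ``None`` runs the unstimulated resting model.
    t_span : (float, float)
        Simulated time interval (s).
    settings : SolverSettings, optional
    params : ParameterSet, optional
    initial_state : SystemState, optional
        If omitted, built from ``condition`` with residual charges and
        osmolytes installed.
    condition : str
        Initial condition used when ``initial_state`` is omitted:
        ``"calibrated"`` (default; the package's full-precision settled
        resting state), or the published ``"post_calibrated"`` /
        ``"pre_calibrated"`` columns.

    Returns
    -------
    Trajectory
        ``success`` is False (with ``message`` set) if integration
        terminated early; the partial trajectory is still returned.
    """
    if settings is None:
        settings = SolverSettings()
    if params is None:
        params = build_default_parameters()
    if initial_state is None:
        initial_state = build_initial_state(condition, params)
    state0 = initial_state
    # pin the Kir baseline to the starting composition once, outside the
    # integration loop
    params = _glia.resolve_kir_baseline(params, state0)

    trains = None
    if isinstance(protocol, SynapseProtocol):
        trains = protocol.spike_trains()

    kernel = make_kernel(params, state0.X, state0.M)
    F = params.constants.F

    if protocol is None:

        def fun(t, y):
            return kernel(t, y)[0]

    elif isinstance(protocol, InjectionProtocol):
        k = ION_NAMES.index(protocol.species)
        z_k = {"Na": 1.0, "K": 1.0, "Cl": -1.0}[protocol.species]
        if protocol.target == "both":
            stim_entries = [
                (k * 6 + 0, k * 6 + 1, protocol.I_stim / 2.0 / (F * z_k)),
                (k * 6 + 3, k * 6 + 4, protocol.I_stim / 2.0 / (F * z_k)),
            ]
        elif protocol.target == "soma":
            stim_entries = [(k * 6 + 0, k * 6 + 1, protocol.I_stim / (F * z_k))]
        else:
            stim_entries = [(k * 6 + 3, k * 6 + 4, protocol.I_stim / (F * z_k))]
        t_on, t_off = protocol.t_on, protocol.t_off

        def fun(t, y):
            dy = kernel(t, y)[0]
            if t_on <= t < t_off:
                for idx_i, idx_e, rate in stim_entries:
                    dy[idx_i] += rate
                    dy[idx_e] -= rate
            return dy

    elif isinstance(protocol, SynapseProtocol):

        def fun(t, y):
            dy, aux = kernel(t, y)
            if aux is None:
                return dy
            phi_msn, phi_mdn, E_Na_s, E_K_s, E_Ca_s, E_Na_d, E_K_d, E_Ca_d = aux
            for comp, spikes in trains.items():
                if comp == 0:
                    phi_m, E = phi_msn, (E_Na_s, E_K_s, E_Ca_s)
                else:
                    phi_m, E = phi_mdn, (E_Na_d, E_K_d, E_Ca_d)
                I_Na, I_K, I_Ca = synaptic_currents(t, spikes, phi_m, *E, protocol)
                for k, I, zk in ((0, I_Na, 1.0), (1, I_K, 1.0), (3, I_Ca, 2.0)):
                    r = I / (F * zk)
                    dy[k * 6 + comp] -= r
                    dy[k * 6 + comp + 1] += r
            return dy

    else:
        raise TypeError(f"unknown protocol type {type(protocol).__name__}")

    t0, t_end = t_span
    n_out = int(math.floor((t_end - t0) / settings.output_stride + 0.5)) + 1
    t_eval = t0 + settings.output_stride * np.arange(n_out)
    t_eval = t_eval[t_eval <= t_end + 1e-12]

    sol = solve_ivp(
        fun,
        (t0, t_end),
        state0.to_vector(),
        method=settings.method,
        max_step=settings.max_step,
        rtol=settings.rtol,
        atol=settings.atol,
        t_eval=t_eval,
        dense_output=False,
    )

    y = sol.y.T  # (n, 36)
    return Trajectory(
        t=sol.t,
        N=y[:, :24].reshape(-1, 4, 6),
        gating=y[:, 24:30],
        V=y[:, 30:36],
        X=state0.X.copy(),
        M=state0.M.copy(),
        params=params,
        success=bool(sol.success),
        message=str(sol.message),
        kir_baseline=state0.kir_baseline,
    )


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    """A named experiment: stimulus protocol plus recommended end time
    and solver settings."""

    protocol: InjectionProtocol | SynapseProtocol | None
    t_end: float
    settings: SolverSettings = field(default_factory=SolverSettings)
    description: str = ""


def protocol_presets() -> dict[str, Preset]:
    """Named stimulus presets for the standard experiments.

    ``fig3``: 22 pA K+ somatic step, 1 Hz physiological firing (600 s
    stimulus, 1400 s total including recovery).
    ``fig4``: 150 pA K+ somatic step driving depolarization block (7 s
    stimulus, 600 s to terminal steady state).
    ``fig6_phys`` / ``fig6_path``: single points of the constant-current
    sweep grid (90 / 130 pA somatic K+).
    ``fig7A/B/C``: Poissonian AMPA drive at the soma.
    Use ``injection_sweep`` for the full stimulus-condition grids.
    """
    long_stride = SolverSettings(output_stride=1e-3)
    return {
        "fig3": Preset(
            InjectionProtocol("K", "soma", 22e-12, 1.0, 600.0), 1400.0, long_stride,
            "1 Hz physiological firing with recovery",
        ),
        "fig4": Preset(
            InjectionProtocol("K", "soma", 150e-12, 1.0, 8.0), 600.0, long_stride,
            "depolarization block (pathological)",
        ),
        "fig6_phys": Preset(
            InjectionProtocol("K", "soma", 90e-12, 1.0, 60.0), 60.0,
            SolverSettings(max_step=1e-5),
            "sweep sample point, physiological regime",
        ),
        "fig6_path": Preset(
            InjectionProtocol("K", "soma", 130e-12, 1.0, 60.0), 600.0, long_stride,
            "sweep sample point, pathological regime",
        ),
        "fig7A": Preset(
            SynapseProtocol("soma", 300.0, 1.0, 10.0), 10.0, long_stride,
            "somatic AMPA drive, burst illustration",
        ),
        "fig7B": Preset(
            SynapseProtocol("soma", 300.0, 1.0, 60.0), 60.0, long_stride,
            "somatic AMPA drive, physiological",
        ),
        "fig7C": Preset(
            SynapseProtocol("soma", 700.0, 1.0, 60.0), 600.0, long_stride,
            "somatic AMPA drive, pathological",
        ),
    }


def injection_sweep(
    species: str = "K",
    target: str = "soma",
    amplitudes: np.ndarray | None = None,
    t_on: float = 1.0,
    t_off: float = 60.0,
) -> list[InjectionProtocol]:
    """Constant-current sweep grid across stimulus amplitudes (A)."""
    if amplitudes is None:
        amplitudes = np.arange(20e-12, 200e-12, 20e-12)
    return [
        InjectionProtocol(species, target, float(I), t_on, t_off) for I in amplitudes
    ]
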