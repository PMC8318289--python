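"""Post-processing: extracellular-potential decomposition, slow
potentials, spike metrics, and concentration/volume summaries.

The soma-layer extracellular potential phi_se splits exactly into three
components: the potential predicted by volume-conductor theory from the
neuronal current sink/source configuration (phi_se_n), the analogous
glial component (phi_se_g), and the diffusion-potential correction from
extracellular concentration gradients (phi_se_diff).  Their sum
reproduces the simulator's phi_se identically.

The total dendritic membrane currents entering the volume-conductor
terms (which must include capacitive and stimulus currents) are obtained
from the intracellular axial current balance, i_md * A_m = i_axial * A_i,
rather than by numerically differentiating the membrane potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import COMPARTMENTS, ION_NAMES
from .simulator import Trajectory

__all__ = [
    "PotentialDecomposition",
    "decompose_phi_se",
    "moving_average",
    "selected_slow_potential",
    "detect_spikes",
    "firing_rate",
    "summary_metrics",
]

_DOMAIN_SLICES = {"neuron": (0, 3), "ecs": (1, 4), "glia": (2, 5)}


@dataclass
class PotentialDecomposition:
    """Time series (V) of the three phi_se components and their sum."""

    t: np.ndarray
    phi_se_n: np.ndarray
    phi_se_g: np.ndarray
    phi_se_diff: np.ndarray
    phi_se: np.ndarray  # KNP value from the trajectory

    @property
    def phi_se_sum(self) -> np.ndarray:
        return self.phi_se_n + self.phi_se_g + self.phi_se_diff


def _axial_currents(traj: Trajectory):
    """Vectorized total axial current densities and ECS diffusive part.

    Returns (i_in, i_ig, i_diff_e, sigma_e), each shape (n,)."""
    p = traj.params
    geo, con = p.geometry, p.constants
    D, z, gam = p.D, p.z, p.gamma_n
    c = traj.concentrations
    phi = traj.potentials()

    def domain(s, d, gamma, lam):
        cbar = gamma * (c[:, :, d] + c[:, :, s]) / 2.0
        sig = con.F**2 / (con.RT * lam**2) * (cbar @ (D * z**2))
        grad = gamma * (c[:, :, d] - c[:, :, s])
        i_diff = -con.F / (lam**2 * geo.dx) * (grad @ (D * z))
        i_field = -sig * (phi[:, d] - phi[:, s]) / geo.dx
        return i_diff + i_field, i_diff, sig

    i_in, _, _ = domain(0, 3, gam, geo.lambda_i)
    i_ig, _, _ = domain(2, 5, 1.0, geo.lambda_i)
    _, i_diff_e, sig_e = domain(1, 4, 1.0, geo.lambda_e)
    return i_in, i_ig, i_diff_e, sig_e


def decompose_phi_se(traj: Trajectory) -> PotentialDecomposition:
    """Split the soma-layer ECS potential into neuronal, glial, and
    diffusive components.

    The neuronal/glial terms are the volume-conductor potentials of the
    total dendritic membrane currents (ionic + capacitive + stimulus),
    reconstructed from the axial current balance; the diffusive term is
    the correction from the extracellular diffusion current.  The three
    components sum to the trajectory's phi_se to round-off.
    """
    p = traj.params
    geo = p.geometry
    i_in, i_ig, i_diff_e, sig_e = _axial_currents(traj)
    phi = traj.potentials()
    fac = geo.dx / (geo.A_e * sig_e)
    return PotentialDecomposition(
        t=traj.t,
        phi_se_n=-geo.A_i * i_in * fac,
        phi_se_g=-geo.A_i * i_ig * fac,
        phi_se_diff=-i_diff_e * geo.dx / sig_e,
        phi_se=phi[:, 1],
    )


def moving_average(
    t: np.ndarray, x: np.ndarray, window: float = 10.0, mode: str = "centered"
) -> np.ndarray:
    """Moving average of a uniformly sampled series over a time window.

    Edges use the available partial window.  ``mode`` is ``"centered"``
    (default) or ``"trailing"``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = np.asarray(t)
    x = np.asarray(x, dtype=float)
    if len(t) < 2:
        return x.copy()
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(window / dt)))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    if mode == "centered":
        lo = np.maximum(idx - w // 2, 0)
        hi = np.minimum(idx + (w - w // 2), n)
    elif mode == "trailing":
        lo = np.maximum(idx - w + 1, 0)
        hi = idx + 1
    else:
        raise ValueError("mode must be 'centered' or 'trailing'")
    return (csum[hi] - csum[lo]) / (hi - lo)


def selected_slow_potential(
    decomposition: PotentialDecomposition,
    t_end: float | None = None,
    window: float = 10.0,
) -> dict[str, float]:
    """Scalar slow-potential summary: the mean of each component over the
    final ``window`` seconds ending at ``t_end`` (V)."""
    t = decomposition.t
    if t_end is None:
        t_end = float(t[-1])
    t_lo = t_end - window
    if t_lo < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValueError(
            f"trajectory [{t[0]}, {t[-1]}] s does not cover the averaging "
            f"window [{t_lo}, {t_end}] s"
        )
    mask = (t >= t_lo) & (t <= t_end)
    return {
        "phi_se_n": float(decomposition.phi_se_n[mask].mean()),
        "phi_se_g": float(decomposition.phi_se_g[mask].mean()),
        "phi_se_diff": float(decomposition.phi_se_diff[mask].mean()),
        "phi_se_sum": float(decomposition.phi_se_sum[mask].mean()),
    }


def detect_spikes(
    t: np.ndarray,
    phi_m: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 5e-3,
) -> np.ndarray:
    """Action-potential times: upward threshold crossings separated by at
    least the refractory interval.

    Defaults: 0 V threshold (AP peaks overshoot 0 mV) and 5 ms
    refractory (comfortably shorter than the fastest sustained firing).
    """
    phi_m = np.asarray(phi_m)
    above = phi_m >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    times = np.asarray(t)[crossings]
    kept = [times[0]]
    for ts in times[1:]:
        if ts - kept[-1] >= refractory:
            kept.append(ts)
    return np.asarray(kept)


def firing_rate(
    spike_times: np.ndarray, t_start: float, t_stop: float
) -> float:
    """Mean firing rate (Hz): spike count in [t_start, t_stop) divided by
    the window length."""
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    spike_times = np.asarray(spike_times)
    n = int(np.sum((spike_times >= t_start) & (spike_times < t_stop)))
    return n / (t_stop - t_start)


def summary_metrics(traj: Trajectory, deviation_threshold: float = 0.01) -> dict:
    """Concentration and volume summaries against the initial sample.

    Returns a dict with:

    ``max_abs_deviation``
        (4, 6) array, signed concentration deviation of largest magnitude
        per ion/compartment (mM).
    ``volume_change_pct``
        (n, 3) percent volume change per domain (neuron, ECS, glia),
        soma + dendrite layers summed.
    ``final_volume_change_pct``
        The last row of the above.
    ``recovery_time``
        First time from which every concentration deviation stays below
        ``deviation_threshold`` (mM); NaN if never reached.
    """
    conc = traj.concentrations
    dev = conc - conc[0]
    absdev = np.abs(dev)
    flat_idx = absdev.reshape(len(traj), -1).argmax(axis=0)
    max_dev = np.take_along_axis(
        dev.reshape(len(traj), -1), flat_idx[None, :], axis=0
    ).reshape(4, 6)

    Vdom = np.stack(
        [traj.V[:, s] + traj.V[:, d] for s, d in _DOMAIN_SLICES.values()], axis=1
    )
    vol_pct = 100.0 * (Vdom - Vdom[0]) / Vdom[0]

    exceeded = (absdev >= deviation_threshold).reshape(len(traj), -1).any(axis=1)
    if not exceeded.any():
        recovery = float(traj.t[0])
    elif exceeded[-1]:
        recovery = float("nan")
    else:
        last_bad = int(np.flatnonzero(exceeded)[-1])
        recovery = float(traj.t[last_bad + 1])

    return {
        "ions": ION_NAMES,
        "compartments": COMPARTMENTS,
        "max_abs_deviation": max_dev,
        "volume_change_pct": vol_pct,
        "final_volume_change_pct": vol_pct[-1],
        "recovery_time": recovery,
    }
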