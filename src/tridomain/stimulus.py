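"""Stimulus protocols: constant ionic injection currents and ion-specific
dual-exponential AMPA synaptic drive from Poisson spike trains.

Both stimulus types conserve ions exactly: every ion added to an
intracellular compartment is removed from the adjacent extracellular
compartment (and vice versa), equivalent to a current through an open
ion channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ION_NAMES, ParameterSet

__all__ = [
    "InjectionProtocol",
    "SynapseProtocol",
    "injection_rates",
    "poisson_spike_train",
    "read_spike_times",
    "write_spike_times",
    "synaptic_conductance_envelope",
    "synaptic_currents",
]


def write_spike_times(path, times: np.ndarray) -> None:
    """Write spike times (s) as a one-column plain-text file."""
    np.savetxt(path, np.asarray(times), fmt="%.9f")


def read_spike_times(path) -> np.ndarray:
    """Read a one-column plain-text spike-times file (s), sorted."""
    times = np.loadtxt(path, ndmin=1)
    return np.sort(times)

_ION_Z = {"Na": 1, "K": 1, "Cl": -1, "Ca": 2}
_TARGETS = ("soma", "dendrite", "both")


@dataclass(frozen=True)
class InjectionProtocol:
    """Constant ionic injection current into the neuron.

    ``I_stim`` (A) of charge carried by ``species`` is injected into the
    target neuronal compartment(s) and the same amount of ions removed
    from the paired ECS compartment(s) for t in [t_on, t_off).  With
    target ``"both"`` the current is split equally between soma and
    dendrite.
    """

    species: str = "K"
    target: str = "soma"
    I_stim: float = 22e-12
    t_on: float = 1.0
    t_off: float = 600.0

    def __post_init__(self) -> None:
        if self.species not in ("Na", "K", "Cl"):
            raise ValueError(f"injection species must be Na, K, or Cl, got {self.species!r}")
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")


def injection_rates(protocol: InjectionProtocol, t: float, F: float = 9.648e4) -> np.ndarray:
    """Per-compartment amount-rate corrections (mol/s) at time t.

    Returns a (4, 6) array (ions x compartments): +I/(F z) into the
    intracellular compartment(s) and -I/(F z) from the paired ECS
    compartment(s); zero outside the stimulus window.  The total amount
    of each species is conserved.
    """
    dNdt = np.zeros((4, 6))
    if not (protocol.t_on <= t < protocol.t_off):
        return dNdt
    k = ION_NAMES.index(protocol.species)
    z = _ION_Z[protocol.species]
    if protocol.target == "both":
        currents = ((0, 1, protocol.I_stim / 2.0), (3, 4, protocol.I_stim / 2.0))
    elif protocol.target == "soma":
        currents = ((0, 1, protocol.I_stim),)
    else:
        currents = ((3, 4, protocol.I_stim),)
    for comp_i, comp_e, I in currents:
        rate = I / (F * z)
        dNdt[k, comp_i] += rate
        dNdt[k, comp_e] -= rate
    return dNdt


def poisson_spike_train(
    rate: float, t_start: float, t_stop: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Homogeneous Poisson spike times in [t_start, t_stop), sorted.

    Inter-arrival intervals are sampled i.i.d. exponential with mean
    1/rate; the same seed yields an identical train.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or t_stop <= t_start:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = t_stop - t_start
    # draw in blocks until the window is covered
    n_guess = max(16, int(rate * duration + 6.0 * math.sqrt(rate * duration) + 10))
    times = []
    t = t_start
    while t < t_stop:
        gaps = rng.exponential(1.0 / rate, size=n_guess)
        arrivals = t + np.cumsum(gaps)
        times.append(arrivals)
        t = arrivals[-1]
    spikes = np.concatenate(times)
    return spikes[spikes < t_stop]


@dataclass(frozen=True)
class SynapseProtocol:
    """Poisson-driven AMPA synaptic input.

    The synaptic conductance is a dual exponential with decay time
    ``tau_1`` and rise time ``tau_2``; the current is split between Na+,
    K+, and Ca2+ with fixed maximal conductances (S).  With target
    ``"both"``, independent full-strength synapses with independent
    Poisson trains are attached to each compartment.
    """

    target: str = "soma"
    rate: float = 300.0
    t_start: float = 1.0
    t_stop: float = 60.0
    seed: int = 0
    g_syn_Na: float = 1.0e-9
    g_syn_K: float = 1.9e-9
    g_syn_Ca: float = 6.5e-12
    tau_1: float = 3.0e-3
    tau_2: float = 1.0e-3
    #: optional truncation: drop spikes older than this multiple of tau_1
    #: when summing the conductance envelope (0 disables truncation)
    truncation_window: float = 0.0

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if not self.tau_1 > self.tau_2 > 0:
            raise ValueError("need tau_1 > tau_2 > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.truncation_window and self.truncation_window < 10.0 * self.tau_1:
            raise ValueError("truncation_window must be 0 or >= 10 tau_1")

    def spike_trains(self) -> dict[int, np.ndarray]:
        """Spike trains keyed by target compartment index (0 soma, 3
        dendrite); independent streams derived from the protocol seed."""
        rng = np.random.default_rng(self.seed)
        targets = {"soma": (0,), "dendrite": (3,), "both": (0, 3)}[self.target]
        return {
            comp: poisson_spike_train(self.rate, self.t_start, self.t_stop, rng)
            for comp in targets
        }


def synaptic_conductance_envelope(
    t: float, spike_times: np.ndarray, tau_1: float, tau_2: float, truncation_window: float = 0.0
) -> float:
    """Unitless dual-exponential envelope summed over past spikes:
    sum_s [exp(-(t-t_s)/tau_1) - exp(-(t-t_s)/tau_2)] for t >= t_s."""
    past = spike_times[spike_times <= t]
    if truncation_window:
        past = past[past >= t - truncation_window]
    if past.size == 0:
        return 0.0
    dt = t - past
    return float(np.sum(np.exp(-dt / tau_1) - np.exp(-dt / tau_2)))


def synaptic_currents(
    t: float,
    spike_times: np.ndarray,
    phi_m: float,
    E_Na: float,
    E_K: float,
    E_Ca: float,
    protocol: SynapseProtocol,
) -> tuple[float, float, float]:
    """Ion-specific synaptic currents (I_Na, I_K, I_Ca) in A, outward
    positive (inward currents are negative at rest)."""
    env = synaptic_conductance_envelope(
        t, spike_times, protocol.tau_1, protocol.tau_2, protocol.truncation_window
    )
    return (
        protocol.g_syn_Na * env * (phi_m - E_Na),
        protocol.g_syn_K * env * (phi_m - E_K),
        protocol.g_syn_Ca * env * (phi_m - E_Ca),
    )


def synaptic_rates(
    t: float,
    trains: dict[int, np.ndarray],
    phi_m_by_comp: dict[int, float],
    E_by_comp: dict[int, tuple[float, float, float]],
    protocol: SynapseProtocol,
    F: float = 9.648e4,
) -> np.ndarray:
    """Per-compartment amount-rate corrections (mol/s), shape (4, 6).

    For each targeted neuronal compartment, -I/(F z) is applied
    intracellularly and +I/(F z) extracellularly for Na+, K+, and Ca2+,
    conserving each species exactly.
    """
    dNdt = np.zeros((4, 6))
    for comp, spikes in trains.items():
        comp_e = comp + 1
        I_Na, I_K, I_Ca = synaptic_currents(
            t, spikes, phi_m_by_comp[comp], *E_by_comp[comp], protocol
        )
        for k, I, z in ((0, I_Na, 1.0), (1, I_K, 1.0), (3, I_Ca, 2.0)):
            rate = I / (F * z)
            dNdt[k, comp] -= rate
            dNdt[k, comp_e] += rate
    return dNdt
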