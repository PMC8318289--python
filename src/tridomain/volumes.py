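"""Osmotically driven transmembrane water flow and volume dynamics.

Water crosses each cellular membrane at a rate proportional to the
osmotic pressure difference (van't Hoff; hydrostatic pressure differences
are assumed zero).  The osmotic driving force is expressed as the
difference in *deviation* of each compartment's total solute
concentration from its own t = 0 baseline (the static residual osmolyte
concentration M): this makes all four transmembrane water flows exactly
zero at t = 0 by construction, and any constant background contribution
(e.g. the static residual charges) cancels in the deviation.

The system is closed: ECS volumes absorb the negatives of the cellular
volume changes and the total volume is conserved exactly.  Membrane areas
and axial cross-sections stay constant as volumes change; intra-domain
(axial) water flow is neglected.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet
from .state import SystemState

__all__ = ["volume_derivatives"]


class VolumeCollapseError(RuntimeError):
    """A compartment volume became nonpositive during integration."""


def volume_derivatives(state: SystemState, params: ParameterSet) -> np.ndarray:
    """dV/dt for the six compartments (m^3/s), ordered as COMPARTMENTS.

    Raises
    ------
    VolumeCollapseError
        If any volume is nonpositive.
    """
    if np.any(state.V <= 0):
        raise VolumeCollapseError(
            "nonpositive compartment volume encountered; the simulation "
            "left the physical regime"
        )
    con = params.constants
    mem = params.membrane
    # deviation of total osmolarity from the per-compartment baseline
    dev = state.N.sum(axis=0) / state.V - state.M
    dVdt = np.zeros(6)
    # cellular compartments: dV_i/dt = -G RT (dev_e - dev_i)
    dVdt[0] = -mem.G_n * con.RT * (dev[1] - dev[0])  # sn
    dVdt[2] = -mem.G_g * con.RT * (dev[1] - dev[2])  # sg
    dVdt[3] = -mem.G_n * con.RT * (dev[4] - dev[3])  # dn
    dVdt[5] = -mem.G_g * con.RT * (dev[4] - dev[5])  # dg
    # closed system: the ECS absorbs the opposite
    dVdt[1] = -(dVdt[0] + dVdt[2])
    dVdt[4] = -(dVdt[3] + dVdt[5])
    return dVdt
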