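"""Regenerate the packaged full-precision calibrated resting state.

Starting from the published (rounded) post-calibrated initial values,
the model is relaxed without stimulus until the resting fluxes balance,
with the water permeabilities set to zero and the glial Kir baseline
pinned to the starting composition -- the same calibration procedure
that produced the published column, which was itself written to file at
full precision.  The settled state is written to
``src/tridomain/data/calibrated_state.json`` and shipped as the default
initial condition.

Usage:  python scripts/calibrate.py [--t-relax 500] [--out PATH]
"""

from __future__ import annotations

import argparse
import json
import math
from pathlib import Path

import numpy as np

import tridomain as td
from tridomain.simulator import SolverSettings


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--t-relax", type=float, default=500.0,
                    help="relaxation time in simulated seconds")
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "src/tridomain/data/calibrated_state.json")
    args = ap.parse_args()

    K_e_b, K_g_b = 3.5, 101.2  # published post-calibrated basal values
    E_K_b = (8.314 * 309.14 / 9.648e4) * math.log(K_e_b / K_g_b)
    params = td.build_default_parameters(
        {"membrane": {"G_n": 0.0, "G_g": 0.0,
                      "K_e_basal": K_e_b, "E_K_basal": E_K_b}}
    )
    state0 = td.build_initial_state("post_calibrated", params)
    settings = SolverSettings(max_step=1e-3, output_stride=1.0)
    traj = td.run(None, (0.0, args.t_relax), settings, params, initial_state=state0)
    if not traj.success:
        raise SystemExit(f"relaxation failed: {traj.message}")
    conc = traj.concentrations
    drift = np.abs(conc[-1] - conc[-11]).max()
    print(f"residual drift over final 10 s: {drift:.3e} mM")
    if drift > 1e-3:
        raise SystemExit("state has not settled; increase --t-relax")

    final = traj.state_at(len(traj) - 1)
    c = final.concentrations
    mem = traj.membrane_potentials()[-1]
    print(f"settled: phi_msn={mem[0]*1e3:.4f} mV, phi_msg={mem[2]*1e3:.4f} mV")

    payload = {
        "description": (
            "Full-precision settled resting state, generated by "
            "scripts/calibrate.py (relaxation with zero water "
            "permeability from the published post-calibrated values)."
        ),
        "t_relax_s": args.t_relax,
        "phi_mn0": [float(mem[0]), float(mem[1])],
        "phi_mg0": [float(mem[2]), float(mem[3])],
        "concentrations": {
            ion: {comp: float(c[i, j]) for j, comp in enumerate(td.COMPARTMENTS)}
            for i, ion in enumerate(td.ION_NAMES)
        },
        "gating": {g: float(v) for g, v in zip(td.GATING_NAMES, final.gating)},
        "kir_baseline": {"K_e_basal": K_e_b, "E_K_basal": E_K_b},
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(payload, fh, indent=1)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
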