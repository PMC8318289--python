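"""Overnight regression checks: the long-duration (hundreds of
simulated seconds) quantitative targets.  These require roughly an hour
of compute and are kept out of the desk-scale suite under tests/.

Run with:  python -m pytest regression/ -v
"""

import numpy as np
import pytest

import tridomain as td
from tridomain.analysis import decompose_phi_se, selected_slow_potential, summary_metrics
from tridomain.simulator import SolverSettings


@pytest.fixture(scope="module")
def fig3_full():
    """Full physiological protocol: 22 pA K+ somatic step for 600 s,
    1400 s total with recovery."""
    proto = td.InjectionProtocol("K", "soma", 22e-12, 1.0, 600.0)
    return td.run(proto, (0.0, 1400.0), SolverSettings(output_stride=5e-3))


@pytest.fixture(scope="module")
def fig4_full():
    """Full pathological protocol: 150 pA K+ somatic step for 7 s,
    600 s total to the terminal steady state."""
    proto = td.InjectionProtocol("K", "soma", 150e-12, 1.0, 8.0)
    return td.run(proto, (0.0, 600.0), SolverSettings(output_stride=5e-3))


def test_peak_extracellular_potassium_deviation(fig3_full):
    """Sustained 1 Hz firing deviates [K+]_e by at most ~0.4 mM."""
    m = summary_metrics(fig3_full)
    k_e_dev = max(abs(m["max_abs_deviation"][1, 1]), abs(m["max_abs_deviation"][1, 4]))
    assert k_e_dev == pytest.approx(0.4, abs=0.15)


def test_recovery_time_after_stimulus(fig3_full):
    """All concentrations return to within 0.01 mM of baseline roughly
    700 s after the stimulus ends (about t = 1300 s)."""
    m = summary_metrics(fig3_full)
    assert 1000.0 < m["recovery_time"] < 1400.0


def test_pathological_slow_potential_components(fig4_full):
    """Terminal steady state: neuronal ~ +0.3 mV, glial ~ -0.8 mV,
    diffusive ~ -1.5 mV, summing to ~ -2 mV."""
    dec = decompose_phi_se(fig4_full)
    sel = selected_slow_potential(dec, window=10.0)
    assert sel["phi_se_n"] * 1e3 == pytest.approx(0.3, abs=0.3)
    assert sel["phi_se_g"] * 1e3 == pytest.approx(-0.8, abs=0.4)
    assert sel["phi_se_diff"] * 1e3 == pytest.approx(-1.5, abs=0.5)
    assert sel["phi_se_sum"] * 1e3 == pytest.approx(-2.0, abs=0.7)


def test_terminal_swelling(fig4_full):
    """Terminal volumes: neuron swollen by ~46.7 %, ECS shrunk by
    ~88.5 %, glia shrunk by ~2.44 %."""
    m = summary_metrics(fig4_full)
    neuron, ecs, glia = m["final_volume_change_pct"]
    assert neuron == pytest.approx(46.7, rel=0.1)
    assert ecs == pytest.approx(-88.5, rel=0.1)
    assert glia == pytest.approx(-2.44, rel=0.25)
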