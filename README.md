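# tridomain

An electrodiffusive neuron–extracellular–glia unit model: six coupled
compartments (soma and dendrite layers × neuron/ECS/glia domains) whose
ion concentrations, electrical potentials, and volumes evolve
self-consistently.  The model fires somatic action potentials and
dendritic Ca²⁺ spikelets, tracks the ionic cost of activity and its
homeostatic recovery, swells and shrinks its cells osmotically, and
decomposes the extracellular potential into neuronal, glial, and
diffusive components — the three contributors to slow/DC potentials
that conventional volume-conductor modeling cannot separate.

It is intended for computational neuroscientists studying ion
concentration dynamics, spreading-depression-like pathology, astrocytic
K⁺ buffering, and the biophysical origin of slow extracellular
potentials.

## The model in brief

State: amounts N_k,c of Na⁺, K⁺, Cl⁻, Ca²⁺ in six compartments, six
gating variables, six volumes.  Ion conservation gives, e.g. for the
soma-layer neuron,

    dN_k,sn/dt = −j_k,msn A_m − j_k,in A_i,

with transmembrane flux densities j_m (leaks, Na⁺/K⁺-DR/Ca²⁺/AHP/K-C
channels, 3Na⁺/2K⁺ pump, KCC2, NKCC1, 2Na⁺/Ca²⁺ exchanger; glial Na⁺/Cl⁻
leaks, Kir, pump) and axial electrodiffusive (Nernst–Planck) fluxes

    j_k = −(D_k γ_k/λ²) Δc_k/Δx − (D_k z_k F/λ²RT) c̄_k Δφ/Δx.

Potentials are algebraic functions of the state (Kirchhoff–Nernst–
Planck): membrane potentials from the capacitor relation
φ_m = Q/(c_m A_m), the soma-layer ECS potential from closure of the
axial current loop A_i(i_in + i_ig) = −A_e i_e.  Volumes follow osmosis:
dV_i/dt = −G RT ΔOsm across each membrane, with the ECS absorbing the
balance.  The extracellular potential decomposes exactly as

    φ_se = φ_se,n + φ_se,g + φ_se,diff,

the volume-conductor potentials of the total dendritic neuronal and
glial membrane currents plus the diffusion potential −i_diff,e Δx/σ_e.

See `docs/methods.md` for the full formulation, parameter meanings, and
numerical choices.

## Worked example

```python
import numpy as np
import tridomain as td

params = td.build_default_parameters()

# reversal potentials at the default (post-calibration) composition
ion = params.ions[td.ION_NAMES.index("K")]
E_K = td.nernst_potential(ion, 3.5, 138.1, params.constants)
print(f"E_K,n = {E_K*1e3:.1f} mV")

# 1: resting behaviour, 10 unstimulated seconds
traj = td.run(None, t_span=(0.0, 10.0))
mem = traj.membrane_potentials()
drift = np.abs(traj.concentrations - traj.concentrations[0]).max()
print(f"phi_msn = {mem[:,0].mean()*1e3:.2f} mV, "
      f"phi_msg = {mem[:,2].mean()*1e3:.2f} mV, "
      f"max concentration drift = {drift:.1e} mM")

# 2: constant K+ injection into the soma -> regular firing
proto = td.InjectionProtocol(species="K", target="soma",
                             I_stim=22e-12, t_on=1.0, t_off=600.0)
traj = td.run(proto, t_span=(0.0, 20.0),
              settings=td.SolverSettings(output_stride=5e-4))
spikes = td.detect_spikes(traj.t, traj.membrane_potentials()[:, 0],
                          threshold=-20e-3)
print(f"firing rate over [10, 20] s: {td.firing_rate(spikes, 10, 20):.1f} Hz")

# 3: decompose the extracellular potential
dec = td.decompose_phi_se(traj)
sel = td.selected_slow_potential(dec, window=10.0)
print("slow potential (mV): "
      + ", ".join(f"{k.split('_')[-1]} {v*1e3:+.3f}" for k, v in sel.items()))
```

prints

```
E_K,n = -97.9 mV
phi_msn = -67.04 mV, phi_msg = -83.57 mV, max concentration drift = 7.6e-06 mM
firing rate over [10, 20] s: 2.0 Hz
slow potential (mV): n -0.422, g +0.261, diff -0.008, sum -0.169
```

The resting potentials hold steady and concentrations are static to
1e-5 mM: the shipped calibrated state is a genuine fixed point.  Under
a 22 pA somatic K⁺ injection the neuron settles into regular ~2 Hz
firing, and the slow (10 s averaged) extracellular potential splits
into a negative neuronal contribution (the stimulus is a current sink
at the soma), an opposing positive glial contribution, and a small
diffusion potential.

A thin CLI wraps the same machinery:

```sh
tridomain run --protocol fig3 --t-end 20 --out traj.h5
tridomain analyze traj.h5 --out metrics.json
tridomain sweep --species K --target soma --t-end 60 --out sweep.csv
```

Named presets (`fig3`, `fig4`, `fig6_phys`, `fig6_path`, `fig7A/B/C`)
cover the standard experiments: 22 pA physiological firing, 150 pA
depolarization-block pathology, the constant-current sweep points, and
Poissonian AMPA drive.

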