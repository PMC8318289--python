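# Methods

## The model

`tridomain` simulates a "unit" of layered brain tissue as six coupled
compartments: two layers (soma-level and dendrite-level) times three
domains (neuron, extracellular space, glia).  The neuronal domain is a
two-compartment Pinsky–Rinzel-type neuron; the glial domain represents
the average astrocytic buffering available to that neuron; the ECS is
what it has at its disposal.  Initial volume fractions are
neuron/ECS/glia = 0.4/0.2/0.4 per layer.

The state variables are *amounts of substance* `N[k][c]` for the four
ion species (Na⁺, K⁺, Cl⁻, Ca²⁺) in the six compartments, the six
Hodgkin–Huxley gating variables (h, n, s, c, q, z; the Na⁺ activation m
is instantaneous), and the six compartment volumes — 36 ODEs in total.
Electrical potentials are *not* state variables: they are recovered
algebraically from the ion amounts at every right-hand-side evaluation
(the Kirchhoff–Nernst–Planck scheme):

- the dendrite-layer ECS is the potential reference, φ_de = 0;
- each cellular compartment's membrane potential follows from the
  capacitor relation φ_m = Q/(c_m A_m), where Q = F(Σ_k z_k N_k − X) is
  the compartment's net charge including a static residual X;
- the soma-layer ECS potential φ_se closes the axial current loop:
  A_i(i_in + i_ig) = −A_e i_e, giving a closed-form expression in the
  diffusion current densities and conductivities of the three domains.

Axial transport within each domain is electrodiffusive
(Nernst–Planck): a Fickian term −(D/λ²)γ Δc/Δx plus a field-driven term
−(D z F / λ²RT) c̄ Δφ/Δx, with c̄ the mean of the two layer
concentrations.  Tortuosities λ_i = 3.2 (intracellular) and λ_e = 1.6
(ECS) hinder free diffusion; the intraneuronal mobile fraction γ is 1
for Na⁺/K⁺/Cl⁻ and 0.01 for Ca²⁺ (99 % of intracellular calcium is
buffered; only the free fraction diffuses, sets the Ca²⁺ reversal
potential, and gates the Ca-activated K⁺ machinery).

Membrane mechanisms (fluxes in mol/(m² s), outward positive):

- **Neuron, both compartments**: Na⁺/K⁺/Cl⁻ leaks, a 3Na⁺/2K⁺ pump
  (sigmoidal in intracellular Na⁺ and ECS K⁺, one net charge extruded
  per cycle), KCC2 and NKCC1 cotransporters (electroneutral; NKCC1 is
  gated by a sigmoid with 16 mM ECS-K⁺ midpoint, i.e. essentially
  pathology-only), and a 2Na⁺/Ca²⁺ exchanger that relaxes total
  intracellular Ca²⁺ toward its 0.01 mM basal value with rate
  U_Ca_dec = 75 s⁻¹.
- **Neuron, soma only**: transient Na⁺ (m∞²h) and delayed-rectifier K⁺
  (n) channels.
- **Neuron, dendrite only**: voltage-gated Ca²⁺ (s²z), voltage-gated
  afterhyperpolarization K⁺ (q), and Ca²⁺-activated K⁺ (c·χ) channels;
  χ and the q activation rate are driven by free Ca²⁺ above a
  99.8 nM offset and clamped to [0, 1] and [0, 10 s⁻¹] respectively,
  which keeps all rates nonnegative and all gates in [0, 1].
- **Glia, both compartments**: Na⁺ and Cl⁻ leaks, an inward-rectifying
  K⁺ (Kir) channel whose conductance scales linearly with ECS K⁺
  relative to a basal value and shuts sigmoidally on depolarization
  relative to the K⁺ reversal potential, and a 3Na⁺/2K⁺ pump with
  Hill-type (exponent 1.5, threshold 10 mM) Na⁺ dependence and
  Michaelis-type (threshold 1.5 mM) K⁺ dependence.  The glial domain
  carries no Ca²⁺.

Rate functions with removable singularities of the form u/(e^u − 1) are
evaluated by a 2nd-order series when |u| < 1e-4; the direct and series
branches agree to better than 1e-6 relative where they meet.

## Volume dynamics

Water crosses each cellular membrane at a rate proportional to the
osmotic pressure difference (van't Hoff, hydrostatic pressure
differences assumed zero): dV_i/dt = −G RT (Osm_e − Osm_i).  The
osmolarity entering this force is the *deviation* of each compartment's
total solute concentration from its own t = 0 baseline (the static
residual osmolyte concentration M), so all four water flows are exactly
zero at initialization by construction, and any constant background
contribution cancels.  The ECS volumes absorb the negatives of the
cellular volume changes: total volume is conserved exactly.  Membrane
areas and axial cross-sections stay fixed as volumes change; axial
(intra-domain) water flow is neglected.  Total (not free) ionic amounts
are osmotically active.

## Residual charges and osmolytes

Physical cells contain impermeant anionic macromolecules; the model
represents them as a static residual species X (charge −1, immobile)
whose per-compartment amounts are computed *at initialization, never
read from file*, such that each membrane separates charge Q from −Q
matching the target initial membrane potentials and the system is
exactly electroneutral.  A negative computed amount would mean the
requested initial state is unphysical and raises a configuration error.
The residual osmolytes M are likewise fixed at initialization to each
compartment's initial total ionic osmolar concentration.  Because the
layers may be initialized asymmetrically (see the calibrated state
below), both X and M are computed per compartment from that
compartment's own initial content.

## Initial conditions and the calibrated state

Three named initial conditions ship with the package:

- `pre_calibrated` — the composition assembled from the two predecessor
  single-domain models (rounded published values);
- `post_calibrated` — the resting composition after the combined system
  is calibrated (rounded published values);
- `calibrated` (default) — the package's own full-precision settled
  resting state, generated by `scripts/calibrate.py`.

The calibration procedure relaxes the model from `post_calibrated` for
500 s with the water permeabilities set to zero and the glial Kir
baseline pinned to the starting composition (K_e,b = 3.5 mM), then
stores the settled per-compartment concentrations, gating values, and
membrane potentials at full precision.  This step matters because the
rounded published values are only a few-decimal snapshot of a delicate
flux balance: initialized from the rounded values alone the system
drifts by ~0.05 mM over the first tens of seconds while it re-settles;
from the shipped calibrated state the drift over 10 s is below 1e-5 mM.
The settled state is slightly layer-asymmetric (soma and dendrite carry
different active channels), hence the per-compartment storage.  The
resting potentials of the calibrated state are −67.04 mV (neuron) and
−83.57 mV (glia), within 0.15/0.35 mV of the rounded targets.

The glial Kir baseline constants (K_e,b and the corresponding E_K,b)
are fixed at run start: from explicit membrane-parameter overrides if
given, else from the initial condition's stored baseline, else from the
initial composition itself.

## Stimulus protocols

Constant injections deliver a current I_stim carried by a chosen ion
species (K⁺ by default, the least disruptive choice) into the somatic,
dendritic, or both neuronal compartments, with the same amount of ions
removed from the adjacent ECS compartment — equivalent to a current
through an open ion channel, and exactly ion-conserving.  "Both" splits
the current equally.

Synaptic drive is an ion-specific AMPA conductance: a dual-exponential
envelope (decay 3 ms, rise 1 ms) summed over the spikes of a
homogeneous Poisson train (exponential inter-arrival sampling; the
random stream is owned by the protocol's seed, never global).  The
maximal conductances split the current between Na⁺, K⁺, and Ca²⁺ so
that at rest the K⁺ current is half the Na⁺ current in magnitude and
~2 % of the total is carried by Ca²⁺.  With target "both", independent
full-strength synapses with independent Poisson streams attach to each
compartment.  All past spikes are kept in the envelope sum by default;
an optional truncation window (≥ 10 decay constants) is available for
long high-rate runs.

## Numerical integration

`run()` integrates with SciPy's adaptive embedded Runge–Kutta 3(2)
pair.  The maximal step size (default 1e-4 s) is the effective accuracy
control: in SI units the ion amounts (~1e-16 mol) are far below any
practical absolute tolerance, so the error test binds only on the
gating variables during action potentials, where the step shrinks
below the cap.  Defaults rtol = 1e-6, atol = 1e-9, output stride 1 ms
(0.1–0.5 ms recommended when spike peaks must be resolved on the output
grid; a ~100 ms stride bounds memory on multi-hundred-second runs).
Ion amounts and total volume are conserved exactly by construction of
the right-hand side — every flux enters one compartment and leaves
another — so conservation holds to round-off regardless of step size.

The public `rhs()` composes the electrodiffusion, neuron, glia, and
volume modules and is the reference implementation; the integrator
itself uses a fused scalar kernel (`_kernel.py`) that evaluates the
same expressions ~15× faster.  The test suite asserts the two paths
agree to better than 1e-9 relative on randomized states.  On an invalid
trial state (nonpositive volume or concentration) the kernel returns
NaN derivatives, which makes the integrator shrink its step and
terminate with a failure record and a partial trajectory rather than
crash.

## Analysis

The soma-layer ECS potential splits exactly into three components:
φ_se,n and φ_se,g (volume-conductor potentials of the *total* dendritic
neuronal and glial membrane currents) and φ_se,diff (the diffusion
potential −i_diff,e Δx/σ_e).  The total membrane currents must include
the capacitive and stimulus currents; they are reconstructed from the
intracellular axial current balance i_md A_m = i_axial A_i rather than
by numerically differentiating the membrane potential, which makes the
identity φ_se,n + φ_se,g + φ_se,diff = φ_se hold to round-off at every
sample and avoids differentiation noise.

Slow potentials are the 10 s moving average of each component (centered
by default, trailing available; edges use the partial window), and the
scalar "selected" slow potential of a run is the mean over its final
10 s, where either convention coincides.

Spike detection is upward threshold crossing (default 0 mV) with a 5 ms
refractory interval.  On a 1 ms output grid the ~1 ms action-potential
peaks are undersampled and a 0 mV threshold misses spikes whose sampled
peak falls below zero; rate measurements in the shipped analyses and
tests therefore either sample at ≤ 0.5 ms or pass an explicit −20 mV
threshold, which every action potential exceeds for over 2 ms.

Summary metrics report signed concentration deviations from the initial
sample per ion and compartment, percent volume changes summed per
domain (soma + dendrite layers), and a recovery time defined as the
first time from which all concentration deviations stay below 0.01 mM.

## Default behaviour of the shipped protocols

Values computed by this package's acceptance script and test suite,
with the default parameters and calibrated initial state:

- reversal potentials at the default composition: E_Na,n = 54 mV,
  E_K,n = −98 mV, E_Cl,n = −78 mV, E_Ca,n = 124 mV;
- unstimulated 10 s run: membrane potentials steady at −67.0 mV
  (neuron) and −83.6 mV (glia), concentration drift < 1e-5 mM;
- 22 pA somatic K⁺ step: regular firing at ~2.0 Hz, each action
  potential a somatic spike followed by a ~5 ms dendritic Ca²⁺
  spikelet; the extracellular signature is biphasic, ~−33 mV then
  ~+24 mV;
- 150 pA somatic K⁺ step: ~76 Hz sustained firing over the 7 s
  stimulus; depolarization block appears at higher currents or with
  reduced glial uptake.

## Known limitations

- Exactly two layers × three domains; no lateral or multi-layer
  extension, no open (bath-coupled) boundaries — the unit is closed, so
  nothing clears K⁺ from the system except the glial and neuronal
  uptake within it.
- The closed 1D geometry confines return currents, which inflates fast
  extracellular potential deflections by one to two orders of magnitude
  relative to recordings in open tissue; slow potentials are the
  model's intended observable.
- The Ca²⁺-activated machinery reads a single lumped free-Ca fraction;
  there is no explicit Ca²⁺ buffer kinetics or endoplasmic reticulum.
- Hydrostatic pressure and axial water flow are neglected; membrane
  area does not change as cells swell.
- Temperature enters only through RT/F; channel kinetics carry no Q10.
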