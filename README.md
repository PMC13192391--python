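# ca1plateau

A single-compartment biophysical model of **plateau potentials in CA1
pyramidal neurons** and of their **all-or-none termination by dendritic
inhibition**, with the full analysis pipeline: conductance calibration,
termination-threshold search, timing and decay-τ sweeps, steady-state
fixed-point (phase-plane) analysis, and synthetic surrogate data.

Plateau potentials are prolonged (~140 ms) regenerative depolarizations that
drive dendritic Ca²⁺ signals and behavioral-timescale synaptic plasticity.
Experimentally they are terminated in an all-or-none fashion by inhibitory
input from dendrite-targeting (OLM-type) interneurons: an IPSP either
collapses the plateau outright or leaves its course essentially unchanged.
This package reimplements the conductance-based model that explains that
behavior and makes every analysis step reproducible without wet-lab data.

## The model

An isopotential sphere (d = 10 µm, area 3.14×10⁻⁶ cm², C_m = 1 µF/cm²)
obeying

```
C_m dV/dt = −(I_pas + I_VGCC + I_KCa + I_GABA − I_inj)

I_pas  = g_pas (V − E_pas)
I_VGCC = ḡ_cal · m · h²(caᵢ) · GHK(V, caᵢ, cao)      (Ca²⁺ channel, GHK flux)
I_KCa  = ḡ_kca · m³ · (V − E_K)                       (SK-type, Ca²⁺-gated)
I_GABA = g_syn (V − E_GABA)                            (ExpSyn-style synapse)
dcaᵢ/dt = −10⁴ I_VGCC / (2 F · depth) + (ca_inf − caᵢ)/τ_r
```

The VGCC activation gate `m` has voltage-dependent rates
(α = 0.055·(−27.01−V)/(exp((−27.01−V)/3.8)−1), β = 0.94·exp((−63.01−V)/17));
its Ca²⁺-dependent inactivation is h = ki/(ki+caᵢ).  The SK gate follows
m_inf = (caᵢ/cac)²/(1+(caᵢ/cac)²).  Simulations run at 32 °C with a fixed
0.025 ms step.  The two maximal conductance scales are not constrained a
priori; they are **calibrated by grid search** so that a brief suprathreshold
step evokes a repolarizing plateau of 100–200 ms (experimental cohort:
140.2 ± 10.2 ms, n = 51).

The mechanism in one paragraph: VGCC current sustains the depolarization in
a positive feedback loop; accumulating Ca²⁺ grows the SK current and
inactivates the VGCC, so the plateau is a slowly hyperpolarizing
*near-stable point* of the membrane current.  Solving the quasi-steady
current for I = 0 reveals a second, *repelling* point below it — the
termination threshold — which drifts toward the plateau as Ca²⁺ rises.
That geometry yields all-or-none termination, early resistance to
inhibition, and (through VGCC gate lag) a dynamic threshold that deepens
when approached quickly.

## Worked example

```python
from ca1plateau import calibrated_parameters, simulate
from ca1plateau.calibrate import standard_protocol
from ca1plateau.plateau import detect_plateau, find_termination_threshold

p = calibrated_parameters()            # grid-search-calibrated conductances
proto = standard_protocol(p)           # 10 ms ignition step at 2x threshold
metrics = detect_plateau(simulate(p, proto))
print(f"plateau: {metrics.duration:.1f} ms at {metrics.plateau_level:.1f} mV")

th = find_termination_threshold(p, proto, ipsg_onset=50.0, tau_syn=10.0)
print(f"termination threshold g* = {th.g_star*1e3:.3f} nS")
print(f"just-sub lasts {th.sub_verdict.trial_duration:.1f} ms, "
      f"just-supra {th.supra_verdict.trial_duration:.1f} ms")
```

prints

```
plateau: 148.9 ms at -9.1 mV
termination threshold g* = 0.538 nS
just-sub lasts 143.2 ms, just-supra 43.6 ms
```

— a 148.9 ms plateau near −9 mV, and an IPSG threshold at which the plateau
duration collapses from ~143 ms to ~44 ms across a <1 % amplitude change:
the all-or-none termination.  The same library backs a CLI
(`ca1plateau simulate|threshold|sweep-timing|sweep-amp-tau|phase-plane|`
`calibrate|pharm-scan|synth-population|verify`) and the numbered drivers in
`analysis/` (01 calibration → 08 synthetic population), which write tidy
CSV/JSON tables under `results/`.

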