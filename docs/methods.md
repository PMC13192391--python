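# Methods

## Model

The cell is an isopotential sphere of diameter 10 µm (membrane area
π·d² = 3.1416×10⁻⁶ cm²) with specific capacitance 1 µF/cm².  Five mechanisms
contribute current (densities in mA/cm², outward positive):

* **Leak** — `I_pas = g_pas (V − E_pas)` with g_pas = 5×10⁻⁵ S/cm²
  (membrane time constant 20 ms) and E_pas = −65 mV.
* **Voltage-gated Ca²⁺ channel (VGCC)** —
  `I_VGCC = ḡ_cal · m · h²(caᵢ) · GHK(V, caᵢ, cao)`.
  The activation gate relaxes first-order toward
  m_inf = α/(α+β) with τ_m = 1/(tfa·(α+β)), where
  α(V) = 0.055·(−27.01−V)/(exp((−27.01−V)/3.8)−1) (removable singularity
  at −27.01 mV handled by the series of z/(eᶻ−1)) and
  β(V) = 0.94·exp((−63.01−V)/17); tfa = 1.
  Inactivation is instantaneous in Ca²⁺: h = ki/(ki+caᵢ), ki = 10⁻³ mM.
  The flux factor is the standard constant-field (GHK) expression for a
  divalent ion, `1e-3·2F·(caᵢ·efun(−z) − cao·efun(z))` with
  z = 2FV·10⁻³/(RT) and efun(z) = z/(eᶻ−1) (series 1−z/2 for |z|<10⁻⁴).
  It is zero exactly at the Ca²⁺ Nernst potential (≈ +130 mV at the default
  concentrations) and monotonically increasing in V.  ḡ_cal therefore
  carries permeability-like units making the product a current density.
* **SK-type Ca²⁺-activated K⁺ current** — `I_KCa = ḡ_kca · m³ (V − E_K)`,
  E_K = −90 mV.  Its gate is voltage-independent:
  m_inf = (caᵢ/cac)²/(1+(caᵢ/cac)²) and
  τ_m = [β·(1+(caᵢ/cac)²)]⁻¹ / tadj with cac = 0.025 mM, β = 0.03 ms⁻¹ and
  tadj = 3^((T−22)/10) (= 3 at 32 °C; tadj divides τ, i.e. warms kinetics).
* **Inhibitory synapse** — a point conductance (µS) that jumps by g_max at
  each event and decays exponentially with τ_syn, reversal E_GABA = −75 mV;
  converted to density via the membrane area.  Because the conductance is a
  linear sum of closed-form exponentials it is rendered exactly on the time
  grid rather than integrated.
* **Submembrane Ca²⁺ pool** —
  `dcaᵢ/dt = −10⁴ I_VGCC/(2F·depth) + (ca_inf − caᵢ)/τ_r` with shell depth
  0.1 µm, removal time constant τ_r = 200 ms and resting level
  ca_inf = 10⁻⁴ mM.  The influx term is clamped at ≥ 0 when the Ca²⁺
  current is outward (no unphysical depletion); the clamp can be disabled.

All constants are fields of `ModelParameters` and can be overridden in
configs.  The two maximal conductance scales ḡ_cal and ḡ_kca have no
principled prior value; they are outputs of the calibration (below).  The
packaged defaults are ḡ_cal = 0.1288, ḡ_kca = 5.273×10⁻⁶ (native units).

With ki = 10⁻³ mM and this pool geometry, plateau-scale VGCC current drives
caᵢ to ~0.1–0.2 mM where h² ≈ 10⁻⁴, so the calibrated ḡ_cal is numerically
large (~0.1); this is a units/regime consequence of the h² inactivation
depth, not an independent physiological claim.

## Integration

Fixed-step operator splitting at dt = 0.025 ms: both gates advance by their
exact exponential relaxation (steady state and τ frozen at the step start);
V and caᵢ then advance by an explicit midpoint (RK2) update using the
freshly advanced gates and the stimulus sample of the step.  When the
linear membrane conductance makes the step stiff (dt·g_lin/C_m > 0.5 in
rate units — only reachable with enormous synaptic conductances during
threshold bracketing) the V update switches to a linearized-implicit form,
unconditionally stable and accurate exactly where V is pinned to the
synaptic reversal.  Correctness is established against the same scheme at
dt/100: on the standard protocols the dt = 0.025 ms trace agrees to
~0.01 mV (`verify_integrator`), with monotone convergence under dt halving,
and against the passive RC closed form to <10⁻⁴ relative.

The resting state is found by relaxation in rounds of 2 s until the largest
state derivative falls below 10⁻⁹ (native units).  The relaxation starts
20 mV below E_pas with the pool at its floor, approaching rest from
hyperpolarization: starting at E_pas with a fully de-inactivated VGCC can
transiently ignite the regenerative loop and settle onto a depolarized
attractor that is not the resting state.  Parameter sets that never settle
(oscillatory) raise a diagnostic.

## Standard ignition protocol

Analyses use a brief (10 ms) depolarizing step at **twice** the minimal
plateau-evoking amplitude (the minimal amplitude itself is found by
doubling/halving plus bisection to 2%).  Two deliberate choices:

* *Brief step.*  The inhibition-timing analyses probe the plateau at 10 ms
  after initiation; the plateau must be fully established by then.
* *2× margin.*  A marginal step ignites the plateau so slowly that the
  takeoff outlasts the earliest challenge times, which inverts the timing
  phenotype (the half-formed plateau is cheap to abort).  Real experiments
  likewise drive plateaus with comfortably suprathreshold injections
  (near-100% evocation reliability).

## Plateau detection and termination classification

* V is smoothed with a 1 ms boxcar before level comparisons (removes
  recording-style noise without moving the much slower crossings).
* The reference depolarization V_ref is sampled 5 ms after stimulus offset;
  the **half-repolarization level** is the midpoint of V_ref and rest.  A
  plateau is present when V_ref ≥ rest + 20 mV and V stays above the half
  level for ≥ 20 ms beyond stimulus offset.
* **Duration** runs from stimulus offset to the end of the *last* epoch that
  stays above the half level for ≥ 20 ms.  Using the last sustained epoch
  (not the first crossing) makes the measure immune to transient IPSP dips
  from which the plateau recovers.
* The **break point** is V at the maximal repolarization speed during the
  final approach to rest (the 40 ms preceding the first return to within
  5 mV of rest); this is where the VGCC gate collapses.
* A trial counts as **terminated** by an inhibitory event iff (a) V reaches
  within 5 mV of rest within 100 ms of the event onset AND (b) the plateau
  time remaining after the event is under half of the control's remaining
  time.  The conjunctive rule keeps the IPSP transient itself from counting
  as termination; comparing *remaining* time makes late-onset terminations
  classifiable.
* Threshold searches bisect the event amplitude (doubling to bracket, then
  bisection to a 0.5% relative bracket, ≤ 30 doublings / 60 iterations).

## Phase-plane analysis

Quasi-steady reduction: caᵢ frozen at its instantaneous value, both gates
at steady state, leaving the total current a function of V alone.  Zeros
are located by a dense sign-change scan (0.01 mV default) refined by
bisection to 10⁻⁶ mV; a zero with dI/dV > 0 is stable, dI/dV < 0 repelling.
Branches are linked across time by nearest-V continuation with a 5 mV jump
cap; a fold ends a branch.  Both trace-driven (caᵢ(t) from a simulation)
and independent caᵢ-sweep modes exist.  During the calibrated plateau there
are exactly two branches above rest + 15 mV: the stable branch that V
tracks (with a structural ~2 mV lag — V follows a moving target with a
finite relaxation time, so the property test uses a 3 mV tolerance) and the
repelling threshold branch, which drifts depolarized as caᵢ rises.

**Dynamic threshold.**  The threshold estimate pairs just-sub/supra trials:
the most hyperpolarized V survived by the sub trial vs the supra trial's
maximal hyperpolarization rate (measured over the first 10 ms, the
synaptically driven phase).  This analysis is restricted to fast decay
constants (τ_syn ∈ {2, 3, 5, 10} ms), where termination is a genuine
dip-versus-recover dichotomy.  For slower events the just-threshold IPSG
terminates by gently accelerating the Ca²⁺ clock — there is no dip whose
depth estimates a threshold — so the estimator validates that the sub
trace truly recovers and the supra trace truly reaches rest.

## Calibration

Grid search over ḡ_cal ∈ [5×10⁻², 1] and ḡ_kca ∈ [2×10⁻⁶, 2×10⁻⁴]
(log-spaced, 20 points per axis by default; axes are exploratory and
overridable).  Every cell receives its own standard ignition protocol and
is scored by plateau duration; cells are labeled no-rest (spontaneously
active), no-plateau, nonrepolarizing, or ok, and the feasible set is the ok
cells with durations in the 100–200 ms band (bracketing the experimental
mean of 140.2 ms).  Selection walks the feasible cells outward from the
150 ms midpoint and returns the first that passes a robustness screen:

1. the resting state survives removal of the SK conductance (the
   experimental SK blocker leaves the resting cell at rest — cells deeper
   in the grid lose resting stability without SK and would make the
   SK-block analog meaningless);
2. termination at 50 ms / τ_syn 10 ms is all-or-none (duration jump
   > 50 ms across the bisected bracket; part of the grid is graded).

Without the screen, selection falls back to the bare nearest-to-midpoint
rule.  The packaged `calibrated_parameters()` are the frozen output of this
pipeline on the default grid.

**Channel-block analogs** rerun the calibrated cell with ḡ_cal = 0 (at 1×
and 3× drive) and ḡ_kca = 0.  VGCC removal abolishes the plateau at any
drive; SK removal lengthens it (~1.4–1.5× here) and IPSP-mimicking current
injections still terminate it — hyperpolarization, not the SK current,
does the terminating.

## Synthetic data

No recordings ship with the package.  `corrupt_trace` adds seeded Gaussian
noise and a slow sinusoidal drift to V (measurement noise: currents are
left untouched).  `sample_population` draws log-normal multiplicative
factors (σ = 0.45) for the two conductances per synthetic cell, gives each
its own ignition protocol, and tabulates durations with mean/SEM; draws
without a plateau are recorded, never dropped.  The σ default is the
largest value at which ~90% of draws keep a plateau and the population
mean stays at the base duration.  The attainable duration CV saturates
near 0.2–0.4 because the model is deterministic and each cell's drive is
normalized; the experimental CV (~0.5) additionally contains trial-to-trial
biological variability this model does not represent.  Passing population
tests therefore demonstrate pipeline integrity (seeded reproducibility,
mean recovery), not a match to biological dispersion.

## Problem sizes

The test suite uses the default 0.9 s protocols, an 8×8 calibration grid,
a 51-cell population and dt/20–dt/100 refinement checks; the acceptance
script runs the full 20×20 grid.  These sizes were chosen so the whole
pipeline re-runs from scratch in minutes on one CPU while every reported
quantity is computed, not cached.

## Known limitations

* The quasi-balance of inward and outward currents mid-plateau is good but
  not tighter than ~14% (peak; ~8% mean) of the dominant current: the early
  plateau is still relaxing from ignition while tracking a fast-moving
  stable branch.
* Termination verdicts exactly on the bisected threshold bracket are not
  integrator-independent — on the all-or-none boundary any perturbation,
  including discretization at the 0.01 mV level, flips the outcome.
  Verdicts at a ±10% amplitude margin are integrator-independent.
* No Na⁺, HCN, A-type K⁺ or Ca²⁺-activated Cl⁻ currents; no dendritic
  cable; no stochastic gating.  Experimental features attributable to those
  (AP firing, plateau regeneration, growth of IPSP amplitude late in the
  plateau) are out of scope.
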