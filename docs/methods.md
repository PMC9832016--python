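# Methods

## The plant: a three-neuron corticothalamic motif

Childhood absence epilepsy (CAE) is modeled with three coupled
single-compartment Hodgkin–Huxley-type neurons: a thalamic relay cell (TC),
a cortical cell (CT) and a reticular thalamic cell (RT).  Membrane voltage
obeys

    C dV/dt = −Σ I_ionic − I_syn + I_ext (+ u + d)

with C = 1 µF/cm² for all cells; u is the stimulation (control) current and
d an exogenous disturbance current, both in µA/cm².  Channel complements:
TC — leak, Na, K, low-threshold Ca (I_T), hyperpolarization-activated mixed
cation (I_h), slow K (I_K2); CT — leak, Na, K, muscarinic K (I_M); RT —
leak, Na, K, low-threshold Ca (I_TS).

Synapses (AMPA: CT→TC, TC→CT, TC→RT; GABA_A: RT→TC, RT→RT; GABA_B: RT→TC)
use first-order transmitter-gated kinetics ds/dt = αT(1−s) − βs with the
sigmoidal release function T(V) = 2.84/(1+exp((2−V)/5)), except GABA_B,
which uses the second-order receptor cascade ds/dt = 0.18r − 0.034s,
dr/dt = 0.5T(1−r) − 0.0012r and the fourth-power conductance
ḡ s⁴/(s⁴+K_d).  Two conduction delays enter through the release function:
the corticothalamic delay τ₁ (default 10 ms, configurable 2–10) on CT→TC
and the thalamocortical delay τ₂ = 2.8 ms on TC→CT.

The `normal` and `cae` presets differ only in I_ext^TC (5 vs 6 µA/cm²) and
the RT→TC GABA_A maximal conductance (0.65 vs 0.32 mS/cm²); weaker fast
thalamic inhibition plus stronger drive converts the bursting/single-spiking
normal rhythm into the faster, highly regular tonic spiking of the seizure
state (measured here as higher firing rate and lower ISI coefficient of
variation on all three cells).

### Ionic kinetics choices

The detailed rate functions follow the standard Destexhe-type
formulations: Traub-style Na/K rates with a per-cell threshold shift
(−52 mV for TC and RT, −56.2 mV for CT), I_T with instantaneous m∞²
activation, Huguenard–McCormick I_h and I_K2, a Pospischil-style
regular-spiking I_M for the cortical cell and the reticular-cell I_TS with
m²h gating.  Two conductance values were fixed by the qualitative behavior
the motif must show rather than taken verbatim from the literature: the TC
leak (0.05 mS/cm²) and the RT leak reversal (−90 mV).  With the weaker
literature leaks the isolated TC cell is an intrinsic slow oscillator
(I_T/I_h pacemaker) and the RT cell a spontaneous pacemaker, whereas this
motif requires every uncoupled, undriven cell to rest (verified:
|dV/dt| < 10⁻⁶ mV/ms after 6 s).  Each channel is a named, separately
tested component so transcription errors localize.

## Numerics

Classical RK4 with a fixed step, default dt = 10⁻³ ms (also the control
update period).  Delays are handled by the method of steps: ring buffers at
grid resolution hold past voltages, delays are validated as exact grid
multiples at configuration time, pre-history queries return the initial
voltage, and the delayed transmitter drive is frozen over each step (the
delays exceed dt by 3–4 orders of magnitude).  Observed convergence order
is 4.0 in the asymptotic regime (dt ≤ 4·10⁻³ ms on a 10 ms segment); at
coarser steps spike-flank sensitivity dominates and the order measurement
is not meaningful.  A ±150 mV guard flags divergence.  sign(0) = 0
throughout.  Everything inside the time loop (plant, fuzzy inference,
controller, adaptation) is compiled with numba into a single kernel;
2000 ms at dt = 10⁻³ ms runs in ~10 s on one CPU.

## Canonical control form

For control design the voltage dynamics are read as
ẋ = f(x,t) + f_τ(x_τ,t) + G·u + d with x the three voltages.  f_τ collects
exactly the two synaptic currents whose presynaptic drive is delayed
(CT→TC and TC→CT AMPA); G = diag(1/C) is constant, positive definite and
bounded below by (1/max C)·I.  The recombination f + f_τ + G u + d equals
the plant derivative to machine precision (tested at 1000 random states);
the split is a testing oracle — the deployed controller never sees it.

## The controller

Tracking error e = x_d − x against the normal-plant trajectory x_d; the
desired derivative ẋ_d is evaluated exactly from the normal plant's vector
field along its stored state (no finite differencing).  Nonsingular
terminal sliding surface and fast reaching law:

    s_i = ∫ e_i dt + σ|e_i|^η sign e_i ,      ṡ = −K₁s − K₂|s|^ρ sign s

On the surface the error obeys ė = −|e|^{2−η} sign(e)/(ση), reaching zero
in the finite time t_s = ση/(η−1)|e(t_r)|^{η−1}; the reaching-time and
boundary-layer expressions are exposed as `time_bounds`.

The deployable law is certainty-equivalent with a regularized gain
inverse,  u_c = Ĝᵀ(ε₀I + ĜĜᵀ)⁻¹·[−f̂ − f̂_τ + ẋ_d + (1/ησ)|e|^{2−η}sign e
+ K₁s + K₂|s|^ρ sign s],  plus the continuous robustifying term
u_r = s|sᵀ|(ε̂_f + ε̂_fτ + ε̂_g|u_c| + d̂ + |u₀|)/(σ₀‖s‖² + Υ), where the
bound estimates grow by terminal-weighted adaptive laws and Υ shrinks
monotonically (floored at 10⁻⁶ to avoid division blow-up).  All terms are
continuous in (e, ∫e, s) — the controller is chattering-free by
construction, which the chattering-index comparison against the classical
sliding-mode baseline verifies.

### Fuzzy estimators

15 fuzzy logic systems approximate the unknown dynamics: 3 for f (inputs:
the three voltages), 3 for f_τ (inputs: the delayed voltages), 9 for the
entries of G.  Each uses five Gaussian membership functions per input with
centers (−60, −40, 0, 40, 60) mV and width δ = 1 mV, product inference and
center-average defuzzification (125 rules).  The normalized rule basis
factorizes over inputs, so it is computed exactly as the outer product of
three per-input normalized membership vectors in the log domain; this keeps
the basis a well-defined simplex vector (sum-to-one verified to 10⁻¹²)
even though δ = 1 mV makes raw 125-term products underflow between
centers.  Weights start uniform on [0, 1] and adapt by terminal-gradient
laws ψ̇ ∝ −|e|^{η−1} ζ s (and ·u_c for the gain entries), clipped at ±10⁶
as a numerical safeguard.

### Gains

The source study states its gains were selected by trial and error and does
not print them; the defaults here were tuned the same way against the
nominal tracking scenario and then frozen for all disturbance/uncertainty
runs:

| parameter | value | role |
|---|---|---|
| η, ρ, σ | 1.5, 0.6, 0.05 | surface exponents / scale |
| K₁, K₂ | 2000·I, 400·I | reaching-law gains |
| ε₀ | 1.0 | gain-inverse regularization |
| σ₀, Υ(0), Υ_min | 1, 1, 10⁻⁶ | robust-term denominator |
| κ_f, κ_fτ, κ_g | 10 | estimator learning rates |
| κ₀, γ₀, γ₁, γ₃ | 0.1 | bound-adaptation rates |
| γ₂ | 10⁻³ | ε̂_g adaptation rate |

Two values deserve comment.  ε₀ = 1 (not "very small"): with the true gain
matrix equal to the identity, a strong regularization only rescales the
certainty-equivalent input (the |u₀| term in the robust law compensates)
while greatly taming the start-up transient, when Ĝ is a random, typically
near-singular matrix whose inversion otherwise produces a violent
wrong-direction kick.  γ₂ = 10⁻³: ε̂_g is a monotone integrator multiplying
|u_c| inside the robust term; at γ₂ = 0.1 it winds up to ~80 over a
spike-dense 2000 ms run and turns spike-tracking events unstable.  Tracking
RMSE is insensitive to K₁, K₂ over roughly a decade around the defaults.

### Baselines

The comparison controllers are textbook reconstructions (their exact forms
are not given in the source): an adaptive fuzzy SMC on the linear surface
s = e + λ∫e with a discontinuous k_sw·sign(s) reaching term and the same
estimator bank (λ = 1, k_sw = 20, proportional gain 200 — the terminal
controller's K₁ is unstable on the linear surface at this control rate),
and a per-channel super-twisting controller u = a√|s| sign s + w,
ẇ = b sign s (a = 20, b = 100).

## Scenario generators

*Disturbance*: rectangular current pulses (default 1 ms width) whose onset
intervals are i.i.d. Gamma(shape 2, mean 1/14 s); overlapping pulses merge.
Injected into the CT neuron's voltage equation (the figure-caption
convention; the target is configurable).

*Parameter uncertainty*: each of the 28 ionic maximal conductances and
reversal potentials of the actual plant follows an independent
multiplicative drift 1 + p·w(t), where w is a uniform [−1,1] sequence
redrawn every 2 s, linearly interpolated, passed through a second-order
critically-damped low-pass filter with 0.05 Hz natural frequency and
clamped to [−1,1]; the multiplier stays within [1−p, 1+p] by construction
and ≥95 % of its power lies below 0.1 Hz.  Over a single 2 s trial the
drift is consequently quasi-static, as in the source protocol.

*Initialization*: all six initial voltages uniform on [−60, −20] mV with
gating and synaptic gates at their voltage-dependent steady states; fuzzy
weights uniform on [0, 1].  Every trial is fully determined by (config,
seed); batches spawn independent per-trial seeds.

## What the synthetic conditions do and do not show

The generators reproduce the study's stated conditions (sample sizes,
rates, amplitudes, drift levels).  They do not emulate channel noise,
network heterogeneity beyond three cells, electrode/field geometry, or
measurement noise on the voltages — the controller sees noiseless membrane
potential.  Passing tests therefore demonstrate correctness of the model
and control implementation under the published protocol, not clinical
robustness.

## Problem sizes

Acceptance runs use the full protocol resolution (2000 ms at dt = 10⁻³ ms,
2·10⁶ samples per trial) with 5-trial batches for the disturbance and
uncertainty means (the source used 15); unit and property tests use shorter
segments (20–500 ms closed loop, dt = 10⁻² ms open loop where the
controller is not involved).

## Known limitations

- The ionic kinetics are a documented reconstruction; absolute firing
  rates and bifurcation boundaries will differ from the original model
  even though the qualitative normal/CAE distinction and all tracking
  criteria hold.
- The adaptive bound estimates never decrease (by design); arbitrarily
  long runs would eventually need the γ rates rescaled or a leakage term.
- Baseline controllers are reconstructions; their absolute RMSEs are not
  comparable to the source figures, only their qualitative ordering
  (chattering, degradation) is.
- dt = 10⁻² ms is adequate for open-loop integration but the tuned
  closed loop is only validated at the 10⁻³ ms control period.
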