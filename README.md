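# caedbs

Closed-loop deep-brain-stimulation control of a conductance-based
childhood-absence-epilepsy (CAE) model.

Absence seizures arise from pathological dynamics in the corticothalamic
loop: weakened GABA_A inhibition from the reticular thalamic nucleus onto
thalamic relay cells, together with increased external drive, turns the
normal bursting rhythm of the loop into fast, hypersynchronous tonic
spiking.  This package implements that loop as three coupled
Hodgkin–Huxley-type neurons — thalamic relay (TC), cortical (CT) and
reticular (RT) — with AMPA/GABA_A/GABA_B synapses and two axonal conduction
delays, and asks a control question: can injected stimulation currents
(a simulated closed-loop DBS system) force the seizing network to reproduce
the healthy network's membrane-voltage trajectories, without knowing the
model's equations?

The controller is an **adaptive fuzzy terminal sliding-mode controller
(AFTSMC)**.  Writing the three membrane voltages as
ẋ = f(x) + f_τ(x_τ) + G·u + d, the tracking error e = x_d − x is driven
onto the nonsingular terminal surface

    s_i = ∫₀ᵗ e_i dt + σ|e_i|^η sign(e_i),   1 < η < 2,

by the fast reaching law ṡ = −K₁s − K₂|s|^ρ sign(s), which gives
finite-time convergence with a continuous (chattering-free) input.  The
unknown dynamics f, f_τ and G are approximated online by 15 Gaussian-
membership fuzzy logic systems whose weights adapt by terminal-gradient
laws, and a continuous robustifying term with adaptive disturbance/error
bounds absorbs approximation error and injected disturbances.  Classical
adaptive-fuzzy SMC and super-twisting SMC baselines, gamma-process
disturbance trains, slow filtered parameter drift, and a batched trial
harness with tracking-RMSE and chattering metrics complete the toolkit.

For model equations, parameter tables, tuning rationale and limitations,
see [docs/methods.md](docs/methods.md).

## Worked example

One closed-loop trial: the CAE plant (I_ext^TC = 6 µA/cm²,
ḡ_GABA_A(RT→TC) = 0.32 mS/cm²) tracks the normal plant (5 µA/cm²,
0.65 mS/cm²) for 2000 ms at the 1 µs control period, from random initial
voltages on [−60, −20] mV and random fuzzy weights on [0, 1]:

```python
from caedbs import TrialConfig, run_trial

res = run_trial(TrialConfig(duration_ms=2000.0, dt_ms=1e-3, seed=42))
m = res.metrics()
print(f"TC RMSE = {m['rmse_tc_mv']:.4f} mV")
print(f"CT RMSE = {m['rmse_ct_mv']:.4f} mV")
print(f"RT RMSE = {m['rmse_rt_mv']:.4f} mV")
print(f"chattering index (TC) = {m['chattering_tc']:.3f}")
```

prints

```
TC RMSE = 0.0539 mV
CT RMSE = 0.0495 mV
RT RMSE = 0.0334 mV
chattering index (TC) = 0.301
```

The per-neuron RMSE is the root-mean-square voltage tracking error over
all 2·10⁶ samples; values well below 1 mV mean the seizing network's
voltages are indistinguishable from the healthy trajectory except during
the first milliseconds, i.e. the tonic spiking pattern is fully
suppressed.  The chattering index (mean per-step input change, normalized
by dt and input range) is small because the terminal design keeps the
stimulation current continuous; the classical sliding-mode baseline scores
an order of magnitude higher on the same seed.

The same machinery is available from the shell:

```bash
caedbs simulate --preset cae --duration 2000 --dt 0.01   # open loop
caedbs control --seed 42 --out trial_out                 # one trial
caedbs batch --seed 1 --n-trials 15 --amplitudes 1.25,1.5,1.75,2
caedbs compare --seed 1                                  # controller head-to-head
```

Every output directory contains the resolved configuration and seed for
exact replay; trials are byte-identical given (config, seed).

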