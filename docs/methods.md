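# Methods

## The problem

Synaptic plasticity rules that depend on the postsynaptic membrane
potential — not only on spike times — appear to force a *time-driven*
synapse update: the synapse needs the voltage at every step, so its code
would run every step, for every one of the K incoming connections of a
neuron.  This package implements and certifies the alternative: the
postsynaptic neuron *archives* the plasticity-relevant signal, and the
synapse integrates the archived segment only when a spike actually
crosses it (event-driven), or the neuron maintains one partially
accumulated integral per distinct last-presynaptic-spike time and shares
the integration across all incoming synapses (event-driven with
compression).

Three rules are implemented: pair-based STDP (the baseline that needs no
voltage archive), the Clopath rule (voltage-based STDP with a sparse,
thresholded LTP signal), and the Urbanczik–Senn rule (dendritic
prediction error, a dense signal that never vanishes).  The Urbanczik–Senn
rule also has a spike-based variant in which the dendritic rate
prediction is replaced by a Poisson sample, making the error a pure
spike–spike comparison.

## Update algebra

All histories are keyed by integer grid steps (`t = alpha * h`,
`h = 0.1 ms` by default); intervals are half-open `(t_from, t_to]`, and
all voltage reads are shifted by the connection (dendritic) delay `d`, so
a synapse updating at arrival step `t_S` reads history up to
`t_S - d` — which is always available under min_delay-batched delivery.

The central identity is the exponential-prefactor decomposition of the
inter-spike integral.  With the presynaptic trace
`x(t) = x(t_LS+) * exp(-(t - t_LS)/tau_s)` the weight update between two
presynaptic spikes factorizes into the trace amplitude times a purely
postsynaptic integral `dW_i(t_LS, t_S)`, and that integral decomposes
over any interior split:

```
dW_i(t_ref, t2) = dW_i(t_ref, t1) + exp(-(t1 - t_ref) h / tau_s) * dW_i(t1, t2)
```

Every scheme traverses the same per-step products and differs only in
how partial sums are associated:

* **event-driven** — one-shot integration of the whole segment at the
  spike;
* **time-driven** — the same accumulator advanced once per min_delay
  slice (one imposed synapse call per slice);
* **compressed** — the accumulator lives in the postsynaptic node, one
  per distinct last-spike key, advanced for all keys from a single
  integration of the raw trace.

Because the decomposition is exact, schemes agree to float
re-association (measured ~1e-15 relative; certified < 1e-9).

For the Urbanczik–Senn rule the nested double integral (the plasticity
low-pass `kappa` applied to the error-times-trace product) is decomposed
into the pair

```
I1(a,b) = sum_{a < t <= b}  V*(t) x(t) h
I2(a,b) = sum_{a < t <= b}  exp(-(b-t) h/tau_kappa) V*(t) x(t) h
dW      = eta * [ I1 - I2 + I2_acc * (1 - exp(-dt/tau_kappa)) ]
I2_acc <-  exp(-dt/tau_kappa) * I2_acc + I2
```

with a per-synapse running accumulator `I2_acc` carrying the dependence
on the full past.  A brute-force discretized double sum (geometric bin
weight `1 - exp(-h/tau_kappa)` per outer bin, exact exponential decay)
reproduces the cumulative updates to 1e-10 relative; the test suite
implements that oracle independently.

Forward-Euler conventions: weight dependence at interval start,
rectangle rule on the grid, piecewise-constant voltage.  Spikes enter
grid sums as `indicator / h` (one delta of unit weight per bin), which
makes the rate-based and spike-based prediction errors commensurable;
the spike-based error is unbiased for the rate-based one by
construction, verified by Monte-Carlo (1e5 dendritic samplings, 3-sigma
band).

## Archiving and garbage collection

Each archived entry carries an access counter.  A segment read
increments the counters of the returned entries; an entry whose counter
reached the in-degree K of non-compressed readers can never be requested
again and is deleted (front-contiguous only — entries are consumed
oldest-first).  The compressed scheme instead prunes the raw trace up to
its integration frontier.  Reading below the pruned frontier raises a
hard "history underrun" error: it can only mean a GC bug, never a
recoverable condition.  Clopath LTD needs only a delayed point value of
the filtered potential, so it is served from a fixed-length ring buffer
(capacity max_delay + 1) without access counting.

Linear iteration is used for all history searches; no auxiliary
per-spike index is kept.

## Complexity instrumentation

Counters follow the published complexity model of the three schemes:

| quantity | time-driven | event-driven | compressed |
|---|---|---|---|
| history length L | 1 | I | i |
| synapse calls M | K·T | K·T/I | K·T/I |
| weight-change computations C | K·T | K·T | T |
| history manipulations H | T | T | K·T/I·i |

with I the homogeneous inter-spike interval in steps and i the number of
distinct last-spike times.  Semantics: M counts synapse function calls
(event dispatches, or one imposed call per slice for time-driven); C
counts per-step infinitesimal weight-change computations; H counts entry
writes — appends for the raw histories, in-place accumulator updates for
the compressed history (each synapse call touches every stored key;
keys created in the same delivery batch are vacuous and skipped).  In
the compressed scheme the raw trace buffered between events is a
transient integration workspace and its appends are not charged to H,
matching the model above; deletions and reads are never charged.  L_max
is sampled at step boundaries.  The counter experiment phases
presynaptic emissions so arrivals fall at exact multiples of I and
excludes one warmup interval (the formulas are asymptotic per-T counts),
after which all identities hold as exact integers.

## Neuron models

**Clopath-variant AdEx** (`aeif` with delta-pulse inputs).  Defaults are
the published visual-cortex set: C_m = 281 pF, g_L = 30 nS,
E_L = −70.6 mV, Delta_T = 2 mV, V_T_rest = −50.4 mV, tau_w = 144 ms,
a = 4 nS, b = 80.5 pA; filters tau_minus = 10 ms, tau_plus = 7 ms,
thresholds theta_minus = −70.6 mV, theta_plus = −45.3 mV, d_s = 3 ms.
On threshold crossing (`V >= V_T + 2 Delta_T`; the exponential term is
capped at its value at `V_T + 10 Delta_T`) the voltage is clamped to
V_clamp = 33 mV for t_clamp = 2 ms to mimic the action-potential
waveform, the adaptive threshold jumps to V_T_max and relaxes with
tau_VT, and the clamp releases into a depolarized reset
(V_reset = E_L + 15 mV, configurable).  The depolarized release mimics
the afterdepolarization of the original model neuron; releasing at rest
instead lets spike-triggered adaptation hyperpolarize the baseline
between pairings, which inverts the low-frequency end of the pairing
curve.

The LTP-driving signal `V*_LTP(t) = (u_plus(t−d_s) − theta_minus)_+ ·
(V(t) − theta_plus)_+` is computed neuron-side every step and archived
sparsely (non-zero values only).  The backward shift d_s applies to the
filtered potentials; the bare voltage enters unshifted.  An alternative
reading of the original figure shifts the whole product (bare V
included); both reproduce the pairing phenomenology here, and the
unshifted-V convention was kept as the more literal reading of the
rule's equations.  The LTD ring buffer likewise stores
`u_minus(t − d_s)` and is read at `t_S − d` (connection delay only).

**Two-compartment Poisson neuron.**  Soma and dendrite are leaky
compartments (round documented values: C_m = 300 pF each,
g_L = 30 nS each, coupling g_D = 60 nS, E_L = −70 mV, E_E = 0 mV,
E_I = −75 mV; dendritic synaptic current decays with tau_syn = 5 ms).
The soma fires with probability `phi(U)·h` per step — logistic
`phi(V) = phi_max / (1 + exp(−(V − theta)/slope))` with
phi_max = 0.15 /ms, theta = −55 mV, slope = 5 mV, sensitivity
`h(V) = phi'/phi` — with no reset and no refractory period (pure Poisson
readout; the simplest consistent choice).  The dendritic prediction is
V_dend itself by default; the attenuation `g_D/(g_L+g_D)` is a
configuration switch.  At the fixed point of learning the
dendro-somatic coupling cancels and the soma sits at the
teaching-conductance mixture potential
`U_M = (g_L E_L + g_E E_E + g_I E_I)/(g_L + g_E + g_I)`, which is why
the teaching task's loss is defined against exactly that potential.

## Synthetic study conditions

The experiments module defines the conditions everything is measured
under; they emulate the canonical protocols but are deliberately small.

* **Spike pairing** — 5 pre/post pairs at lag ±10 ms, 10–50 Hz, spikes
  forced by one-step current pulses whose amplitude is auto-calibrated
  (doubled until every pulse elicits exactly one spike at the pulse
  step); a readout presynaptic spike 300 ms after the last pair, when
  the filtered potentials are back at rest, flushes the final LTP
  segment without adding depression.  With the 1/tau_s-normalized trace
  kernel the LTP amplitude absorbs a normalization factor; the default
  A_LTP = 4e-3 mV⁻² was calibrated once so this protocol reproduces the
  canonical frequency dependence (pre-post non-decreasing, post-pre
  crossing from depression to potentiation), with A_LTD = 14e-5 mV⁻¹
  at its published value.  Single-step forcing pulses depolarize less
  than a physiological approach to threshold, so amplitudes fitted to
  the original waveform do not transfer literally.
* **E–I network** — 10 excitatory, 3 inhibitory AdEx neurons, 20 Poisson
  sources whose rate profile is a Gaussian bump over source index
  (peak 100 Hz, sigma 3) re-centered every 100 ms; each E neuron reads a
  topographic window (half-width 3) of the sources.  Source→E and E→E
  connections are plastic with a reduced A_LTP = 2e-4 mV⁻² — the
  homeostatic regulation that balances potentiation in long network runs
  is out of scope, so the fixture uses a fixed amplitude that keeps
  weights off their bounds.  Co-activation of neighbouring neurons by
  the moving bump produces bidirectional top-quartile weight motifs.
* **Teaching task** — 100 afferents (60 excitatory / 40 inhibitory,
  Dale-constrained) deliver a frozen 100 ms Poisson pattern (15 Hz each)
  to the dendrite; the soma receives sinusoidal teaching conductances
  solved so that U_M = −60 ± 5 mV at fixed total teaching conductance
  60 nS.  Loss per repetition = time-averaged `(phi(U) − phi(U_M))²`.
  eta = 300 (pA of dendritic current per unit of the dimensionless
  error integral) was chosen once so learning converges within ~60
  repetitions; both the rate- and spike-based variants more than halve
  the loss between the first and last decile of repetitions.
* **Cross-scheme equivalence** — frozen synthetic postsynaptic
  trajectories (burst-like sparse LTP signal for Clopath; a smooth
  random dendritic potential with Poisson somatic spikes for
  Urbanczik–Senn) and K = 20 frozen 50 Hz Poisson input trains, 2000
  steps, delays equal to the step; the deviation is the max over
  synapses and spike times against the event-driven reference.

What these conditions do *not* emulate: conductance-based synapses,
heterogeneous delays in the compressed scheme (rejected at build time,
as in the reference design), realistic cortical in-degrees (K ~ 5000),
wall-clock performance, and the homeostatic voltage dependence of the
LTP amplitude.  Passing tests therefore certify the *algebraic
equivalence and complexity accounting* of the schemes and the
*qualitative* reproduction of the canonical plasticity phenomenology,
not quantitative fits to experimental data.

## Numerical choices and degenerate inputs

* Exact exponential updates for all linear filters (`u' = V + (u−V)
  e^{−h/tau}`), forward Euler for the nonlinear neuron equations.
* Deliveries within a slice are dispatched in (arrival step,
  presynaptic id, connection index) order, giving one canonical
  float-summation order.
* A single master seed spawns independent named RNG streams (inputs,
  soma sampling, dendritic sampling), so enabling the spike-based
  variant never perturbs the somatic spike stream.
* `T` not a multiple of min_delay is rounded up with a warning.
* Zero-valued sparse history writes are dropped silently (and not
  counted); empty segments integrate to zero; zero learning rates leave
  weights bitwise unchanged while every weight-change computation still
  executes.
* Simultaneous pre-arrival and post-spike: the postsynaptic spike at
  exactly the shifted read frontier belongs to the *next* interval
  (half-open convention).

## Known limitations

Pure-Python step loop (the point here is algorithmic accounting, not
throughput); no MPI/thread parallelism; no Hodgkin–Huxley neuron
variant; binary-search history access not implemented (linear iteration
only); the compressed scheme requires delay = h, enforced at build time.
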