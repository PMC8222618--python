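# voltarch

Event-driven synapse updates for voltage-based plasticity rules, in a
small hybrid-clock spiking-network simulator.

## The problem

Modern spiking-network simulators update neurons time-driven on a fixed
grid but touch synapse code only when a spike crosses a synapse — which
works for spike-timing dependent plasticity (STDP), where all the
information a synapse needs is spike times and exponentially filtered
spike traces.  Voltage-based rules break this: in the Clopath rule the
potentiation term is

    dW/dt  =  A_LTP · x̄_j(t) · (ū₊(t−d_s) − θ₋)₊ · (V(t) − θ₊)₊

and in the Urbanczik–Senn rule the weight change is a low-pass-filtered
product of a dendritic prediction error with the presynaptic trace,

    dW/dt = η (κ ∗ [V* · x̄_j])(t),    V* = (s_i − φ(V̂)) · h(V̂),

so the synapse needs the *time course* of postsynaptic state between two
presynaptic spikes, not just point values.  voltarch implements the two
archiving algorithms that reconcile this with event-driven updates:

* **event-driven** — the postsynaptic neuron archives the
  plasticity signal per step (sparsely for the thresholded Clopath
  signal, densely for the never-vanishing prediction error); each entry
  carries an access counter and is garbage-collected once all K
  incoming synapses have read it;
* **event-driven, compressed** — because the presynaptic trace enters
  only through an exponential prefactor, the inter-spike integral
  decomposes over interior splits; the neuron keeps one partially
  accumulated integral per distinct last-presynaptic-spike time and a
  single integration of the voltage trace advances all of them
  (legal when delays equal the simulation step);

next to a **time-driven** reference scheme (one imposed synapse call per
min_delay slice).  An instrumentation layer counts synapse calls M,
infinitesimal weight-change computations C, history-entry manipulations
H and the peak history length L, whose scheme-wise formulas
(time-driven {L=1, M=C=K·T, H=T}; event-driven {L=I, M=K·T/I, C=K·T,
H=T}; compressed {L=i, M=K·T/I, C=T, H=K·T/I·i}) hold as exact integer
identities under homogeneous firing.

Correctness is certified by cross-scheme equivalence (all schemes
produce the same weights at every presynaptic spike time to float
re-association) and by brute-force oracles for the analytic integral
decompositions.  Who this is for: developers of simulator plasticity
infrastructure and designers of learning rules who want to know what a
rule's storage profile costs before scaling it up.

## Worked example

Cross-scheme equivalence for the Clopath rule, and the complexity
counters of the compressed scheme:

```
$ voltarch equivalence --rule clopath --t-steps 2000 --k 20
max relative deviation 2.211e-16  PASS

$ voltarch counters --k 100 --i 10 --t 1000 --scheme event_driven_compressed
{"M": 10000, "C": 1000, "H": 10000, "L_max": 1}
```

The first command runs identical frozen input spike trains and
postsynaptic voltage trajectories through the time-driven, event-driven
and compressed schemes and reports the largest relative weight
difference at any presynaptic spike time — here at the level of
float rounding.  The
second drives one neuron with K=100 synchronously firing inputs at an
inter-spike interval of I=10 steps for T=1000 steps: synapse code runs
M = K·T/I = 10000 times, the voltage trace is integrated only once
(C = T = 1000 weight-change computations instead of K·T = 100000), each
call touches the single shared accumulator (H = M·i = 10000 with i = 1),
and the compressed history never holds more than one entry (L_max = 1).

The canonical plasticity phenomenology is reproduced by the protocol
harnesses:

```
$ voltarch sweep
 10.0 Hz  pre-post 1.0084  post-pre 0.9898
 20.0 Hz  pre-post 1.0084  post-pre 0.9902
 30.0 Hz  pre-post 1.0118  post-pre 0.9904
 40.0 Hz  pre-post 1.1220  post-pre 1.0625
 50.0 Hz  pre-post 1.4857  post-pre 1.4306
```

— the relative weight change after five forced spike pairs: pre→post
pairs potentiate increasingly with pairing frequency, post→pre pairs
depress at low frequency and cross into potentiation at high frequency.

```
$ voltarch urbanczik-task --variant spike --n-reps 60
loss first10% 4.504e-04 -> last10% 3.380e-05
```

— a two-compartment neuron learns to reproduce a sinusoidal target
potential from a frozen dendritic spike pattern; the time-averaged
squared rate error falls by well over half even with the noisy
spike-based prediction error.

## Layout

| module | contents |
|---|---|
| `voltarch.engine` | clock, min_delay slicing, scheme dispatch, counters, network build/run |
| `voltarch.neurons` | Clopath-variant AdEx neuron, two-compartment Poisson neuron, stimulus generators |
| `voltarch.archiving` | histories with access counters, pruning, ring buffer, compressed accumulators |
| `voltarch.plasticity` | STDP / Clopath / Urbanczik–Senn update algebra for all schemes |
| `voltarch.experiments` | pairing protocol, E–I fixture, teaching task, equivalence and counter harnesses |
| `voltarch.cli` | config loading, writers, manifests, `voltarch` command line |

See `docs/methods.md` for the model equations, parameter defaults and
the design decisions behind them.
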