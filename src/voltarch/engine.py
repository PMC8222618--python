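"""Fixed-step simulation kernel with min_delay-batched spike delivery.

The simulator uses the hybrid clock common to spiking-network engines:
neurons advance time-driven on the grid ``t = alpha * h`` while synapses
are updated according to their scheme — ``time_driven`` (one imposed call
per min_delay slice), ``event_driven`` (only when a spike crosses the
synapse, reading archived postsynaptic signals), or
``event_driven_compressed`` (node-side accumulators shared across all
incoming connections; legal only when the connection delay equals the
step size, because spike delivery is batched per min_delay and therefore
not chronological across synapses otherwise).

All times are integer steps internally; milliseconds exist only at the
I/O boundary.  A spike emitted at step ``a`` reaches a synapse with delay
``d`` at step ``a + d``; within a delivery batch events are dispatched in
``(arrival step, presynaptic id, connection index)`` order so that
floating-point summation has one canonical association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import archiving, plasticity
from .archiving import (CompressedHistory, ContinuousHistory, DelayRingBuffer,
                        SparseHistory, SpikeArchive)
from .neurons import (AdexClopathState, ClopathNeuronParams,
                      TwoCompartmentParams, TwoCompartmentState,
                      adex_clopath_step, two_compartment_step)

SCHEMES = ("time_driven", "event_driven", "event_driven_compressed")
RULES = ("static", "stdp", "clopath", "urbanczik")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationClock:
    h_ms: float = 0.1
    step: int = 0
    min_delay_steps: int = 1
    max_delay_steps: int = 1


@dataclass(frozen=True)
class SpikeEvent:
    source: int
    step: int            # emission step


@dataclass
class InstrumentationCounters:
    """Complexity accounting: synapse calls M, infinitesimal weight-change
    computations C, history-entry writes H (appends / in-place updates;
    deletions and reads are free), and the peak history length L_max."""

    M: int = 0
    C: int = 0
    H: int = 0
    L_max: int = 0

    def snapshot(self) -> "InstrumentationCounters":
        return InstrumentationCounters(self.M, self.C, self.H, self.L_max)

    def delta(self, earlier: "InstrumentationCounters") -> "InstrumentationCounters":
        return InstrumentationCounters(
            self.M - earlier.M, self.C - earlier.C, self.H - earlier.H,
            self.L_max)

    def reset_peak(self) -> None:
        self.L_max = 0

    def as_dict(self) -> dict:
        return {"M": self.M, "C": self.C, "H": self.H, "L_max": self.L_max}


# -- engine-side neuron wrappers -------------------------------------------

class SpikeSourceNeuron:
    """Plays back a fixed train of emission steps."""

    def __init__(self, spike_steps):
        self.spike_steps = set(int(s) for s in spike_steps)

    def deliver(self, step, weight, port):  # sources ignore input
        pass

    def advance(self, t_step, node, counters, rngs) -> bool:
        return t_step in self.spike_steps


class ScriptedNeuron:
    """Plays back frozen postsynaptic signal trajectories.

    Arrays are indexed by step-1 (value for grid step 1 first).  Used by
    the cross-scheme and counter harnesses, where identical voltage
    trajectories must be fed to every scheme.
    """

    def __init__(self, vltp=None, u_minus=None, vstar=None, spike_steps=(),
                 theta_minus=0.0):
        self.vltp = None if vltp is None else np.asarray(vltp, float)
        self.u_minus = None if u_minus is None else np.asarray(u_minus, float)
        self.vstar = None if vstar is None else np.asarray(vstar, float)
        self.spike_steps = set(int(s) for s in spike_steps)
        self.theta_minus = theta_minus

    def deliver(self, step, weight, port):
        pass

    def advance(self, t_step, node, counters, rngs) -> bool:
        i = t_step - 1
        if node is not None:
            if node.vltp is not None and self.vltp is not None:
                node.write_vltp(t_step, float(self.vltp[i]), counters)
            if node.ring is not None:
                u = float(self.u_minus[i]) if self.u_minus is not None else 0.0
                node.ring.write(t_step, u)
            if node.vstar is not None and self.vstar is not None:
                node.write_vstar(t_step, float(self.vstar[i]), counters)
            spiked = t_step in self.spike_steps
            if spiked and node.spike_archive is not None:
                node.spike_archive.set_spiketime(t_step, counters)
            return spiked
        return t_step in self.spike_steps


class AdexClopathNeuron:
    """Clopath-variant AdEx neuron wired to its archiving node.

    Incoming spikes are delta pulses on the membrane (mV per unit weight).
    ``I_ext`` may be a scalar, an array over steps, or a dict
    step -> pA pulse.  The node receives the thresholded LTP signal
    ``max(u_plus(t - d_s) - theta_minus, 0) * max(V(t) - theta_plus, 0)``
    and the ``d_s``-shifted low-pass potential u_minus for the LTD ring.
    """

    def __init__(self, params: ClopathNeuronParams | None = None, I_ext=0.0,
                 h_ms: float = 0.1):
        self.params = params or ClopathNeuronParams()
        p = self.params
        self.state = AdexClopathState(
            V=p.E_L_mV, w_adapt=0.0, V_T=p.V_T_rest_mV,
            u_minus=p.E_L_mV, u_plus=p.E_L_mV)
        self.I_ext = I_ext
        self._pending: dict[int, float] = {}
        self._ds = p.d_s_steps(h_ms)
        # rolling shift registers for the d_s-delayed filtered potentials
        self._uplus_hist = [p.E_L_mV] * (self._ds + 1)
        self._uminus_hist = [p.E_L_mV] * (self._ds + 1)

    def deliver(self, step, weight, port):
        self._pending[step] = self._pending.get(step, 0.0) + weight

    def _i_ext_at(self, t_step):
        if isinstance(self.I_ext, dict):
            return self.I_ext.get(t_step, 0.0)
        if np.ndim(self.I_ext) > 0:
            return float(self.I_ext[t_step - 1])
        return float(self.I_ext)

    def advance(self, t_step, node, counters, rngs) -> bool:
        self.state.V += self._pending.pop(t_step, 0.0)
        h = node.h_ms if node is not None else 0.1
        self.state, spiked = adex_clopath_step(
            self.state, self.params, self._i_ext_at(t_step), h)
        self._uplus_hist.append(self.state.u_plus)
        self._uminus_hist.append(self.state.u_minus)
        uplus_shift = self._uplus_hist.pop(0)
        uminus_shift = self._uminus_hist.pop(0)
        if node is not None:
            p = self.params
            v_ltp = max(uplus_shift - p.theta_minus_mV, 0.0) \
                * max(self.state.V - p.theta_plus_mV, 0.0)
            if node.vltp is not None:
                node.write_vltp(t_step, v_ltp, counters)
            if node.ring is not None:
                node.ring.write(t_step, uminus_shift)
            if spiked and node.spike_archive is not None:
                node.spike_archive.set_spiketime(t_step, counters)
        return spiked


class TwoCompartmentNeuron:
    """Soma+dendrite Poisson neuron wired to its archiving node.

    ``g_E``/``g_I`` are arrays of teaching conductances per step (nS).
    Incoming spikes on the dendrite port add ``weight`` pA to the
    exponentially decaying dendritic current.  The prediction-error
    signal V* (rate or spike variant) is written to the node each step.
    """

    def __init__(self, params: TwoCompartmentParams | None = None,
                 g_E=None, g_I=None, variant: str = "rate",
                 record_potentials: bool = False):
        self.params = params or TwoCompartmentParams()
        p = self.params
        self.state = TwoCompartmentState(U=p.E_L_mV, V_dend=p.E_L_mV)
        self.g_E = g_E
        self.g_I = g_I
        self.variant = variant
        self._pending: dict[int, float] = {}
        self.u_log: list[float] | None = [] if record_potentials else None

    def deliver(self, step, weight, port):
        if port not in (None, "dendrite"):
            raise ConfigurationError(f"unknown port {port!r}")
        self._pending[step] = self._pending.get(step, 0.0) + weight

    def _g_at(self, arr, t_step):
        if arr is None:
            return 0.0
        if np.ndim(arr) > 0:
            return float(arr[(t_step - 1) % len(arr)])
        return float(arr)

    def advance(self, t_step, node, counters, rngs) -> bool:
        self.state.I_dend += self._pending.pop(t_step, 0.0)
        self.state.g_E = self._g_at(self.g_E, t_step)
        self.state.g_I = self._g_at(self.g_I, t_step)
        h = node.h_ms if node is not None else 0.1
        self.state, spiked, (s_ind, v_hat) = two_compartment_step(
            self.state, self.params, h, rngs["soma"])
        if self.u_log is not None:
            self.u_log.append(self.state.U)
        if node is not None and node.vstar is not None:
            v_star = plasticity.urbanczik_error_signal(
                s_ind, v_hat, self.params.rate, h, self.variant, rngs["dend"])
            node.write_vstar(t_step, v_star, counters)
        if node is not None and spiked and node.spike_archive is not None:
            node.spike_archive.set_spiketime(t_step, counters)
        return spiked


# -- archiving node ---------------------------------------------------------

class ArchivingNode:
    """Per-neuron container of plasticity histories and their GC policy.

    Containers are created for the signals that at least one incoming
    plastic connection actually reads.  Raw-history appends count toward H
    only when a non-compressed reader exists (the complexity model of the
    compressed scheme charges compressed-entry updates instead); pruning
    combines the access-counter criterion (in-degree of non-compressed
    readers) with the compressed integration frontier.
    """

    def __init__(self, h_ms: float):
        self.h_ms = h_ms
        self.vltp: SparseHistory | None = None
        self.vstar: ContinuousHistory | None = None
        self.ring: DelayRingBuffer | None = None
        self.spike_archive: SpikeArchive | None = None
        self.comp_clopath: CompressedHistory | None = None
        self.comp_urbanczik: CompressedHistory | None = None
        self.theta_minus: float = 0.0
        self.k_clopath = 0           # non-compressed Clopath readers
        self.k_urbanczik = 0
        self.k_stdp = 0

    # -- writes ------------------------------------------------------------
    def write_vltp(self, t_step, value, counters):
        self.vltp.write(t_step, value,
                        counters if self.k_clopath > 0 else None)

    def write_vstar(self, t_step, value, counters):
        self.vstar.write(t_step, value,
                         counters if self.k_urbanczik > 0 else None)

    # -- garbage collection -------------------------------------------------
    def _prune(self, hist, k, comp):
        if hist is None:
            return
        if comp is None:
            hist.prune(k)
            return
        while hist.entries and hist.entries[0].t_step <= comp.t_proc \
                and hist.entries[0].access_counter >= k:
            e = hist.entries.popleft()
            hist.pruned_through = max(hist.pruned_through, e.t_step)

    def prune_clopath(self):
        self._prune(self.vltp, self.k_clopath, self.comp_clopath)

    def prune_urbanczik(self):
        self._prune(self.vstar, self.k_urbanczik, self.comp_urbanczik)

    def prune_stdp(self):
        if self.spike_archive is not None:
            self.spike_archive.prune(self.k_stdp)

    # -- compressed access --------------------------------------------------
    def compress_clopath(self, t_new, counters):
        self._compress(self.comp_clopath, self.vltp, t_new, counters,
                       self.prune_clopath)

    def compress_urbanczik(self, t_new, counters):
        self._compress(self.comp_urbanczik, self.vstar, t_new, counters,
                       self.prune_urbanczik)

    def _compress(self, comp, hist, t_new, counters, prune):
        seg = hist.get_segment(comp.t_proc, t_new) if t_new > comp.t_proc else []
        archiving.compress_and_advance(comp, seg, t_new, counters)
        prune()

    def comp_clopath_read(self, t_ref, t_new):
        return archiving.read_and_reset_compressed(self.comp_clopath, t_ref, t_new)

    def comp_urbanczik_read(self, t_ref, t_new):
        return archiving.read_and_reset_compressed(self.comp_urbanczik, t_ref, t_new)

    def monitored_length(self) -> int:
        """Length of the container the complexity model charges as L."""
        lengths = []
        if self.comp_clopath is not None:
            lengths.append(len(self.comp_clopath))
        elif self.vltp is not None and self.k_clopath > 0:
            lengths.append(len(self.vltp))
        if self.comp_urbanczik is not None:
            lengths.append(len(self.comp_urbanczik))
        elif self.vstar is not None and self.k_urbanczik > 0:
            lengths.append(len(self.vstar))
        if self.spike_archive is not None and self.k_stdp > 0:
            lengths.append(len(self.spike_archive))
        return max(lengths, default=0)


# -- connections ------------------------------------------------------------

_RULE_STATE = {
    "stdp": plasticity.STDPSynapseState,
    "clopath": plasticity.ClopathSynapseState,
    "urbanczik": plasticity.UrbanczikSynapseState,
}

_ON_PRE = {
    "stdp": plasticity.stdp_on_pre_event,
    "clopath": plasticity.clopath_on_pre_event,
    "urbanczik": plasticity.urbanczik_on_pre_event,
}

_SLICE = {
    "stdp": plasticity.stdp_slice_update,
    "clopath": plasticity.clopath_slice_update,
    "urbanczik": plasticity.urbanczik_slice_update,
}


@dataclass
class Connection:
    pre: int
    post: int
    delay_steps: int
    rule: str = "static"
    scheme: str = "event_driven"
    weight: float = 1.0              # static weight; plastic rules use state.W
    state: object = None
    port: str | None = None
    index: int = 0
    record: bool = True
    weight_log: list = field(default_factory=list)
    pending: list = field(default_factory=list)   # arrivals for time_driven

    @property
    def w(self) -> float:
        return self.state.W if self.state is not None else self.weight


# -- network ----------------------------------------------------------------

def _named_streams(seed: int, names=("inputs", "soma", "dend", "misc")):
    """Independent named RNG streams spawned from one master seed."""
    idx = {"inputs": 0, "soma": 1, "dend": 2, "misc": 3}
    return {n: np.random.default_rng(np.random.SeedSequence([seed, idx[n]]))
            for n in names}


@dataclass
class SimulationRecord:
    spikes: list = field(default_factory=list)        # (neuron_id, step)
    weight_snapshots: dict = field(default_factory=dict)  # step -> {(pre,post,idx): W}
    counters: InstrumentationCounters = field(default_factory=InstrumentationCounters)
    h_ms: float = 0.1
    T_steps: int = 0

    def spike_times_ms(self):
        return [(nid, s * self.h_ms) for nid, s in self.spikes]


class Network:
    def __init__(self, h_ms: float = 0.1, min_delay_steps: int = 1,
                 seed: int = 0):
        self.clock = SimulationClock(h_ms=h_ms, min_delay_steps=min_delay_steps)
        self.seed = seed
        self.rngs = _named_streams(seed)
        self.neurons: list = []
        self.nodes: list[ArchivingNode | None] = []
        self.connections: list[Connection] = []
        self.in_by_post: dict[int, list[Connection]] = {}
        self.out_by_pre: dict[int, list[Connection]] = {}
        self.counters = InstrumentationCounters()
        self._future_events: dict[int, list[tuple[int, Connection]]] = {}
        self._prepared = False
        self.record = SimulationRecord(h_ms=h_ms)
        self.record_weights_every: int | None = None
        self.default_t_steps: int | None = None

    # -- construction -------------------------------------------------------
    def add_neuron(self, neuron) -> int:
        if self._prepared:
            raise RuntimeError("cannot add neurons after the run started")
        self.neurons.append(neuron)
        self.nodes.append(None)
        return len(self.neurons) - 1

    def connect(self, pre: int, post: int, delay_steps: int = 1,
                rule: str = "static", scheme: str = "event_driven",
                weight: float = 1.0, state=None, port=None,
                record: bool = True) -> Connection:
        if self._prepared:
            raise RuntimeError("cannot connect after the run started")
        if rule not in RULES:
            raise ConfigurationError(f"unknown rule {rule!r}")
        if rule != "static" and scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme {scheme!r}")
        if delay_steps < 1:
            raise ConfigurationError("delay must be at least one step")
        if scheme == "event_driven_compressed" and rule != "static" \
                and delay_steps != 1:
            raise ConfigurationError(
                f"connection {pre}->{post}: the compressed scheme requires "
                f"the delay to equal the simulation step (got "
                f"{delay_steps} steps)")
        if rule == "stdp" and scheme == "event_driven_compressed":
            raise ConfigurationError("STDP has no compressed scheme")
        if rule != "static" and state is None:
            state = _RULE_STATE[rule](W=weight)
        conn = Connection(pre, post, delay_steps, rule, scheme, weight,
                          state, port, index=len(self.connections),
                          record=record)
        self.connections.append(conn)
        self.in_by_post.setdefault(post, []).append(conn)
        self.out_by_pre.setdefault(pre, []).append(conn)
        return conn

    def _node_for(self, post: int) -> ArchivingNode:
        if self.nodes[post] is None:
            self.nodes[post] = ArchivingNode(self.clock.h_ms)
        return self.nodes[post]

    def prepare(self) -> None:
        """Instantiate archiving containers and shifted initial frontiers."""
        if self._prepared:
            return
        self.clock.max_delay_steps = max(
            [c.delay_steps for c in self.connections],
            default=self.clock.min_delay_steps)
        self.clock.max_delay_steps = max(self.clock.max_delay_steps,
                                         self.clock.min_delay_steps)
        for c in self.connections:
            if c.rule == "static":
                continue
            node = self._node_for(c.post)
            post_neuron = self.neurons[c.post]
            if c.rule == "clopath":
                if node.vltp is None:
                    node.vltp = SparseHistory()
                    node.ring = DelayRingBuffer(self.clock.max_delay_steps + 1,
                                                fill=0.0)
                    if isinstance(post_neuron, AdexClopathNeuron):
                        node.theta_minus = post_neuron.params.theta_minus_mV
                        fill = post_neuron.params.E_L_mV
                        node.ring = DelayRingBuffer(
                            self.clock.max_delay_steps + 1, fill=fill)
                    elif isinstance(post_neuron, ScriptedNeuron):
                        node.theta_minus = post_neuron.theta_minus
                if c.scheme == "event_driven_compressed":
                    if node.comp_clopath is None:
                        node.comp_clopath = CompressedHistory(
                            c.state.tau_s_ms, self.clock.h_ms)
                else:
                    node.k_clopath += 1
            elif c.rule == "urbanczik":
                if node.vstar is None:
                    node.vstar = ContinuousHistory()
                if c.scheme == "event_driven_compressed":
                    if node.comp_urbanczik is None:
                        node.comp_urbanczik = CompressedHistory(
                            c.state.tau_s_ms, self.clock.h_ms,
                            tau_k_ms=c.state.tau_kappa_ms)
                else:
                    node.k_urbanczik += 1
            elif c.rule == "stdp":
                if node.spike_archive is None:
                    node.spike_archive = SpikeArchive(
                        c.state.tau_minus_ms, self.clock.h_ms)
                node.k_stdp += 1
            if c.rule == "stdp":
                c.state.t_ls = 0
                c.state.t_proc = -c.delay_steps
            # shifted initial frontiers: virtual last spike at step 0
            if c.rule in ("clopath", "urbanczik"):
                c.state.t_ls = 0
                c.state.t_ref = -c.delay_steps
                c.state.t_proc = -c.delay_steps
                if c.scheme == "event_driven_compressed":
                    comp = (self.nodes[c.post].comp_clopath if c.rule == "clopath"
                            else self.nodes[c.post].comp_urbanczik)
                    comp.register_key(c.state.t_ref)
        self._prepared = True

    # -- dynamics -----------------------------------------------------------
    def _schedule(self, source: int, step: int) -> None:
        for c in self.out_by_pre.get(source, []):
            arrival = step + c.delay_steps
            self._future_events.setdefault(arrival, []).append((source, c))

    def _deliver(self, conn: Connection, arrival: int) -> None:
        self.neurons[conn.post].deliver(arrival, conn.w, conn.port)

    def _log_weight(self, conn: Connection, arrival: int) -> None:
        if conn.record:
            conn.weight_log.append((arrival, conn.w))

    def dispatch_spike(self, event: SpikeEvent, conn: Connection) -> None:
        """Route one spike through an event-driven synapse (update, log,
        deliver).  Static synapses only deliver and are not counted."""
        arrival = event.step + conn.delay_steps
        if conn.rule == "static":
            self._deliver(conn, arrival)
            return
        self.counters.M += 1
        node = self.nodes[conn.post]
        _ON_PRE[conn.rule](conn.state, node, arrival, conn.delay_steps,
                           conn.scheme, self.counters)
        self._log_weight(conn, arrival)
        self._deliver(conn, arrival)

    def run(self, t_steps: int) -> SimulationRecord:
        """Advance ``t_steps`` steps in min_delay slices (resumable).

        ``t_steps`` not a multiple of min_delay is rounded up with a
        warning.  Within each slice: due events are dispatched first
        (their histories end before the slice), time-driven synapses get
        their one imposed call, then neurons step forward.
        """
        self.prepare()
        md = self.clock.min_delay_steps
        if t_steps % md:
            t_steps = ((t_steps // md) + 1) * md
            warnings.warn(f"t_steps rounded up to {t_steps} "
                          f"(multiple of min_delay)")
        end = self.clock.step + t_steps
        while self.clock.step < end:
            s0 = self.clock.step
            s1 = s0 + md
            # 1) event-driven deliveries due in this slice, canonical order
            due = []
            for a in range(s0 + 1, s1 + 1):
                for src, conn in self._future_events.pop(a, []):
                    due.append((a, src, conn))
            due.sort(key=lambda e: (e[0], e[1], e[2].index))
            for a, src, conn in due:
                if conn.rule != "static" and conn.scheme == "time_driven":
                    conn.pending.append(a)
                else:
                    self.dispatch_spike(SpikeEvent(src, a - conn.delay_steps),
                                        conn)
            # 2) one imposed call per time-driven synapse per slice
            for conn in self.connections:
                if conn.rule == "static" or conn.scheme != "time_driven":
                    continue
                self.counters.M += 1
                node = self.nodes[conn.post]
                upd = _SLICE[conn.rule]
                for a in conn.pending:
                    upd(conn.state, node, a, conn.delay_steps, [a],
                        self.counters)
                    self._log_weight(conn, a)
                    self._deliver(conn, a)
                conn.pending.clear()
                upd(conn.state, node, s1, conn.delay_steps, [], self.counters)
            # 3) neurons step forward through the slice
            for step in range(s0 + 1, s1 + 1):
                for nid, neuron in enumerate(self.neurons):
                    spiked = neuron.advance(step, self.nodes[nid],
                                            self.counters, self.rngs)
                    if spiked:
                        self.record.spikes.append((nid, step))
                        self._schedule(nid, step)
                for node in self.nodes:
                    if node is not None:
                        self.counters.L_max = max(self.counters.L_max,
                                                  node.monitored_length())
                if self.record_weights_every \
                        and step % self.record_weights_every == 0:
                    self.record.weight_snapshots[step] = {
                        (c.pre, c.post, c.index): c.w
                        for c in self.connections if c.rule != "static"}
            self.clock.step = s1
        self.record.counters = self.counters
        self.record.T_steps = self.clock.step
        return self.record


# -- config-driven construction --------------------------------------------

def _steps_of(ms: float, h_ms: float, what: str) -> int:
    n = ms / h_ms
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"{what} = {ms} ms is not an integer multiple of h = {h_ms} ms")
    return int(round(n))


def build_network(config: dict) -> Network:
    """Construct a network from a canonicalized config mapping.

    Sections: ``engine`` (h_ms, min_delay_ms, seed), ``neurons`` (list of
    {model, params...}), ``connections`` (list of {pre, post, delay_ms,
    rule, scheme, weight, params}).  Construction is deterministic given
    content + seed and independent of key order.
    """
    from .neurons import inhomogeneous_poisson_train  # local, avoids cycle noise

    eng = config.get("engine", {})
    h = float(eng.get("h_ms", 0.1))
    md = _steps_of(float(eng.get("min_delay_ms", h)), h, "min_delay")
    seed = int(eng.get("seed", 0))
    net = Network(h_ms=h, min_delay_steps=md, seed=seed)
    t_steps = _steps_of(float(eng.get("T_ms", 0.0)), h, "T") \
        if "T_ms" in eng else None
    net.default_t_steps = t_steps

    for spec in config.get("neurons", []):
        model = spec.get("model", "spike_source")
        params = dict(spec.get("params", {}))
        if model == "spike_source":
            if "spike_times_ms" in spec:
                steps = [_steps_of(t, h, "spike time")
                         for t in spec["spike_times_ms"]]
            elif "rate_hz" in spec:
                if t_steps is None:
                    raise ConfigurationError(
                        "poisson source needs engine.T_ms")
                steps = inhomogeneous_poisson_train(
                    float(spec["rate_hz"]) / 1000.0, t_steps, h,
                    net.rngs["inputs"])
            else:
                steps = spec.get("spike_steps", [])
            net.add_neuron(SpikeSourceNeuron(steps))
        elif model == "adex_clopath":
            net.add_neuron(AdexClopathNeuron(
                ClopathNeuronParams(**params), h_ms=h))
        elif model == "two_compartment":
            net.add_neuron(TwoCompartmentNeuron(
                TwoCompartmentParams(**params),
                variant=spec.get("variant", "rate")))
        elif model == "scripted":
            net.add_neuron(ScriptedNeuron(
                vltp=spec.get("vltp"), u_minus=spec.get("u_minus"),
                vstar=spec.get("vstar"),
                spike_steps=spec.get("spike_steps", ())))
        else:
            raise ConfigurationError(f"unknown neuron model {model!r}")

    for spec in config.get("connections", []):
        d = _steps_of(float(spec.get("delay_ms", h)), h, "delay")
        rule = spec.get("rule", "static")
        state = None
        if rule != "static":
            state = _RULE_STATE[rule](**dict(spec.get("params", {})))
            if "weight" in spec:
                state.W = float(spec["weight"])
        net.connect(int(spec["pre"]), int(spec["post"]), d, rule,
                    spec.get("scheme", "event_driven"),
                    float(spec.get("weight", 1.0)), state,
                    spec.get("port"))
    return net
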