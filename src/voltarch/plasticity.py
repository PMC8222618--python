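"""The three plasticity rules and their scheme-specific update paths.

Every rule is written so that the time-driven, event-driven and compressed
schemes traverse the *same* per-step products and differ only in how the
partial sums are associated:

* event-driven: the whole inter-spike segment is integrated in one shot at
  the presynaptic spike;
* time-driven: the synapse advances a partial accumulator once per
  min_delay slice using the exponential-prefactor decomposition
  ``dW(t_ref, t2) = dW(t_ref, t1) + exp(-(t1 - t_ref) h/tau) dW(t1, t2)``;
* compressed: the postsynaptic node advances one such accumulator per
  distinct last-spike time, integrating the raw trace exactly once.

The decomposition is exact, so schemes agree to float re-association
(~1e-15 relative), which is what the cross-scheme equivalence harness
certifies.

Conventions: integer grid steps, forward Euler (weight dependence at
interval start), rectangle rule on the grid, half-open segments
``(t_from, t_to]``, all segment coordinates shifted by the dendritic delay
``d`` (``t_ref = t_LS - d``).  Spikes enter grid sums as indicator / h
(delta of weight one per bin), making rate- and spike-variant prediction
errors commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .neurons import RateFunctionParams, rate_and_sensitivity


def trace_propagate(x: float, tau_ms: float, dt_ms: float) -> float:
    """Exponential synaptic trace advanced analytically by ``dt``."""
    if dt_ms < 0:
        raise ValueError("negative propagation interval")
    return x * math.exp(-dt_ms / tau_ms)


# -- synapse states ---------------------------------------------------------

@dataclass
class STDPSynapseState:
    W: float = 1.0
    x_pre: float = 0.0               # presynaptic trace, 1/ms (tau_plus kernel)
    t_ls: int = 0                    # last presynaptic arrival step
    lambda_plus: float = 0.01
    lambda_minus: float = 0.012
    tau_plus_ms: float = 20.0
    tau_minus_ms: float = 20.0
    weight_dep: str = "additive"     # or "multiplicative"
    w_max: float = 10.0
    t_proc: int = 0                  # read frontier (unshifted; STDP has no V)

    def f_plus(self) -> float:
        if self.weight_dep == "multiplicative":
            return self.lambda_plus * max(self.w_max - self.W, 0.0)
        return self.lambda_plus

    def f_minus(self) -> float:
        if self.weight_dep == "multiplicative":
            return self.lambda_minus * max(self.W, 0.0)
        return self.lambda_minus


@dataclass
class ClopathSynapseState:
    W: float = 1.0
    x_pre: float = 0.0               # presynaptic trace x_bar, 1/ms
    t_ls: int = 0
    A_LTD: float = 14e-5             # 1/mV
    A_LTP: float = 4e-3              # 1/mV^2 (normalized-trace convention)
    tau_s_ms: float = 15.0
    W_min: float = 0.0
    W_max: float = 10.0
    # partial LTP integral for chunked (time-driven) advancing
    P: float = 0.0
    t_ref: int = 0                   # last spike in shifted coords, t_ls - d
    t_proc: int = 0                  # shifted frontier, = t_ref after a spike


@dataclass
class UrbanczikSynapseState:
    W: float = 1.0
    x_pre: float = 0.0
    t_ls: int = 0
    eta: float = 0.1
    tau_s_ms: float = 5.0            # presynaptic trace kernel kappa_s
    tau_kappa_ms: float = 50.0       # plasticity low-pass kernel kappa
    I2_acc: float = 0.0              # running I2(0, t_LS)
    sign_class: str = "excitatory"   # or "inhibitory"; fixed for life
    I1_p: float = 0.0
    I2_p: float = 0.0
    t_ref: int = 0
    t_proc: int = 0


def apply_weight_bounds(state) -> None:
    """Dale rectification at zero and, where defined, hard weight bounds."""
    if isinstance(state, UrbanczikSynapseState):
        if state.sign_class == "excitatory":
            state.W = max(state.W, 0.0)
        elif state.sign_class == "inhibitory":
            state.W = min(state.W, 0.0)
        else:
            raise ValueError(f"unknown sign class {state.sign_class!r}")
    elif isinstance(state, ClopathSynapseState):
        state.W = min(max(state.W, state.W_min), state.W_max)
    elif isinstance(state, STDPSynapseState):
        state.W = min(max(state.W, 0.0), state.w_max)


# -- shared segment algebra -------------------------------------------------

def _exp_weighted_sum(segment, t_ref: int, tau_ms: float, h_ms: float) -> float:
    """Rectangle-rule sum  Sigma exp(-(t - t_ref) h/tau) * value * h."""
    s = 0.0
    for e in segment:
        if e.t_step <= t_ref:
            raise ValueError(f"segment entry {e.t_step} not after t_ref {t_ref}")
        s += math.exp(-(e.t_step - t_ref) * h_ms / tau_ms) * e.value * h_ms
    return s


# -- STDP -------------------------------------------------------------------

def stdp_update_at_spike(state: STDPSynapseState, post_archive, t_s: int,
                         h_ms: float, d: int = 0, counters=None) -> None:
    """All-to-all pair STDP update at a presynaptic spike arrival.

    Facilitation at every postsynaptic spike since the last processed step
    (presynaptic trace propagated analytically to the post-spike time),
    then depression at ``t_s`` against the post trace; finally the pre
    trace is incremented by ``1/tau_plus``.  Post spikes are read in
    dendritic-delay-shifted coordinates ``(.., t_s - d]`` — with
    min_delay-batched delivery the archive is complete only up to the
    current slice start, which the shift guarantees.
    """
    _stdp_advance(state, post_archive, t_s - d, h_ms, counters)
    state.W -= state.f_minus() * post_archive.trace_at(t_s - d)
    state.x_pre = trace_propagate(
        state.x_pre, state.tau_plus_ms, (t_s - state.t_ls) * h_ms)
    state.x_pre += 1.0 / state.tau_plus_ms
    apply_weight_bounds(state)
    state.t_ls = t_s
    state.t_proc = t_s - d


def _stdp_advance(state: STDPSynapseState, post_archive, t_to: int,
                  h_ms: float, counters=None) -> None:
    """Facilitation terms for post spikes in ``(t_proc, t_to]``."""
    if t_to < state.t_proc:
        raise ValueError("STDP advance moving backwards")
    seg = post_archive.get_segment(state.t_proc, t_to)
    for e in seg:
        x_at = trace_propagate(
            state.x_pre, state.tau_plus_ms, (e.t_step - state.t_ls) * h_ms)
        state.W += state.f_plus() * x_at
        if counters is not None:
            counters.C += 1
    state.t_proc = t_to


# -- Clopath ----------------------------------------------------------------

def clopath_ltd_at_spike(state: ClopathSynapseState, u_minus_delayed: float,
                         theta_minus: float) -> float:
    """Depression increment at one presynaptic spike (threshold-linear)."""
    return -state.A_LTD * max(u_minus_delayed - theta_minus, 0.0)


def clopath_ltp_integrate_segment(segment, x_pre_at_ls_plus: float, t_ref: int,
                                  tau_s_ms: float, A_LTP: float, h_ms: float
                                  ) -> float:
    """One-shot LTP integral over a sparse V*_LTP segment.

    ``t_ref`` is the last presynaptic spike in shifted (dendritic-delay)
    coordinates; the presynaptic trace enters through its post-increment
    value at the last spike times the exponential kernel offset.
    """
    return A_LTP * x_pre_at_ls_plus * _exp_weighted_sum(
        segment, t_ref, tau_s_ms, h_ms)


def _clopath_advance(state: ClopathSynapseState, node, t_to: int,
                     counters=None) -> None:
    """Advance the partial LTP integral to shifted step ``t_to``."""
    if t_to < state.t_proc:
        raise ValueError("Clopath advance moving backwards")
    if t_to == state.t_proc:
        return
    seg = node.vltp.get_segment(state.t_proc, t_to)
    chunk = _exp_weighted_sum(seg, state.t_proc, state.tau_s_ms, node.h_ms)
    state.P += math.exp(
        -(state.t_proc - state.t_ref) * node.h_ms / state.tau_s_ms) * chunk
    if counters is not None:
        counters.C += len(seg)
    state.t_proc = t_to
    node.prune_clopath()


def _clopath_finalize(state: ClopathSynapseState, node, t_s: int, d: int,
                      p_ltp_sum: float) -> None:
    """Apply LTP + LTD + trace increment + clip at arrival ``t_s``."""
    state.W += state.A_LTP * state.x_pre * p_ltp_sum
    state.W += clopath_ltd_at_spike(
        state, node.ring.read(t_s, d), node.theta_minus)
    state.x_pre = trace_propagate(
        state.x_pre, state.tau_s_ms, (t_s - state.t_ls) * node.h_ms)
    state.x_pre += 1.0 / state.tau_s_ms
    apply_weight_bounds(state)
    state.t_ls = t_s
    state.t_ref = t_s - d
    state.t_proc = t_s - d
    state.P = 0.0


def clopath_on_pre_event(state: ClopathSynapseState, node, t_s: int, d: int,
                         scheme: str, counters=None) -> None:
    """Event-driven / compressed Clopath update at a presynaptic arrival."""
    t_ref = state.t_ref
    if scheme == "event_driven":
        seg = node.vltp.get_segment(t_ref, t_s - d)
        p = _exp_weighted_sum(seg, t_ref, state.tau_s_ms, node.h_ms)
        if counters is not None:
            counters.C += len(seg)
        node.prune_clopath()
    elif scheme == "event_driven_compressed":
        node.compress_clopath(t_s - d, counters)
        p = node.comp_clopath_read(t_ref, t_s - d)[0]
    else:
        raise ValueError(f"clopath_on_pre_event got scheme {scheme!r}")
    _clopath_finalize(state, node, t_s, d, p)


def clopath_slice_update(state: ClopathSynapseState, node, t_slice_end: int,
                         d: int, arrivals, counters=None) -> None:
    """Time-driven per-slice call: advance the partial integral and fold in
    any presynaptic arrivals of this slice, in order."""
    for a in arrivals:
        _clopath_advance(state, node, a - d, counters)
        _clopath_finalize(state, node, a, d, state.P)
    _clopath_advance(state, node, t_slice_end - d, counters)


# -- Urbanczik-Senn ---------------------------------------------------------

def urbanczik_error_signal(spike_indicator: int, v_hat: float,
                           rate_params: RateFunctionParams, h_ms: float,
                           variant: str = "rate",
                           rng: np.random.Generator | None = None) -> float:
    """Prediction error V* on the grid.

    rate variant:  ``(s/h - phi(V_hat)) * h(V_hat)`` — somatic spikes
    against the dendritic rate prediction.  spike variant: the rate
    prediction is replaced by a Poisson sample ``s_dend`` with rate
    ``phi(V_hat)``, so the error compares somatic and dendritic spikes;
    its expectation over the dendritic sampling equals the rate variant.
    """
    phi, h_v = rate_and_sensitivity(v_hat, rate_params)
    if variant == "rate":
        return (spike_indicator / h_ms - phi) * h_v
    if variant == "spike":
        if rng is None:
            raise ValueError("spike variant needs an rng stream")
        s_dend = int(rng.random() < min(phi * h_ms, 1.0))
        return (spike_indicator - s_dend) / h_ms * h_v
    raise ValueError(f"unknown variant {variant!r}")


def urbanczik_compute_I1_I2(segment, x_pre_at_ls_plus: float, t_ref: int,
                            t_s: int, tau_s_ms: float, tau_kappa_ms: float,
                            h_ms: float) -> tuple[float, float]:
    """One-shot I1/I2 pair over a continuous V* segment ``(t_ref, t_s]``.

    With ``g(t) = V*(t) x_pre exp(-(t - t_ref) h/tau_s)``:
    ``I1 = Sigma g h`` and ``I2 = Sigma exp(-(t_s - t) h/tau_kappa) g h``.
    """
    i1 = 0.0
    i2 = 0.0
    for e in segment:
        if e.t_step <= t_ref:
            raise ValueError(f"segment entry {e.t_step} not after t_ref {t_ref}")
        g = e.value * x_pre_at_ls_plus \
            * math.exp(-(e.t_step - t_ref) * h_ms / tau_s_ms) * h_ms
        i1 += g
        i2 += math.exp(-(t_s - e.t_step) * h_ms / tau_kappa_ms) * g
    return i1, i2


def urbanczik_apply_update(state: UrbanczikSynapseState, i1: float, i2: float,
                           dt_ms: float) -> None:
    """Weight update from the analytically decomposed double integral.

    ``dW = eta [I1 - I2 + I2_acc (1 - exp(-dt/tau_kappa))]``; the running
    accumulator is then overwritten,
    ``I2_acc <- exp(-dt/tau_kappa) I2_acc + I2``, and Dale's principle is
    enforced by rectification at zero.
    """
    decay = math.exp(-dt_ms / state.tau_kappa_ms)
    state.W += state.eta * (i1 - i2 + state.I2_acc * (1.0 - decay))
    state.I2_acc = decay * state.I2_acc + i2
    apply_weight_bounds(state)


def _urbanczik_advance(state: UrbanczikSynapseState, node, t_to: int,
                       counters=None) -> None:
    """Advance the per-synapse (I1, I2) partials to shifted step ``t_to``.

    I1 obeys the trace-prefactor decomposition; I2 additionally decays
    with ``tau_kappa`` as its right endpoint moves.
    """
    if t_to < state.t_proc:
        raise ValueError("Urbanczik advance moving backwards")
    if t_to == state.t_proc:
        return
    seg = node.vstar.get_segment(state.t_proc, t_to)
    h = node.h_ms
    c1 = 0.0
    c2 = 0.0
    for e in seg:
        g = math.exp(-(e.t_step - state.t_proc) * h / state.tau_s_ms) * e.value * h
        c1 += g
        c2 += math.exp(-(t_to - e.t_step) * h / state.tau_kappa_ms) * g
    if counters is not None:
        counters.C += len(seg)
    pref = math.exp(-(state.t_proc - state.t_ref) * h / state.tau_s_ms)
    state.I1_p += pref * c1
    state.I2_p = state.I2_p * math.exp(-(t_to - state.t_proc) * h / state.tau_kappa_ms) \
        + pref * c2
    state.t_proc = t_to
    node.prune_urbanczik()


def _urbanczik_finalize(state: UrbanczikSynapseState, node, t_s: int, d: int,
                        i1_raw: float, i2_raw: float) -> None:
    """Apply the update at arrival ``t_s``; raw integrals exclude the trace
    amplitude, which multiplies in here."""
    dt_ms = (t_s - state.t_ls) * node.h_ms
    urbanczik_apply_update(state, state.x_pre * i1_raw, state.x_pre * i2_raw,
                           dt_ms)
    state.x_pre = trace_propagate(state.x_pre, state.tau_s_ms, dt_ms)
    state.x_pre += 1.0 / state.tau_s_ms
    state.t_ls = t_s
    state.t_ref = t_s - d
    state.t_proc = t_s - d
    state.I1_p = 0.0
    state.I2_p = 0.0


def urbanczik_on_pre_event(state: UrbanczikSynapseState, node, t_s: int,
                           d: int, scheme: str, counters=None) -> None:
    """Event-driven / compressed Urbanczik-Senn update at an arrival."""
    t_ref = state.t_ref
    if scheme == "event_driven":
        seg = node.vstar.get_segment(t_ref, t_s - d)
        i1, i2 = urbanczik_compute_I1_I2(
            seg, 1.0, t_ref, t_s - d, state.tau_s_ms, state.tau_kappa_ms,
            node.h_ms)
        if counters is not None:
            counters.C += len(seg)
        node.prune_urbanczik()
    elif scheme == "event_driven_compressed":
        node.compress_urbanczik(t_s - d, counters)
        i1, i2 = node.comp_urbanczik_read(t_ref, t_s - d)
    else:
        raise ValueError(f"urbanczik_on_pre_event got scheme {scheme!r}")
    _urbanczik_finalize(state, node, t_s, d, i1, i2)


def urbanczik_slice_update(state: UrbanczikSynapseState, node, t_slice_end: int,
                           d: int, arrivals, counters=None) -> None:
    """Time-driven per-slice call for the Urbanczik-Senn rule."""
    for a in arrivals:
        _urbanczik_advance(state, node, a - d, counters)
        _urbanczik_finalize(state, node, a, d, state.I1_p, state.I2_p)
    _urbanczik_advance(state, node, t_slice_end - d, counters)


def stdp_slice_update(state: STDPSynapseState, node, t_slice_end: int,
                      d: int, arrivals, counters=None) -> None:
    """Time-driven per-slice call for STDP (reads the post spike archive)."""
    for a in arrivals:
        stdp_update_at_spike(state, node.spike_archive, a, node.h_ms, d,
                             counters)
        node.prune_stdp()
    _stdp_advance(state, node.spike_archive, t_slice_end - d, node.h_ms,
                  counters)
    node.prune_stdp()


def stdp_on_pre_event(state: STDPSynapseState, node, t_s: int, d: int,
                      scheme: str, counters=None) -> None:
    if scheme != "event_driven":
        raise ValueError("STDP supports time_driven and event_driven only")
    stdp_update_at_spike(state, node.spike_archive, t_s, node.h_ms, d,
                         counters)
    node.prune_stdp()
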