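"""Protocol generators and verification harnesses.

These are the synthetic study conditions of the package: the spike-pairing
protocol and its frequency sweep, the small excitatory-inhibitory network
with a moving Gaussian input bump, the dendritic-prediction teaching task,
the cross-scheme equivalence harness, and the complexity-counter
experiment whose integer identities certify the M/C/H/L accounting of the
three update schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (AdexClopathNeuron, Network, ScriptedNeuron,
                     SpikeSourceNeuron, TwoCompartmentNeuron)
from .neurons import (ClopathNeuronParams, RateFunctionParams,
                      TwoCompartmentParams, gaussian_profile_rates,
                      inhomogeneous_poisson_train, rate_and_sensitivity)
from .plasticity import (ClopathSynapseState, STDPSynapseState,
                         UrbanczikSynapseState)


class ProtocolError(RuntimeError):
    pass


# -- spike pairing ----------------------------------------------------------

@dataclass
class PairingProtocol:
    """Pre/post pairs at lag ``dt`` (pre before post when positive),
    repeated ``n_pairs`` times at ``f_pair``."""

    dt_ms: float = 10.0
    f_pair_hz: float = 20.0
    n_pairs: int = 5

    def __post_init__(self):
        if abs(self.dt_ms) >= 1000.0 / self.f_pair_hz:
            raise ValueError("pairs interleave: |dt| must be below the "
                             "pairing period")


def _forced_spike_run(protocol: PairingProtocol, pulse_pA: float,
                      rule_state: ClopathSynapseState, scheme: str,
                      neuron_params: ClopathNeuronParams, h_ms: float,
                      w_syn: float):
    h = h_ms
    t0 = int(round(50.0 / h))
    period = int(round(1000.0 / protocol.f_pair_hz / h))
    dt = int(round(protocol.dt_ms / h))
    pre_pulses = [t0 + k * period for k in range(protocol.n_pairs)]
    post_pulses = [p + dt for p in pre_pulses]
    # readout spike long after the last pair flushes the last LTP segment
    # once the filtered potentials have decayed back to rest (no LTD there)
    readout = max(pre_pulses + post_pulses) + int(round(300.0 / h))
    t_end = readout + 10

    net = Network(h_ms=h, min_delay_steps=1, seed=0)
    pre = net.add_neuron(AdexClopathNeuron(
        neuron_params, I_ext={s: pulse_pA for s in pre_pulses + [readout]},
        h_ms=h))
    post = net.add_neuron(AdexClopathNeuron(
        neuron_params, I_ext={s: pulse_pA for s in post_pulses}, h_ms=h))
    import copy
    net.connect(pre, post, 1, "clopath", scheme, weight=w_syn,
                state=copy.deepcopy(rule_state))
    net.run(t_end)
    pre_spikes = [s for nid, s in net.record.spikes if nid == pre]
    post_spikes = [s for nid, s in net.record.spikes if nid == post]
    return net, pre_spikes, post_spikes, pre_pulses + [readout], post_pulses


def spike_pairing_experiment(protocol: PairingProtocol,
                             neuron_params: ClopathNeuronParams | None = None,
                             rule_state: ClopathSynapseState | None = None,
                             scheme: str = "event_driven",
                             h_ms: float = 0.1,
                             w_syn: float = 1.0) -> float:
    """Relative weight change W_end / W_0 after the pairing protocol.

    Spikes are forced with brief suprathreshold current pulses; the pulse
    amplitude is auto-calibrated (doubled from a safe start) until every
    pulse elicits exactly one spike at the pulse step.
    """
    neuron_params = neuron_params or ClopathNeuronParams()
    rule_state = rule_state or ClopathSynapseState(W=1.0, W_max=10.0)
    w0 = rule_state.W
    pulse = 1.0e5
    for _ in range(8):
        net, pre_s, post_s, pre_expect, post_expect = _forced_spike_run(
            protocol, pulse, rule_state, scheme, neuron_params, h_ms, w_syn)
        if pre_s == pre_expect and post_s == post_expect:
            conn = net.connections[0]
            return conn.state.W / w0
        pulse *= 2.0
    raise ProtocolError(
        f"forcing failed: expected pre spikes at {pre_expect}, got {pre_s}; "
        f"post at {post_expect}, got {post_s}")


def frequency_sweep(freqs_hz=(10.0, 20.0, 30.0, 40.0, 50.0),
                    dts_ms=(10.0, -10.0), scheme: str = "event_driven",
                    **kwargs) -> dict[float, list[float]]:
    """Pairing-frequency curves W_end/W_0, one per lag."""
    return {dt: [spike_pairing_experiment(
        PairingProtocol(dt_ms=dt, f_pair_hz=f), scheme=scheme, **kwargs)
        for f in freqs_hz] for dt in dts_ms}


# -- E-I network fixture ----------------------------------------------------

def build_ei_network_fixture(n_e: int = 10, n_i: int = 3, n_p: int = 20,
                             t_steps: int = 10000, seed: int = 0,
                             h_ms: float = 0.1,
                             plastic: bool = True) -> Network:
    """Small all-to-all plastic excitatory network with moving-bump input.

    ``n_p`` Poisson sources carry a Gaussian rate profile over source
    index whose center jumps every 100 ms; each excitatory neuron receives
    a topographic window of the sources, so the moving bump co-activates
    neighbouring neurons.  Source->E and E->E connections are
    Clopath-plastic, inhibition is static.  With ``plastic=False`` all
    learning amplitudes are zero, so the raster is identical to the
    plastic build at the initial weights (the zero-learning-rate method
    for comparing schemes and rules on the same network state).
    """
    net = Network(h_ms=h_ms, min_delay_steps=1, seed=seed)
    rates = gaussian_profile_rates(n_p, t_steps, h_ms,
                                   peak_rate_per_ms=0.1, sigma_sources=3.0,
                                   recenter_every_ms=100.0,
                                   rng=net.rngs["inputs"])
    p_ids = [net.add_neuron(SpikeSourceNeuron(
        inhomogeneous_poisson_train(rates[j], t_steps, h_ms,
                                    net.rngs["inputs"])))
        for j in range(n_p)]
    e_ids = [net.add_neuron(AdexClopathNeuron(h_ms=h_ms))
             for _ in range(n_e)]
    i_ids = [net.add_neuron(AdexClopathNeuron(h_ms=h_ms))
             for _ in range(n_i)]

    def clopath_state(w):
        # reduced LTP amplitude: the homeostatic regulation that balances
        # potentiation in long network runs is out of scope, so the fixture
        # uses a fixed amplitude that keeps weights off their bounds
        a_ltd = 14e-5 if plastic else 0.0
        a_ltp = 2e-4 if plastic else 0.0
        return ClopathSynapseState(W=w, A_LTD=a_ltd, A_LTP=a_ltp, W_min=0.0,
                                   W_max=6.0)

    rf_half = 3    # receptive-field half width in source indices
    for k, e in enumerate(e_ids):
        center = k * n_p / n_e
        for j, pid in enumerate(p_ids):
            dist = min(abs(j - center), n_p - abs(j - center))
            if dist <= rf_half:
                net.connect(pid, e, 1, "clopath", "event_driven",
                            state=clopath_state(5.0))
    for a in e_ids:
        for b in e_ids:
            if a != b:
                net.connect(a, b, 1, "clopath", "event_driven",
                            state=clopath_state(1.0))
        for i in i_ids:
            net.connect(a, i, 1, "static", weight=2.0)
    for i in i_ids:
        for e in e_ids:
            net.connect(i, e, 1, "static", weight=-4.0)
    net.ei_groups = {"P": p_ids, "E": e_ids, "I": i_ids}
    return net


def ei_weight_matrix(net: Network) -> np.ndarray:
    """E->E weight matrix (zero diagonal) of the fixture network."""
    e_ids = net.ei_groups["E"]
    pos = {nid: k for k, nid in enumerate(e_ids)}
    m = np.zeros((len(e_ids), len(e_ids)))
    for c in net.connections:
        if c.rule == "clopath" and c.pre in pos and c.post in pos:
            m[pos[c.pre], pos[c.post]] = c.state.W
    return m


# -- Urbanczik-Senn teaching task ------------------------------------------

def teaching_conductances(t_steps: int, h_ms: float,
                          params: TwoCompartmentParams,
                          u_mean_mV: float = -60.0, u_amp_mV: float = 5.0,
                          g_total_nS: float = 60.0):
    """Sinusoidal teaching conductances realizing a target potential.

    Solves the conductance mixture for ``g_E(t)`` at fixed total teaching
    conductance so the matching potential
    ``U_M = (g_L E_L + g_E E_E + g_I E_I) / (g_L + g_E + g_I)``
    is ``u_mean + u_amp * sin(2 pi t / T)``.  Returns (g_E, g_I, U_M)
    arrays over steps 1..t_steps.
    """
    p = params
    t = np.arange(1, t_steps + 1) * h_ms
    u_m = u_mean_mV + u_amp_mV * np.sin(2 * np.pi * t / (t_steps * h_ms))
    g_l = p.g_L_soma_nS
    g_e = ((g_l + g_total_nS) * u_m - g_l * p.E_L_mV - g_total_nS * p.E_I_mV) \
        / (p.E_E_mV - p.E_I_mV)
    g_i = g_total_nS - g_e
    if np.any(g_e < 0) or np.any(g_i < 0):
        raise ValueError("target potential not realizable with non-negative "
                         "teaching conductances")
    return g_e, g_i, u_m


def urbanczik_teaching_task(pattern_period_ms: float = 100.0,
                            n_reps: int = 60, variant: str = "rate",
                            seed: int = 0, n_inputs: int = 100,
                            frac_exc: float = 0.6, input_rate_hz: float = 15.0,
                            eta: float = 300.0, scheme: str = "event_driven",
                            h_ms: float = 0.1,
                            u_amp_mV: float = 5.0,
                            return_network: bool = False):
    """Loss curve of the dendritic-prediction task, one value per repetition.

    A Poisson spike pattern over ``n_inputs`` afferents is drawn once and
    frozen, then repeated; the soma receives sinusoidal teaching
    conductances.  The per-repetition loss is the time-averaged squared
    rate error ``(phi(U) - phi(U_M))^2`` against the conductance-implied
    matching potential U_M.
    """
    period = int(round(pattern_period_ms / h_ms))
    net = Network(h_ms=h_ms, min_delay_steps=1, seed=seed)
    params = TwoCompartmentParams()
    g_e, g_i, u_m = teaching_conductances(period, h_ms, params,
                                          u_amp_mV=u_amp_mV)
    post = net.add_neuron(TwoCompartmentNeuron(
        params, g_E=g_e, g_I=g_i, variant=variant, record_potentials=True))
    pattern_rng = net.rngs["inputs"]
    n_exc = int(round(frac_exc * n_inputs))
    for j in range(n_inputs):
        one_period = inhomogeneous_poisson_train(
            input_rate_hz / 1000.0, period, h_ms, pattern_rng)
        tiled = np.concatenate(
            [one_period + r * period for r in range(n_reps)])
        pre = net.add_neuron(SpikeSourceNeuron(tiled))
        exc = j < n_exc
        w0 = pattern_rng.uniform(5.0, 15.0) * (1.0 if exc else -1.0)
        net.connect(pre, post, 1, "urbanczik", scheme,
                    state=UrbanczikSynapseState(
                        W=w0, eta=eta,
                        sign_class="excitatory" if exc else "inhibitory"))
    neuron = net.neurons[post]
    phi_m = np.array([rate_and_sensitivity(u, params.rate)[0] for u in u_m])
    losses = np.empty(n_reps)
    for r in range(n_reps):
        net.run(period)
        u = np.array(neuron.u_log)
        neuron.u_log.clear()
        phi_u = np.array([rate_and_sensitivity(x, params.rate)[0] for x in u])
        losses[r] = np.mean((phi_u - phi_m) ** 2)
    if return_network:
        return losses, net
    return losses


# -- cross-scheme equivalence ----------------------------------------------

def frozen_clopath_traces(t_steps: int, rng: np.random.Generator):
    """Synthetic frozen postsynaptic trajectories for the Clopath rule:
    a sparse burst-like LTP signal and a wandering filtered potential."""
    vltp = np.zeros(t_steps)
    n_bursts = max(1, t_steps // 250)
    for c in rng.choice(np.arange(20, t_steps - 25), n_bursts, replace=False):
        vltp[c:c + 20] = rng.uniform(0.5, 40.0, 20)
    u_minus = -70.6 + np.cumsum(rng.normal(0, 0.08, t_steps))
    return vltp, u_minus


def frozen_urbanczik_traces(t_steps: int, rng: np.random.Generator,
                            rate_params: RateFunctionParams | None = None,
                            h_ms: float = 0.1):
    """Synthetic frozen prediction-error trajectory: a smooth dendritic
    potential, Poisson somatic spikes at its predicted rate, and the
    resulting V* per step."""
    rp = rate_params or RateFunctionParams()
    v_hat = -58.0 + np.cumsum(rng.normal(0, 0.15, t_steps))
    v_hat = np.clip(v_hat, -75.0, -45.0)
    vstar = np.empty(t_steps)
    for i, v in enumerate(v_hat):
        phi, h_v = rate_and_sensitivity(v, rp)
        s = int(rng.random() < phi * h_ms)
        vstar[i] = (s / h_ms - phi) * h_v
    return vstar


def scheme_equivalence_check(rule: str, seed: int, t_steps: int = 2000,
                             k: int = 20, h_ms: float = 0.1,
                             rate_hz: float = 50.0) -> float:
    """Max relative weight deviation across legal schemes for one rule.

    Identical frozen input spike trains and postsynaptic trajectories are
    run through every legal scheme; the deviation is taken over all
    synapses and all presynaptic spike times against the event-driven
    reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    trains = [inhomogeneous_poisson_train(rate_hz / 1000.0, t_steps - 2,
                                          h_ms, rng) for _ in range(k)]
    if rule == "clopath":
        vltp, u_minus = frozen_clopath_traces(t_steps, rng)
        post_factory = lambda: ScriptedNeuron(vltp=vltp, u_minus=u_minus,
                                              theta_minus=-70.6)
        make_state = lambda: ClopathSynapseState(W=1.0, W_max=100.0)
        schemes = ("event_driven", "time_driven", "event_driven_compressed")
    elif rule == "urbanczik":
        vstar = frozen_urbanczik_traces(t_steps, rng)
        post_factory = lambda: ScriptedNeuron(vstar=vstar)
        make_state = lambda: UrbanczikSynapseState(W=1.0, eta=1.0)
        schemes = ("event_driven", "time_driven", "event_driven_compressed")
    elif rule == "stdp":
        post_spikes = inhomogeneous_poisson_train(rate_hz / 1000.0,
                                                  t_steps - 2, h_ms, rng)
        post_factory = lambda: ScriptedNeuron(spike_steps=post_spikes)
        make_state = lambda: STDPSynapseState(W=1.0)
        schemes = ("event_driven", "time_driven")
    elif rule == "static":
        post_factory = lambda: ScriptedNeuron()
        make_state = None
        schemes = ("event_driven", "time_driven")
    else:
        raise ValueError(f"unknown rule {rule!r}")

    def run(scheme):
        net = Network(h_ms=h_ms, min_delay_steps=1, seed=seed)
        post = net.add_neuron(post_factory())
        for tr in trains:
            pre = net.add_neuron(SpikeSourceNeuron(tr))
            if rule == "static":
                net.connect(pre, post, 1, "static", weight=1.0)
            else:
                net.connect(pre, post, 1, rule, scheme, state=make_state())
        net.run(t_steps)
        return net

    ref = run(schemes[0])
    dev = 0.0
    for scheme in schemes[1:]:
        other = run(scheme)
        for c_ref, c in zip(ref.connections, other.connections):
            if c_ref.rule == "static":
                if c_ref.w != c.w:
                    dev = max(dev, abs(c_ref.w - c.w))
                continue
            assert [x[0] for x in c_ref.weight_log] == \
                [x[0] for x in c.weight_log], "update times diverged"
            wa = np.array([x[1] for x in c_ref.weight_log])
            wb = np.array([x[1] for x in c.weight_log])
            if len(wa):
                dev = max(dev, float(np.max(
                    np.abs(wa - wb) / (np.abs(wa) + 1e-12))))
    return dev


# -- complexity-counter experiment ------------------------------------------

@dataclass
class CounterExperimentSpec:
    """Homogeneous-firing complexity probe: in-degree K, inter-spike
    interval I (steps), T measured steps, arrival phasing, scheme."""

    K: int = 100
    I_steps: int = 10
    T_steps: int = 1000
    phase: str = "synchronous"        # or "spread"
    scheme: str = "event_driven"

    def __post_init__(self):
        if self.T_steps % self.I_steps:
            raise ValueError("T must be a multiple of I")
        if self.phase == "spread" and self.K > self.I_steps:
            raise ValueError("spread phases need K <= I distinct bins")


def counter_experiment(spec: CounterExperimentSpec, seed: int = 0,
                       h_ms: float = 0.1):
    """Measured instrumentation counters under homogeneous periodic firing.

    The continuous-history (Urbanczik-Senn) rule is used, delay = h,
    min_delay = h.  Arrivals fall at exact multiples of I inside the
    measurement window; one warmup interval is excluded (startup
    transient — the complexity formulas are asymptotic per-T counts).
    """
    d = 1
    warm_intervals = 1 if spec.phase == "synchronous" else 2
    warm = warm_intervals * spec.I_steps
    total = warm + spec.T_steps
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    vstar = rng.normal(0.0, 0.05, total)
    net = Network(h_ms=h_ms, min_delay_steps=1, seed=seed)
    post = net.add_neuron(ScriptedNeuron(vstar=vstar))
    for j in range(spec.K):
        off = 0 if spec.phase == "synchronous" else (j % spec.I_steps)
        arrivals = np.arange(spec.I_steps + off, total + 1, spec.I_steps)
        emissions = arrivals - d
        pre = net.add_neuron(SpikeSourceNeuron(emissions[emissions > 0]))
        net.connect(pre, post, d, "urbanczik", spec.scheme,
                    state=UrbanczikSynapseState(W=1.0, eta=0.0),
                    record=False)
    net.run(warm)
    before = net.counters.snapshot()
    net.counters.reset_peak()
    net.run(spec.T_steps)
    return net.counters.delta(before)
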