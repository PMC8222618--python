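"""Rule algebra: traces, integral decompositions, weight updates, Dale."""

import math

import numpy as np
import pytest

from voltarch.archiving import ContinuousHistory, SparseHistory, SpikeArchive
from voltarch.neurons import RateFunctionParams, rate_and_sensitivity
from voltarch.plasticity import (ClopathSynapseState, STDPSynapseState,
                                 UrbanczikSynapseState, apply_weight_bounds,
                                 clopath_ltd_at_spike,
                                 clopath_ltp_integrate_segment,
                                 stdp_update_at_spike, trace_propagate,
                                 urbanczik_apply_update,
                                 urbanczik_compute_I1_I2,
                                 urbanczik_error_signal)

H = 0.1


def _hist(values, start=0, sparse=False):
    h = SparseHistory() if sparse else ContinuousHistory()
    for i, v in enumerate(values):
        h.write(start + 1 + i, v)
    return list(h.entries)


class TestTracePropagate:
    def test_zero_interval_is_identity(self):
        assert trace_propagate(0.3, 15.0, 0.0) == 0.3

    def test_closed_form_one_time_constant(self):
        # fresh spike (1/15), propagated one tau: (1/15) e^-1
        x = trace_propagate(0.0, 15.0, 0.0) + 1.0 / 15.0
        assert trace_propagate(x, 15.0, 15.0) == pytest.approx(0.024525,
                                                               abs=1e-6)

    def test_closed_form_equals_exact_exponential_stepping(self):
        x = 1.0 / 15.0
        stepped = x
        for _ in range(150):
            stepped *= math.exp(-H / 15.0)
        assert trace_propagate(x, 15.0, 15.0) == pytest.approx(stepped,
                                                               rel=1e-12)

    def test_semigroup(self):
        x = 0.4
        two = trace_propagate(trace_propagate(x, 10.0, 3.3), 10.0, 4.4)
        assert two == pytest.approx(trace_propagate(x, 10.0, 7.7), rel=1e-12)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            trace_propagate(1.0, 10.0, -1.0)


class TestSTDP:
    def test_single_pair_closed_form(self):
        """One pre spike, one post spike at lag D, readout at a second pre
        spike: potentiation is lambda+ * (1/tau+) * exp(-D/tau+)."""
        arch = SpikeArchive(tau_minus_ms=20.0, h_ms=H)
        s = STDPSynapseState(W=1.0, lambda_plus=0.01, lambda_minus=0.0,
                             t_proc=0)
        stdp_update_at_spike(s, arch, 100, H)       # pre spike, x -> 1/tau+
        arch.set_spiketime(200)                     # post 10 ms later
        w_before = s.W
        stdp_update_at_spike(s, arch, 400, H)       # second pre reads pair
        expect = 0.01 * (1 / 20.0) * math.exp(-10.0 / 20.0)
        assert s.W - w_before == pytest.approx(expect, rel=1e-12)

    def test_depression_against_post_trace(self):
        arch = SpikeArchive(tau_minus_ms=20.0, h_ms=H)
        arch.set_spiketime(100)
        s = STDPSynapseState(W=1.0, lambda_plus=0.0, lambda_minus=0.012,
                             t_proc=150)
        stdp_update_at_spike(s, arch, 200, H)       # pre 10 ms after post
        expect = 0.012 * (1 / 20.0) * math.exp(-10.0 / 20.0)
        assert 1.0 - s.W == pytest.approx(expect, rel=1e-12)

    def test_no_post_spikes_and_empty_trace_changes_nothing(self):
        arch = SpikeArchive(tau_minus_ms=20.0, h_ms=H)
        s = STDPSynapseState(W=1.0)
        stdp_update_at_spike(s, arch, 50, H)
        assert s.W == 1.0

    def test_zero_amplitudes_keep_weight_bitwise_constant(self):
        arch = SpikeArchive(tau_minus_ms=20.0, h_ms=H)
        s = STDPSynapseState(W=0.7312986, lambda_plus=0.0, lambda_minus=0.0)
        for t in range(10, 500, 40):
            arch.set_spiketime(t + 3)
            stdp_update_at_spike(s, arch, t, H)
        assert s.W == 0.7312986


class TestClopathLTD:
    def test_below_threshold_is_zero(self):
        s = ClopathSynapseState(A_LTD=1e-4)
        assert clopath_ltd_at_spike(s, -71.0, -70.6) == 0.0

    def test_direct_evaluation(self):
        s = ClopathSynapseState(A_LTD=1e-4)
        assert clopath_ltd_at_spike(s, -68.6, -70.6) == pytest.approx(-2e-4)

    def test_linearity_above_threshold(self):
        s = ClopathSynapseState(A_LTD=1e-4)
        one = clopath_ltd_at_spike(s, -68.6, -70.6)
        two = clopath_ltd_at_spike(s, -66.6, -70.6)
        assert two == pytest.approx(2 * one)


class TestClopathLTP:
    def test_empty_segment_is_zero(self):
        assert clopath_ltp_integrate_segment([], 0.05, 0, 15.0, 1e-4, H) == 0.0

    def test_single_entry_rectangle_product(self):
        # one entry one step after the reference: A * x * V* * h * e^(-h/tau)
        seg = _hist([4.0], start=0, sparse=True)
        got = clopath_ltp_integrate_segment(seg, 0.05, 0, 15.0, 1e-4, H)
        assert got == pytest.approx(2e-6 * math.exp(-H / 15.0), rel=1e-12)

    def test_entry_at_or_before_reference_rejected(self):
        seg = _hist([4.0], start=0, sparse=True)
        with pytest.raises(ValueError):
            clopath_ltp_integrate_segment(seg, 0.05, 1, 15.0, 1e-4, H)

    def test_segment_integral_equals_per_step_sum(self, rng):
        """One-shot integration equals the sum of per-step contributions
        with the trace propagated step by step (time-driven oracle)."""
        values = np.abs(rng.normal(5.0, 3.0, 200))
        seg = _hist(values, start=10, sparse=True)
        x0, tau_s, a_ltp = 0.05, 15.0, 1e-4
        got = clopath_ltp_integrate_segment(seg, x0, 10, tau_s, a_ltp, H)
        brute = sum(a_ltp * (x0 * math.exp(-(e.t_step - 10) * H / tau_s))
                    * e.value * H for e in seg)
        assert got == pytest.approx(brute, rel=1e-12)


class TestUrbanczikIntegrals:
    def test_zero_signal_gives_zero_pair(self):
        seg = _hist(np.zeros(50))
        assert urbanczik_compute_I1_I2(seg, 0.2, 0, 50, 5.0, 50.0, H) == (0, 0)

    def test_constant_signal_matches_geometric_closed_forms(self):
        n, g0, x0, tau_s, tau_k = 80, 2.0, 1.0, 5.0, 50.0
        seg = _hist(np.full(n, g0))
        i1, i2 = urbanczik_compute_I1_I2(seg, x0, 0, n, tau_s, tau_k, H)
        qs = math.exp(-H / tau_s)
        i1_exp = g0 * x0 * H * qs * (1 - qs**n) / (1 - qs)
        # I2: sum_b exp(-(n-b)H/tk) exp(-bH/ts) = r^n sum (qs/r)^b, r=e^(-H/tk)
        r = math.exp(-H / tau_k)
        q = qs / r
        i2_exp = g0 * x0 * H * (r**n) * q * (1 - q**n) / (1 - q)
        assert i1 == pytest.approx(i1_exp, rel=1e-12)
        assert i2 == pytest.approx(i2_exp, rel=1e-12)

    def test_i2_never_exceeds_i1_for_positive_signal(self, rng):
        seg = _hist(np.abs(rng.normal(1.0, 0.5, 120)))
        i1, i2 = urbanczik_compute_I1_I2(seg, 0.3, 0, 120, 5.0, 50.0, H)
        assert 0 < i2 <= i1


class TestUrbanczikUpdate:
    def test_zero_integrals_zero_accumulator(self):
        s = UrbanczikSynapseState(W=1.0, eta=0.5)
        urbanczik_apply_update(s, 0.0, 0.0, 7.0)
        assert s.W == 1.0 and s.I2_acc == 0.0

    def test_accumulator_release_in_long_interval_limit(self):
        s = UrbanczikSynapseState(W=1.0, eta=0.5, tau_kappa_ms=50.0,
                                  I2_acc=0.8)
        urbanczik_apply_update(s, 0.0, 0.0, 1e9)
        assert s.W == pytest.approx(1.0 + 0.5 * 0.8, rel=1e-9)
        assert s.I2_acc == pytest.approx(0.0, abs=1e-12)

    def test_accumulator_overwrite_rule(self):
        s = UrbanczikSynapseState(W=5.0, eta=0.0, tau_kappa_ms=50.0,
                                  I2_acc=0.5)
        urbanczik_apply_update(s, 0.1, 0.04, 25.0)
        assert s.I2_acc == pytest.approx(
            math.exp(-0.5) * 0.5 + 0.04, rel=1e-12)

    def test_cumulative_updates_equal_nested_double_sum(self, rng):
        """The analytically decomposed per-spike updates reproduce the
        brute-force discretized nested double integral over a 500-step
        synthetic error/trace pair, to 1e-10 relative."""
        n = 500
        tau_s, tau_k, eta = 5.0, 50.0, 0.7
        vstar = rng.normal(0.0, 1.0, n + 1)          # index by step 1..n
        spikes = np.sort(rng.choice(np.arange(2, n), 12, replace=False))

        # exact presynaptic trace on the grid; the bin at a spike step
        # still carries the pre-increment value (the trace is incremented
        # at the end of the update process)
        x = np.zeros(n + 1)
        cur = 0.0
        for t in range(1, n + 1):
            cur *= math.exp(-H / tau_s)
            x[t] = cur
            if t in set(spikes.tolist()):
                cur += 1.0 / tau_s

        # brute force: dW = eta * sum_a sum_{b<a} (1-d) d^(a-1-b) G(b),
        # G(b) = V*(b) x(b) h  (geometric bin weight of the kappa kernel)
        d = math.exp(-H / tau_k)
        g = vstar * x * H
        brute = 0.0
        s_run = 0.0
        for a in range(1, spikes[-1] + 1):
            brute += (1 - d) * s_run
            s_run = d * s_run + g[a]
        brute *= eta

        # implementation: event-driven updates at the spike times
        # (start from a large weight so Dale rectification never engages)
        w0 = 1000.0
        state = UrbanczikSynapseState(W=w0, eta=eta, tau_s_ms=tau_s,
                                      tau_kappa_ms=tau_k,
                                      sign_class="excitatory")
        hist = ContinuousHistory()
        for t in range(1, n + 1):
            hist.write(t, vstar[t])
        t_prev = 0
        x_cur = 0.0
        for t_s in spikes:
            seg = hist.get_segment(t_prev, int(t_s))
            i1, i2 = urbanczik_compute_I1_I2(
                seg, x_cur, t_prev, int(t_s), tau_s, tau_k, H)
            urbanczik_apply_update(state, i1, i2, (t_s - t_prev) * H)
            x_cur = trace_propagate(x_cur, tau_s, (t_s - t_prev) * H) \
                + 1.0 / tau_s
            t_prev = int(t_s)
        assert state.W - w0 == pytest.approx(brute, rel=1e-10)


class TestErrorSignal:
    RP = RateFunctionParams(phi_max_per_ms=0.02, theta_phi_mV=-55.0,
                            slope_mV=5.0)

    def test_rate_variant_direct_evaluation(self):
        rp = RateFunctionParams(phi_max_per_ms=0.02)
        v = rp.theta_phi_mV        # phi = 0.01/ms, h_V = 0.1 mV^-1
        got = urbanczik_error_signal(0, v, rp, H, "rate")
        assert got == pytest.approx((0 - 0.01) * 0.1, rel=1e-12)

    def test_spike_variant_zero_when_spikes_match(self):
        class AlwaysOne:
            def random(self):
                return 0.0   # s_dend = 1 with certainty
        got = urbanczik_error_signal(1, -40.0, self.RP, H, "spike",
                                     AlwaysOne())
        assert got == pytest.approx(0.0, abs=1e-15)

    def test_spike_variant_unbiased_for_rate_variant(self):
        rng = np.random.default_rng(21)
        v = -54.0
        rate = urbanczik_error_signal(0, v, self.RP, H, "rate")
        n = 20000
        draws = np.array([urbanczik_error_signal(0, v, self.RP, H, "spike",
                                                 rng) for _ in range(n)])
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - rate) < 3 * se


class TestWeightBounds:
    def test_dale_rectifies_excitatory_at_zero(self):
        s = UrbanczikSynapseState(W=-0.3, sign_class="excitatory")
        apply_weight_bounds(s)
        assert s.W == 0.0

    def test_dale_rectifies_inhibitory_at_zero(self):
        s = UrbanczikSynapseState(W=0.4, sign_class="inhibitory")
        apply_weight_bounds(s)
        assert s.W == 0.0

    def test_interior_weight_unchanged(self):
        s = UrbanczikSynapseState(W=0.4, sign_class="excitatory")
        apply_weight_bounds(s)
        assert s.W == 0.4

    def test_clopath_clipped_to_box(self):
        s = ClopathSynapseState(W=11.0, W_min=0.0, W_max=10.0)
        apply_weight_bounds(s)
        assert s.W == 10.0
        s.W = -1.0
        apply_weight_bounds(s)
        assert s.W == 0.0
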