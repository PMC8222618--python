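"""Time-driven neuron models and stimulus generators.

Two model neurons are provided:

* :class:`AdexClopathNeuron` — an adaptive exponential integrate-and-fire
  neuron modified for the Clopath rule: after a threshold crossing the
  membrane potential is clamped to ``V_clamp`` for ``t_clamp`` to mimic the
  rectangular shape of an action potential, and the neuron carries two
  built-in low-pass filters of its own voltage (u_minus, u_plus) whose
  thresholded product forms the LTP-driving signal.  Both filtered
  potentials enter plasticity shifted backwards by the spike duration
  ``d_s``.

* :class:`TwoCompartmentNeuron` — a soma + dendrite Poisson-spiking neuron
  for the Urbanczik-Senn rule: the soma fires with probability
  ``phi(U) * h`` per step, the dendritic potential provides the prediction
  ``V_hat`` against which somatic spiking is compared.

Integration is forward Euler on the simulation grid (exact exponential
updates for the linear low-pass filters), matching the piecewise-constant
voltage convention of the synapse-update algebra.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np


def lowpass_update(u_bar: float, v: float, tau_ms: float, h_ms: float) -> float:
    """Exact one-step update of ``tau * du/dt = V - u`` with V held constant."""
    return v + (u_bar - v) * math.exp(-h_ms / tau_ms)


# -- Clopath-variant AdEx neuron ------------------------------------------

@dataclass
class ClopathNeuronParams:
    """AdEx parameters plus the Clopath-specific voltage filters.

    Defaults follow the original voltage-based-rule publication (visual
    cortex set); all values configurable.  ``t_clamp_ms`` must be an
    integer multiple of the step size.
    """

    C_m_pF: float = 281.0
    g_L_nS: float = 30.0
    E_L_mV: float = -70.6
    Delta_T_mV: float = 2.0
    V_T_rest_mV: float = -50.4
    V_T_max_mV: float = -30.4
    tau_VT_ms: float = 50.0
    a_nS: float = 4.0
    b_pA: float = 80.5
    tau_w_ms: float = 144.0
    tau_minus_ms: float = 10.0
    tau_plus_ms: float = 7.0
    theta_minus_mV: float = -70.6
    theta_plus_mV: float = -45.3
    d_s_ms: float = 3.0
    V_clamp_mV: float = 33.0
    t_clamp_ms: float = 2.0
    V_reset_mV: float = -55.6    # depolarized release (afterdepolarization)

    def clamp_steps(self, h_ms: float) -> int:
        n = self.t_clamp_ms / h_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("t_clamp must be an integer multiple of h")
        return int(round(n))

    def d_s_steps(self, h_ms: float) -> int:
        n = self.d_s_ms / h_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("d_s must be an integer multiple of h")
        return int(round(n))


@dataclass
class AdexClopathState:
    V: float
    w_adapt: float
    V_T: float
    u_minus: float
    u_plus: float
    clamp_steps_left: int = 0


def adex_clopath_step(state: AdexClopathState, params: ClopathNeuronParams,
                      I_ext_pA: float, h_ms: float) -> tuple[AdexClopathState, bool]:
    """One forward-Euler step; returns (new state, spiked flag).

    The exponential spike-initiation term is capped at its value at
    ``V = V_T + 10 Delta_T`` to prevent overflow between detection steps;
    a crossing of ``V >= V_T + 2 Delta_T`` triggers the spike: the voltage
    is clamped to ``V_clamp`` for ``t_clamp`` (the detection step included),
    the adaptive threshold jumps to ``V_T_max`` and relaxes with
    ``tau_VT``, and the adaptation current increments by ``b``.  The
    low-pass potentials track V every step, clamped periods included —
    this is what elevates them above their plasticity thresholds around
    spikes.
    """
    p = params
    spiked = False
    if state.clamp_steps_left > 0:
        v_new = p.V_clamp_mV
        clamp_left = state.clamp_steps_left - 1
        if clamp_left == 0:
            v_new = p.V_reset_mV  # release into the afterdepolarized state
    else:
        v_arg = min(state.V, state.V_T + 10.0 * p.Delta_T_mV)
        i_exp = p.g_L_nS * p.Delta_T_mV * math.exp((v_arg - state.V_T) / p.Delta_T_mV)
        dv = (-p.g_L_nS * (state.V - p.E_L_mV) + i_exp
              - state.w_adapt + I_ext_pA) / p.C_m_pF
        v_new = state.V + h_ms * dv
        clamp_left = 0
    w_new = state.w_adapt + h_ms * (
        p.a_nS * (state.V - p.E_L_mV) - state.w_adapt) / p.tau_w_ms
    vt_new = state.V_T + h_ms * (p.V_T_rest_mV - state.V_T) / p.tau_VT_ms

    if clamp_left == 0 and v_new >= vt_new + 2.0 * p.Delta_T_mV:
        spiked = True
        v_new = p.V_clamp_mV
        clamp_left = p.clamp_steps(h_ms)
        vt_new = p.V_T_max_mV
        w_new += p.b_pA

    u_minus_new = lowpass_update(state.u_minus, v_new, p.tau_minus_ms, h_ms)
    u_plus_new = lowpass_update(state.u_plus, v_new, p.tau_plus_ms, h_ms)
    out = AdexClopathState(v_new, w_new, vt_new, u_minus_new, u_plus_new,
                           clamp_left)
    if not (math.isfinite(out.V) and math.isfinite(out.w_adapt)):
        raise FloatingPointError("non-finite AdEx state after step")
    return out, spiked


# -- Two-compartment Poisson neuron ---------------------------------------

@dataclass
class RateFunctionParams:
    """Logistic rate function phi and its logarithmic derivative h.

    ``phi(V) = phi_max / (1 + exp(-(V - theta) / slope))`` in 1/ms; the
    sensitivity is ``h(V) = phi'(V)/phi(V) = (1 - phi/phi_max)/slope``.
    """

    phi_max_per_ms: float = 0.15
    theta_phi_mV: float = -55.0
    slope_mV: float = 5.0


def rate_and_sensitivity(v_mV: float, params: RateFunctionParams) -> tuple[float, float]:
    p = params
    x = -(v_mV - p.theta_phi_mV) / p.slope_mV
    # numerically safe logistic
    if x > 0:
        ex = math.exp(-x)
        phi = p.phi_max_per_ms * ex / (1.0 + ex)
    else:
        phi = p.phi_max_per_ms / (1.0 + math.exp(x))
    h_v = (1.0 - phi / p.phi_max_per_ms) / p.slope_mV
    return phi, h_v


@dataclass
class TwoCompartmentParams:
    """Soma + dendrite leaky compartments with dendro-somatic coupling.

    Round documented values; learning correctness does not hinge on them.
    ``g_D`` couples the dendritic potential into the soma — at the fixed
    point of learning (dendrite matching soma) the coupling term cancels
    and the soma sits at the teaching-conductance mixture potential.
    """

    C_m_soma_pF: float = 300.0
    C_m_dend_pF: float = 300.0
    g_L_soma_nS: float = 30.0
    g_L_dend_nS: float = 30.0
    g_D_nS: float = 60.0
    E_L_mV: float = -70.0
    E_E_mV: float = 0.0
    E_I_mV: float = -75.0
    tau_syn_ms: float = 5.0
    rate: RateFunctionParams = field(default_factory=RateFunctionParams)
    attenuate_prediction: bool = False

    def v_hat(self, v_dend: float) -> float:
        """Dendritic prediction potential (optionally attenuated)."""
        if self.attenuate_prediction:
            g = self.g_D_nS / (self.g_L_soma_nS + self.g_D_nS)
            return self.E_L_mV + g * (v_dend - self.E_L_mV)
        return v_dend


@dataclass
class TwoCompartmentState:
    U: float
    V_dend: float
    I_dend: float = 0.0
    g_E: float = 0.0
    g_I: float = 0.0


def two_compartment_step(state: TwoCompartmentState, params: TwoCompartmentParams,
                         h_ms: float, rng: np.random.Generator
                         ) -> tuple[TwoCompartmentState, bool, tuple[int, float]]:
    """Forward-Euler step; returns (state', spiked, (spike indicator, V_hat)).

    Teaching conductances for this step must already be set on ``state``.
    The soma emits a spike with probability ``min(phi(U) h, 1)``; no reset,
    no refractoriness (pure Poisson readout of the somatic potential).
    """
    p = params
    if state.g_E < 0 or state.g_I < 0:
        raise ValueError("teaching conductances must be non-negative")
    du = (-p.g_L_soma_nS * (state.U - p.E_L_mV)
          + p.g_D_nS * (state.V_dend - state.U)
          + state.g_E * (p.E_E_mV - state.U)
          + state.g_I * (p.E_I_mV - state.U)) / p.C_m_soma_pF
    dv = (-p.g_L_dend_nS * (state.V_dend - p.E_L_mV)
          + state.I_dend) / p.C_m_dend_pF
    u_new = state.U + h_ms * du
    v_new = state.V_dend + h_ms * dv
    i_new = state.I_dend * math.exp(-h_ms / p.tau_syn_ms)
    phi, _ = rate_and_sensitivity(u_new, p.rate)
    p_spike = phi * h_ms
    if p_spike > 1.0:
        warnings.warn("phi(U)*h > 1: somatic rate under-resolved by the grid")
        p_spike = 1.0
    spiked = bool(rng.random() < p_spike)
    out = TwoCompartmentState(u_new, v_new, i_new, state.g_E, state.g_I)
    return out, spiked, (int(spiked), p.v_hat(v_new))


# -- stimulus generators ----------------------------------------------------

def inhomogeneous_poisson_train(rate_per_ms, t_steps: int, h_ms: float,
                                rng: np.random.Generator) -> np.ndarray:
    """Spike steps (1..t_steps) from per-step Bernoulli thinning.

    ``rate_per_ms`` is a scalar, an array of length ``t_steps`` (value for
    steps 1..t_steps), or a callable step -> rate.  Warns when
    ``rate * h`` exceeds 1 (grid under-resolves the rate).
    """
    if callable(rate_per_ms):
        rates = np.array([rate_per_ms(a) for a in range(1, t_steps + 1)], float)
    else:
        rates = np.broadcast_to(np.asarray(rate_per_ms, float), (t_steps,))
    p = rates * h_ms
    if np.any(p > 1.0):
        warnings.warn("rate*h > 1: Poisson train under-resolved by the grid")
        p = np.minimum(p, 1.0)
    hits = rng.random(t_steps) < p
    return np.nonzero(hits)[0] + 1


def gaussian_profile_rates(n_sources: int, t_steps: int, h_ms: float,
                           peak_rate_per_ms: float, sigma_sources: float,
                           recenter_every_ms: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-source, per-step rates with a Gaussian bump over source index.

    The bump's center is redrawn uniformly every ``recenter_every_ms``
    (the moving-stimulus drive of the E-I network experiment).  Returns an
    array of shape (n_sources, t_steps) in 1/ms.
    """
    block = int(round(recenter_every_ms / h_ms))
    idx = np.arange(n_sources)
    rates = np.empty((n_sources, t_steps))
    for start in range(0, t_steps, block):
        center = rng.uniform(0, n_sources)
        dist = np.minimum(np.abs(idx - center), n_sources - np.abs(idx - center))
        profile = peak_rate_per_ms * np.exp(-dist**2 / (2 * sigma_sources**2))
        rates[:, start:start + block] = profile[:, None]
    return rates
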