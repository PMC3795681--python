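"""Pure update rules for one neuron and one synapse.

Every dynamical variable of the network model — membrane potential,
AMPA/NMDA gating, short-term plasticity (u, x), and the adaptation
conductance g_a — is advanced here by small, individually testable
functions.  The network engine applies vectorized equivalents of these
rules; these scalar forms are the reference semantics.

Conventions: spikes take effect on short-term plasticity and adaptation at
the emission time; gating jumps occur one conduction delay later.  Linear
decays use exact exponential factors; the NMDA gating step freezes the
auxiliary rise variable over the step (exponential-Euler), which is exact
in the limit of small steps.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .params import (AdaptationParams, NeuronParams, STPParams, SynapseParams)


@dataclass
class GatingState:
    """Per-presynaptic-source channel gating."""

    s_ampa: float = 0.0   # fraction of open AMPA channels (unnormalized, >= 0)
    x_aux: float = 0.0    # NMDA auxiliary rise variable (>= 0)
    s_nmda: float = 0.0   # fraction of open NMDA channels, in [0, 1]


@dataclass
class NeuronState:
    """Dynamical state of a single neuron."""

    V: float = -70.0                 # membrane potential (mV)
    g_a: float = 0.0                 # adaptation conductance (nS)
    refractory_remaining: float = 0.0  # ms
    u: float = 0.05                  # STP utilization
    x: float = 1.0                   # STP available resource
    gating: GatingState = None

    def __post_init__(self):
        if self.gating is None:
            self.gating = GatingState()


def mg_block(V: float, params: SynapseParams) -> float:
    """Voltage dependence of the NMDA conductance (magnesium block).

    ``B(V) = 1 / (1 + mg_scale * exp(-mg_slope * V))``; strictly increasing
    in V, tending to 0 under full block and to 1 when depolarized.
    """
    if not math.isfinite(V):
        raise ValueError("membrane potential must be finite")
    return 1.0 / (1.0 + params.mg_scale * math.exp(-params.mg_slope * V))


def synaptic_current(V: float, S_ampa: float, S_nmda: float,
                     params: SynapseParams) -> float:
    """Total recurrent excitatory current (pA), AMPA plus Mg-blocked NMDA.

    ``S_ampa`` and ``S_nmda`` are the weighted sums of presynaptic gating
    variables.  The current uses the driving-force convention
    ``I = g (V - V_E) S``: it is negative (inward) below the excitatory
    reversal and is *subtracted* in the membrane equation, hence
    depolarizing.
    """
    if S_ampa < 0 or S_nmda < 0:
        raise ValueError("gating sums must be non-negative")
    drive = V - params.V_E
    I_ampa = params.g_ampa_eff * drive * S_ampa
    I_nmda = params.g_nmda_eff * drive * mg_block(V, params) * S_nmda
    return I_ampa + I_nmda


def gating_decay(state: GatingState, dt: float,
                 params: SynapseParams) -> GatingState:
    """Advance channel gating by ``dt`` ms with no presynaptic input.

    AMPA gating and the NMDA rise variable decay exponentially (exact);
    the NMDA open fraction obeys
    ``ds/dt = -s/tau_decay + alpha * x_aux * (1 - s)``,
    integrated with x_aux frozen at its start-of-step value, which keeps
    s in [0, 1] for any step size.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s_ampa = state.s_ampa * math.exp(-dt / params.tau_ampa)
    # s_nmda: linear ODE ds/dt = -a s + b with x held at its current value
    a = 1.0 / params.tau_nmda_decay + params.alpha_nmda * state.x_aux
    b = params.alpha_nmda * state.x_aux
    s_inf = b / a
    s_nmda = s_inf + (state.s_nmda - s_inf) * math.exp(-a * dt)
    x_aux = state.x_aux * math.exp(-dt / params.tau_nmda_rise)
    return GatingState(s_ampa=s_ampa, x_aux=x_aux, s_nmda=s_nmda)


def gating_on_presyn_spike(state: GatingState, n_spikes: int = 1) -> GatingState:
    """Apply the arrival of presynaptic spike(s): unit jumps in s_ampa and x_aux.

    The NMDA open fraction is driven only through x_aux and does not jump.
    """
    return GatingState(s_ampa=state.s_ampa + n_spikes,
                       x_aux=state.x_aux + n_spikes,
                       s_nmda=state.s_nmda)


def stp_on_spike(u: float, x: float, params: STPParams) -> tuple[float, float]:
    """Short-term plasticity update at a presynaptic spike.

    Facilitation first (default): ``u' = u + U (1 - u)``, then release
    ``x' = x (1 - u')``.  With ``update_order='x_first'`` the release uses
    the pre-spike u.
    """
    if not (0.0 <= u <= 1.0 and 0.0 <= x <= 1.0):
        raise ValueError("u and x must lie in [0, 1]")
    u_new = u + params.U * (1.0 - u)
    if params.update_order == "u_first":
        x_new = x * (1.0 - u_new)
    else:
        x_new = x * (1.0 - u)
    return u_new, x_new


def stp_relax(u: float, x: float, dt: float,
              params: STPParams) -> tuple[float, float]:
    """Inter-spike relaxation of the STP variables over ``dt`` seconds.

    x recovers towards 1 with tau_x; u towards U with tau_u (closed form).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    x_new = 1.0 - (1.0 - x) * math.exp(-dt / params.tau_x)
    u_new = params.U + (u - params.U) * math.exp(-dt / params.tau_u)
    return u_new, x_new


def adaptation_on_spike(g_a: float, params: AdaptationParams) -> float:
    """Per-spike increment of the adaptation conductance."""
    if g_a < 0:
        raise ValueError("g_a must be non-negative")
    return g_a + params.dg_a


def adaptation_decay(g_a: float, dt: float, params: AdaptationParams) -> float:
    """Exponential decay of the adaptation conductance over ``dt`` seconds."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return g_a * math.exp(-dt / params.tau_ca)


def ahp_current(V: float, g_a: float, params: AdaptationParams) -> float:
    """After-hyperpolarization current ``g_a (V - E_ahp)`` in pA."""
    return g_a * (V - params.E_ahp)


def membrane_step(state: NeuronState, I_syn: float, noise_draw: float,
                  dt: float, neuron: NeuronParams,
                  adaptation: AdaptationParams) -> tuple[NeuronState, bool]:
    """Forward-Euler step of the membrane equation; returns (state', spiked).

    ``C_m dV/dt = -g_m (V - V_L) - I_syn - I_AHP`` plus a noise increment
    ``sigma * sqrt(2 dt / tau_m) * noise_draw`` whose leak-only stationary
    s.d. of V equals sigma.  During refractoriness V is clamped at V_reset
    and no noise or current applies.  Threshold crossing resets V, starts
    the refractory clock and reports a spike.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(state.V):
        raise FloatingPointError("membrane potential is not finite")
    if state.refractory_remaining > 0:
        remaining = max(0.0, state.refractory_remaining - dt)
        new = replace(state, V=neuron.V_reset, refractory_remaining=remaining)
        return new, False
    C_pF = neuron.C_m * 1e3  # nF -> pF so that pA / pF * ms = mV
    I_ahp = ahp_current(state.V, state.g_a, adaptation)
    dV = (dt / C_pF) * (-neuron.g_m * (state.V - neuron.V_L) - I_syn - I_ahp)
    dV += neuron.sigma * math.sqrt(2.0 * dt / neuron.tau_m) * noise_draw
    V = state.V + dV
    if not math.isfinite(V):
        raise FloatingPointError("membrane potential update diverged")
    if V >= neuron.V_thr:
        new = replace(state, V=neuron.V_reset,
                      refractory_remaining=neuron.tau_ref)
        return new, True
    return replace(state, V=V), False
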