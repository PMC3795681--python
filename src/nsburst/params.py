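"""Parameter containers for the excitatory culture network model.

Units follow electrophysiological convention throughout: membrane
potentials in mV, conductances in nS, capacitance in nF, fast (membrane
and synaptic) time constants in ms, slow (plasticity and adaptation)
time constants in s.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron constants.

    The membrane obeys ``C_m dV/dt = -g_m (V - V_L) - I_syn - I_AHP + noise``;
    on reaching ``V_thr`` a spike is emitted, V is reset to ``V_reset`` and
    clamped there for ``tau_ref``.
    """

    C_m: float = 0.5          # capacitance (nF)
    g_m: float = 25.0         # leak conductance (nS)
    V_L: float = -70.0        # resting potential (mV)
    V_thr: float = -50.0      # spike threshold (mV)
    V_reset: float = -55.0    # post-spike reset (mV)
    tau_ref: float = 2.0      # absolute refractory period (ms)
    sigma: float = 6.5        # stationary s.d. of the membrane-potential noise (mV)

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_m in ms (C_m nF, g_m nS -> ms via pF/nS)."""
        return 1e3 * self.C_m / self.g_m

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_thr:
            raise ParameterError("V_reset must lie below V_thr")
        if not self.V_L <= self.V_reset:
            raise ParameterError("V_L must not exceed V_reset")
        if self.C_m <= 0 or self.g_m <= 0:
            raise ParameterError("C_m and g_m must be positive")
        if self.sigma < 0:
            raise ParameterError("sigma must be non-negative")
        if self.tau_ref < 0:
            raise ParameterError("tau_ref must be non-negative")


@dataclass(frozen=True)
class SynapseParams:
    """AMPA/NMDA synapse constants.

    The NMDA conductance is gated by the voltage-dependent magnesium block
    ``B(V) = 1 / (1 + mg_scale * exp(-mg_slope * V))`` and by a two-variable
    (rise + saturating decay) gating scheme; AMPA rise time is neglected.
    ``r_ratio`` optionally re-mixes the two components, scaling NMDA by
    ``r`` and AMPA by ``10 (1 - r)`` (near threshold one unit of AMPA
    conductance carries ~1/10 the charge of one unit of NMDA conductance);
    ``None`` means the unmixed conductances are used as given.
    """

    V_E: float = 0.0              # excitatory reversal (mV)
    g_ampa: float = 0.104         # AMPA conductance (nS)
    g_nmda: float = 0.327         # NMDA conductance (nS)
    g_gaba: float = 1.250         # inhibitory conductance (nS); carried, never simulated
    tau_ampa: float = 2.0         # AMPA decay (ms)
    tau_nmda_rise: float = 2.0    # NMDA rise (ms)
    tau_nmda_decay: float = 100.0  # NMDA decay (ms)
    alpha_nmda: float = 0.5       # NMDA saturation rate (1/ms, i.e. 0.5 kHz)
    mg_scale: float = 0.28        # Mg-block multiplier
    mg_slope: float = 0.062       # Mg-block voltage slope (1/mV)
    delay: float = 10.0           # homogeneous conduction delay (ms)
    r_ratio: Optional[float] = None  # NMDA/AMPA mixing parameter in [0, 1]
    W0: float = 6.5               # recurrent excitatory weight (dimensionless)

    def __post_init__(self) -> None:
        for name in ("tau_ampa", "tau_nmda_rise", "tau_nmda_decay"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.g_ampa < 0 or self.g_nmda < 0:
            raise ParameterError("conductances must be non-negative")
        if self.r_ratio is not None and not 0.0 <= self.r_ratio <= 1.0:
            raise ParameterError("r_ratio must lie in [0, 1]")
        if self.delay < 0:
            raise ParameterError("delay must be non-negative")

    @property
    def g_ampa_eff(self) -> float:
        if self.r_ratio is None:
            return self.g_ampa
        return 10.0 * (1.0 - self.r_ratio) * self.g_ampa

    @property
    def g_nmda_eff(self) -> float:
        if self.r_ratio is None:
            return self.g_nmda
        return self.r_ratio * self.g_nmda


@dataclass(frozen=True)
class STPParams:
    """Tsodyks–Markram short-term plasticity constants.

    ``u`` (utilization, facilitation) jumps by ``U (1 - u)`` on each
    presynaptic spike and relaxes to ``U`` with ``tau_u``; the available
    resource ``x`` is multiplied by ``(1 - u)`` and recovers to 1 with
    ``tau_x``.  Bursts of network spikes require ``tau_u > tau_x`` so the
    net modulation u*x is transiently facilitating after a network spike.
    """

    U: float = 0.05      # baseline utilization, (0, 1]
    tau_u: float = 1.6   # facilitation recovery (s)
    tau_x: float = 0.8   # depression recovery (s)
    update_order: str = "u_first"  # "u_first": x release uses the updated u

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ParameterError("U must lie in (0, 1]")
        if self.tau_u <= 0 or self.tau_x <= 0:
            raise ParameterError("STP time constants must be positive")
        if self.update_order not in ("u_first", "x_first"):
            raise ParameterError("update_order must be 'u_first' or 'x_first'")


@dataclass(frozen=True)
class AdaptationParams:
    """Spike-frequency adaptation (after-hyperpolarization) constants.

    A potassium-like leak conductance ``g_a`` increments by ``dg_a`` on every
    spike and decays exponentially with ``tau_ca``; the resulting current
    ``g_a (V - E_ahp)`` slowly raises the effective firing threshold.
    """

    tau_ca: float = 4.0    # adaptation decay time constant (s)
    dg_a: float = 0.1      # per-spike conductance increment (nS)
    E_ahp: float = -80.0   # adaptation reversal potential (mV)

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ParameterError("tau_ca must be positive")
        if self.dg_a < 0:
            raise ParameterError("dg_a must be non-negative")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all single-neuron and synapse parameter groups."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    stp: STPParams = field(default_factory=STPParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    # mechanism toggles used by the scenario battery
    stp_enabled: bool = True           # False: synaptic weight fixed at W0
    facilitation_enabled: bool = True  # False: u pinned at U, depression still runs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stp_enabled"] = self.stp_enabled
        d["facilitation_enabled"] = self.facilitation_enabled
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelParams":
        known = {"neuron", "synapse", "stp", "adaptation",
                 "stp_enabled", "facilitation_enabled"}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown ModelParams keys: {sorted(unknown)}")
        return ModelParams(
            neuron=NeuronParams(**d.get("neuron", {})),
            synapse=SynapseParams(**d.get("synapse", {})),
            stp=STPParams(**d.get("stp", {})),
            adaptation=AdaptationParams(**d.get("adaptation", {})),
            stp_enabled=bool(d.get("stp_enabled", True)),
            facilitation_enabled=bool(d.get("facilitation_enabled", True)),
        )

    def replace(self, **groups) -> "ModelParams":
        """Return a copy with whole groups or toggles replaced."""
        return replace(self, **groups)
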