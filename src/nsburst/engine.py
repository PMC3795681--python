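"""Clock-driven simulation of the fully connected excitatory network.

The network couples N conductance-based LIF neurons all-to-all (no
autapses) through AMPA/NMDA synapses whose instantaneous weight is
``W0 * u_j(t) * x_j(t)`` (short-term plasticity of the presynaptic
source), with a homogeneous conduction delay, per-neuron white membrane
noise, and a spike-triggered adaptation conductance.  Integration is
forward Euler at a fixed step (25 µs by default).

Because connectivity is full and weights are homogeneous, the weighted
gating sums are identical across postsynaptic neurons up to the removal
of the neuron's own contribution, which keeps the cost per step linear
in N.  The inner loop is compiled with numba.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from numba import njit

from .params import ModelParams, ParameterError


class SimulationError(RuntimeError):
    """Raised when the integration blows up (non-finite membrane potential)."""


@dataclass
class SpikeRecord:
    """Timestamped spike events with unit ids and provenance metadata."""

    times: np.ndarray          # seconds, non-decreasing
    units: np.ndarray          # int unit ids in [0, n_units)
    n_units: int
    duration: float            # seconds of recording represented
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.times.shape != self.units.shape:
            raise ValueError("times and units must have equal length")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class StateTraces:
    """Population-mean state variables sampled on a regular grid."""

    t: np.ndarray        # seconds
    u: np.ndarray        # mean utilization
    x: np.ndarray        # mean available resource
    ux: np.ndarray       # mean of the product u*x (elementwise over neurons)
    g_a: np.ndarray      # mean adaptation conductance (nS)
    rate: np.ndarray     # firing rate (spikes/unit/s) in each trace bin


@dataclass
class NetworkConfig:
    """Everything needed to reproduce one simulation run."""

    params: ModelParams = field(default_factory=ModelParams)
    N: int = 800
    dt: float = 0.025            # integration step (ms)
    duration: float = 300.0      # max simulated time after burn-in (s)
    seed: int = 0
    stop_bns: Optional[int] = None   # stop once this many complete BNSs detected
    sim_time_cap: float = 18000.0    # hard simulated-time cap (s), default 5 h
    connectivity: str = "full"       # "full" | "sparse"
    p: float = 1.0                   # connection probability when sparse
    record_traces: bool = False
    trace_dt: float = 0.01       # trace sampling period (s)
    burn_in: float = 5.0         # discarded initial transient (s)
    conductance_scale: Optional[float] = None  # default 800 / N
    chunk: float = 20.0          # chunked execution granularity (s)
    # online NS/BNS detection parameters for the stopping rule
    ns_bin: float = 0.05         # s
    ns_threshold: float = 0.25   # fraction of running max
    bns_gap: float = 6.0         # s

    def __post_init__(self):
        if self.N < 2:
            raise ParameterError("N must be at least 2")
        if self.dt <= 0 or self.duration <= 0:
            raise ParameterError("dt and duration must be positive")
        if self.connectivity not in ("full", "sparse"):
            raise ParameterError("connectivity must be 'full' or 'sparse'")
        if self.connectivity == "sparse" and not 0.0 < self.p <= 1.0:
            raise ParameterError("sparse connectivity needs 0 < p <= 1")

    @property
    def scale(self) -> float:
        """Conductance scaling preserving total recurrent drive when N != 800."""
        if self.conductance_scale is not None:
            return self.conductance_scale
        return 800.0 / self.N


@njit(cache=True)
def _run_kernel(n_steps, k0, dt, seed,
                V, ga, refr, u, x, s_ampa, x_aux, s_nmda,
                ring, indptr, indices, use_sparse,
                C_pF, g_m, V_L, V_thr, V_reset, refr_steps, noise_amp,
                gA, gN, V_E, mg_scale, mg_slope,
                f_ampa, f_rise, inv_tau_d, alpha,
                W, stp_on, facil_on, u_first, U, f_u, f_x,
                dg_a, f_ca, E_ahp,
                spike_step, spike_unit,
                trace_stride, tr_u, tr_x, tr_ux, tr_ga, tr_count, n_tr0):
    """Advance the network by n_steps; returns (n_spikes, n_traces, err_unit, err_step)."""
    np.random.seed(seed)
    N = V.shape[0]
    Dbuf = ring.shape[0]
    D = Dbuf - 1
    wj = np.empty(N)
    n_sp = 0
    n_tr = n_tr0
    tr_spikes = 0
    cap = spike_step.shape[0]
    for step in range(n_steps):
        k = k0 + step
        # instantaneous weights and homogeneous gating sums
        Sa_tot = 0.0
        Sn_tot = 0.0
        for j in range(N):
            if stp_on:
                w = W * u[j] * x[j]
            else:
                w = W
            wj[j] = w
            Sa_tot += w * s_ampa[j]
            Sn_tot += w * s_nmda[j]
        # membrane update
        for i in range(N):
            xi = np.random.standard_normal()
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = V_reset
                continue
            if use_sparse:
                Sa = 0.0
                Sn = 0.0
                for idx in range(indptr[i], indptr[i + 1]):
                    j = indices[idx]
                    Sa += wj[j] * s_ampa[j]
                    Sn += wj[j] * s_nmda[j]
            else:
                Sa = Sa_tot - wj[i] * s_ampa[i]
                Sn = Sn_tot - wj[i] * s_nmda[i]
            Vi = V[i]
            B = 1.0 / (1.0 + mg_scale * math.exp(-mg_slope * Vi))
            drive = Vi - V_E
            I_syn = gA * drive * Sa + gN * B * drive * Sn
            I_ahp = ga[i] * (Vi - E_ahp)
            Vi = Vi + (dt / C_pF) * (-g_m * (Vi - V_L) - I_syn - I_ahp) \
                + noise_amp * xi
            if not math.isfinite(Vi):
                return n_sp, n_tr, i, k
            if Vi >= V_thr:
                # spike: reset, refractoriness, STP and adaptation at emission,
                # gating jump scheduled one conduction delay later
                V[i] = V_reset
                refr[i] = refr_steps
                if n_sp < cap:
                    spike_step[n_sp] = k
                    spike_unit[n_sp] = i
                    n_sp += 1
                tr_spikes += 1
                if stp_on:
                    if facil_on:
                        u_new = u[i] + U * (1.0 - u[i])
                    else:
                        u_new = u[i]
                    if u_first:
                        x[i] = x[i] * (1.0 - u_new)
                    else:
                        x[i] = x[i] * (1.0 - u[i])
                    u[i] = u_new
                ga[i] = ga[i] + dg_a
                ring[(k + D) % Dbuf, i] += 1
            else:
                V[i] = Vi
        # gating decay, delayed arrivals, slow-variable relaxation
        slot = k % Dbuf
        for j in range(N):
            s_ampa[j] *= f_ampa
            a = inv_tau_d + alpha * x_aux[j]
            b = alpha * x_aux[j]
            s_inf = b / a
            s_nmda[j] = s_inf + (s_nmda[j] - s_inf) * math.exp(-a * dt)
            x_aux[j] *= f_rise
            arr = ring[slot, j]
            if arr > 0:
                s_ampa[j] += arr
                x_aux[j] += arr
                ring[slot, j] = 0
            ga[j] *= f_ca
            if stp_on:
                if facil_on:
                    u[j] = U + (u[j] - U) * f_u
                x[j] = 1.0 - (1.0 - x[j]) * f_x
        # trace sampling
        if trace_stride > 0 and (k + 1) % trace_stride == 0:
            if n_tr < tr_u.shape[0]:
                su = 0.0
                sx = 0.0
                sux = 0.0
                sga = 0.0
                for j in range(N):
                    su += u[j]
                    sx += x[j]
                    sux += u[j] * x[j]
                    sga += ga[j]
                tr_u[n_tr] = su / N
                tr_x[n_tr] = sx / N
                tr_ux[n_tr] = sux / N
                tr_ga[n_tr] = sga / N
                tr_count[n_tr] = tr_spikes
                n_tr += 1
            tr_spikes = 0
    return n_sp, n_tr, -1, -1


class _NetworkState:
    """Mutable simulation state persisted across chunks."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        N = config.N
        np_ = config.params.neuron
        self.V = rng.uniform(np_.V_L, np_.V_thr, size=N)
        self.ga = np.zeros(N)
        self.refr = np.zeros(N, dtype=np.int64)
        self.u = np.full(N, config.params.stp.U)
        self.x = np.ones(N)
        self.s_ampa = np.zeros(N)
        self.x_aux = np.zeros(N)
        self.s_nmda = np.zeros(N)
        D = max(1, int(round(config.params.synapse.delay / config.dt)))
        self.ring = np.zeros((D + 1, N))
        if config.connectivity == "sparse" and config.p < 1.0:
            adj = rng.random((N, N)) < config.p
            np.fill_diagonal(adj, False)
            counts = adj.sum(axis=1)
            self.indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
            self.indices = np.nonzero(adj)[1].astype(np.int64)
            self.use_sparse = True
        else:
            self.indptr = np.zeros(1, dtype=np.int64)
            self.indices = np.zeros(0, dtype=np.int64)
            self.use_sparse = False


def _kernel_constants(config: NetworkConfig) -> dict:
    p = config.params
    n, s, stp, ad = p.neuron, p.synapse, p.stp, p.adaptation
    dt = config.dt
    return dict(
        dt=dt,
        C_pF=n.C_m * 1e3,
        g_m=n.g_m, V_L=n.V_L, V_thr=n.V_thr, V_reset=n.V_reset,
        refr_steps=max(1, int(round(n.tau_ref / dt))),
        noise_amp=n.sigma * math.sqrt(2.0 * dt / n.tau_m),
        gA=s.g_ampa_eff * config.scale,
        gN=s.g_nmda_eff * config.scale,
        V_E=s.V_E, mg_scale=s.mg_scale, mg_slope=s.mg_slope,
        f_ampa=math.exp(-dt / s.tau_ampa),
        f_rise=math.exp(-dt / s.tau_nmda_rise),
        inv_tau_d=1.0 / s.tau_nmda_decay,
        alpha=s.alpha_nmda,
        # with STP disabled the efficacy freezes at the baseline
        # utilization level (u*x -> U), not at the raw weight
        W=s.W0 if p.stp_enabled else s.W0 * stp.U,
        stp_on=p.stp_enabled,
        facil_on=p.facilitation_enabled,
        u_first=(stp.update_order == "u_first"),
        U=stp.U,
        f_u=math.exp(-dt / (stp.tau_u * 1e3)),
        f_x=math.exp(-dt / (stp.tau_x * 1e3)),
        dg_a=ad.dg_a,
        f_ca=math.exp(-dt / (ad.tau_ca * 1e3)),
        E_ahp=ad.E_ahp,
    )


def run_simulation(config: NetworkConfig):
    """Simulate the network; returns (SpikeRecord, StateTraces | None).

    Deterministic given (config, seed).  Honors ``duration``; when
    ``stop_bns`` is set, the run halts once that many complete bursts of
    network spikes have been detected on the accumulated raster (50 ms
    bins, quarter-of-running-max threshold) or the simulated-time cap is
    reached.  The initial ``burn_in`` seconds are discarded; reported
    spike times are relative to the end of burn-in.
    """
    from . import events  # deferred to avoid an import cycle

    master = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(master))
    chunk_seeds = master.generate_state(8192, dtype=np.uint32)
    state = _NetworkState(config, rng)
    consts = _kernel_constants(config)
    dt_s = config.dt * 1e-3
    trace_stride = max(1, int(round(config.trace_dt / dt_s))) \
        if config.record_traces else 0

    horizon = min(config.duration, config.sim_time_cap)
    total_steps = int(round((config.burn_in + horizon) / dt_s))
    burn_steps = int(round(config.burn_in / dt_s))
    chunk_steps = max(1, int(round(config.chunk / dt_s)))

    all_steps = []
    all_units = []
    tr_cap = (total_steps // trace_stride + 2) if trace_stride else 1
    tr_u = np.zeros(tr_cap)
    tr_x = np.zeros(tr_cap)
    tr_ux = np.zeros(tr_cap)
    tr_ga = np.zeros(tr_cap)
    tr_count = np.zeros(tr_cap, dtype=np.int64)
    n_tr = 0

    k0 = 0
    chunk_idx = 0
    while k0 < total_steps:
        n_steps = min(chunk_steps, total_steps - k0)
        cap = state.V.shape[0] * (n_steps // consts["refr_steps"] + 2)
        spike_step = np.zeros(cap, dtype=np.int64)
        spike_unit = np.zeros(cap, dtype=np.int64)
        seed = int(chunk_seeds[chunk_idx % chunk_seeds.size])
        n_sp, n_tr, err_unit, err_step = _run_kernel(
            n_steps, k0, consts["dt"], seed,
            state.V, state.ga, state.refr, state.u, state.x,
            state.s_ampa, state.x_aux, state.s_nmda,
            state.ring, state.indptr, state.indices, state.use_sparse,
            consts["C_pF"], consts["g_m"], consts["V_L"], consts["V_thr"],
            consts["V_reset"], consts["refr_steps"], consts["noise_amp"],
            consts["gA"], consts["gN"], consts["V_E"],
            consts["mg_scale"], consts["mg_slope"],
            consts["f_ampa"], consts["f_rise"], consts["inv_tau_d"],
            consts["alpha"],
            consts["W"], consts["stp_on"], consts["facil_on"],
            consts["u_first"], consts["U"], consts["f_u"], consts["f_x"],
            consts["dg_a"], consts["f_ca"], consts["E_ahp"],
            spike_step, spike_unit,
            trace_stride, tr_u, tr_x, tr_ux, tr_ga, tr_count, n_tr)
        if err_unit >= 0:
            raise SimulationError(
                f"membrane potential of neuron {err_unit} diverged at "
                f"t={err_step * dt_s:.6f} s (before burn-in subtraction)")
        all_steps.append(spike_step[:n_sp].copy())
        all_units.append(spike_unit[:n_sp].copy())
        k0 += n_steps
        chunk_idx += 1
        if config.stop_bns is not None and k0 > burn_steps:
            steps = np.concatenate(all_steps)
            t = steps * dt_s - config.burn_in
            t = t[t >= 0]
            if t.size:
                counts, _ = events.bin_counts_from_times(
                    t, bin=config.ns_bin, t_end=k0 * dt_s - config.burn_in)
                ns = events.detect_ns(counts, bin=config.ns_bin,
                                      threshold_fraction=config.ns_threshold)
                bns = events.partition_bns(ns, gap_threshold=config.bns_gap)
                # the trailing BNS may still be growing; count completed ones
                if len(bns) - 1 >= config.stop_bns:
                    break

    steps = np.concatenate(all_steps) if all_steps else np.zeros(0, dtype=np.int64)
    units = np.concatenate(all_units) if all_units else np.zeros(0, dtype=np.int64)
    times = steps * dt_s - config.burn_in
    keep = times >= 0.0
    times = times[keep]
    units = units[keep]
    duration = k0 * dt_s - config.burn_in

    meta = {"config": config_to_dict(config), "source": "simulated",
            "seed": config.seed, "n_units": config.N,
            "duration": duration, "engine": "nsburst-euler"}
    record = SpikeRecord(times=times, units=units, n_units=config.N,
                         duration=duration, meta=meta)
    traces = None
    if trace_stride:
        tgrid = (np.arange(n_tr) + 1) * trace_stride * dt_s - config.burn_in
        keep_tr = tgrid >= 0.0
        rate = tr_count[:n_tr][keep_tr] / (config.N * trace_stride * dt_s)
        traces = StateTraces(t=tgrid[keep_tr], u=tr_u[:n_tr][keep_tr],
                             x=tr_x[:n_tr][keep_tr], ux=tr_ux[:n_tr][keep_tr],
                             g_a=tr_ga[:n_tr][keep_tr], rate=rate)
    return record, traces


def population_rate(record: SpikeRecord, bin: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Mean firing rate (spikes/unit/s) in fixed bins; returns (bin_starts, rate).

    Count conservation holds exactly: ``sum(rate) * bin * n_units`` equals
    the total number of spikes.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    n_bins = max(1, int(math.ceil(record.duration / bin - 1e-9)))
    edges = np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(record.times, bins=edges)
    # spikes at exactly t_end fall in the last bin by the right-open rule
    counts[-1] += np.sum(record.times >= edges[-1])
    rate = counts / (record.n_units * bin)
    return edges[:-1], rate


def config_to_dict(config: NetworkConfig) -> dict:
    d = asdict(config)
    d["params"] = config.params.to_dict()
    return d


def config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    known = {f for f in NetworkConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(f"unknown NetworkConfig keys: {sorted(unknown)}")
    if "params" in d:
        d["params"] = ModelParams.from_dict(d["params"])
    return NetworkConfig(**d)
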