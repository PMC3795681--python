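"""In-silico experiment battery: calibration, mechanism scenarios, sweeps,
and working-point inference.

The free parameters that electrophysiology does not pin down (the
membrane-noise amplitude sigma and the per-spike adaptation increment
dg_a) are set by calibration: sigma so that an isolated neuron fires
with ~2 s mean inter-spike interval, dg_a so that the baseline network
(W0 = 6.5, tau_ca = 4 s) produces bursts of 2–6 network spikes separated
by tens of seconds.  The shipped defaults (sigma = 6.5 mV, dg_a = 0.1 nS)
are the outputs of these routines.

`sweep_w0` maps a (tau_ca, W0) grid onto the (mean IBNSI, CV) plane and
fits the Poisson-with-refractory-period relation per curve;
`infer_working_point` inverts that family of curves to estimate the
apparent adaptation timescale and recurrent weight of a recorded
culture from its interval statistics alone.  When comparing adaptation
timescales, dg_a is rescaled so that the product dg_a * tau_ca stays
constant, preserving the steady-state adaptation conductance per unit
firing rate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import events
from .engine import NetworkConfig, StateTraces, run_simulation
from .events import RefractoryFit
from .params import AdaptationParams, ModelParams, SynapseParams

logger = logging.getLogger(__name__)

#: reference point of the dg_a * tau_ca = const rule (the baseline)
BASELINE_TAU_CA = 4.0
BASELINE_DG_A = 0.1


@dataclass
class SweepCurve:
    """(W0 -> interval statistics) table for one adaptation timescale."""

    tau_ca: float
    w0: list = field(default_factory=list)
    n_bns: list = field(default_factory=list)
    stats: list = field(default_factory=list)      # IntervalStats per W0
    fit: Optional[RefractoryFit] = None
    discarded: list = field(default_factory=list)  # W0 values dropped (< min BNS)


@dataclass(frozen=True)
class ScenarioOutcome:
    """Verdict of one mechanism-battery scenario."""

    scenario: str            # "A" | "B" | "C" | "D"
    toggles: dict
    mean_ns_per_bns: float
    n_bns: int
    bns_present: bool


@dataclass(frozen=True)
class WorkingPoint:
    """Inferred model coordinates of a culture from (mean IBNSI, CV)."""

    tau_ca: float
    W0: float
    mean_ibnsi: float
    cv: float
    extrapolated: bool = False
    culture_id: Optional[str] = None


class ExtrapolationError(ValueError):
    """Query point outside the curve family; carries the clipped estimate."""

    def __init__(self, msg: str, estimate: WorkingPoint):
        super().__init__(msg)
        self.estimate = estimate


def baseline_config(N: int = 800, dt: float = 0.025, **overrides) -> NetworkConfig:
    """The baseline network (full fidelity by default: N=800, dt=25 µs)."""
    return NetworkConfig(params=ModelParams(), N=N, dt=dt, **overrides)


def scaled_config(**overrides) -> NetworkConfig:
    """Reduced problem size for desk-scale runs: N=200 (conductances
    scaled by 800/N) and a 0.1 ms step."""
    overrides.setdefault("N", 200)
    overrides.setdefault("dt", 0.1)
    return NetworkConfig(params=overrides.pop("params", ModelParams()),
                         **overrides)


def _with_adaptation(config: NetworkConfig, tau_ca: float,
                     dg_ref: Optional[float] = None,
                     tau_ref: Optional[float] = None) -> NetworkConfig:
    """Config copy with tau_ca set and dg_a rescaled so dg_a*tau_ca is constant."""
    ad = config.params.adaptation
    dg_ref = ad.dg_a if dg_ref is None else dg_ref
    tau_ref = ad.tau_ca if tau_ref is None else tau_ref
    new_ad = AdaptationParams(tau_ca=tau_ca, dg_a=dg_ref * tau_ref / tau_ca,
                              E_ahp=ad.E_ahp)
    return replace(config, params=config.params.replace(adaptation=new_ad))


def _with_w0(config: NetworkConfig, W0: float) -> NetworkConfig:
    syn = replace(config.params.synapse, W0=W0)
    return replace(config, params=config.params.replace(synapse=syn))


def isolated_mean_isi(sigma: float, duration: float = 1200.0, seed: int = 0,
                      dt: float = 0.025, min_spikes: int = 2) -> tuple[float, int]:
    """Mean single-neuron ISI with recurrence off (W0 = 0)."""
    from .params import NeuronParams

    params = ModelParams(neuron=NeuronParams(sigma=sigma),
                         synapse=SynapseParams(W0=0.0))
    cfg = NetworkConfig(params=params, N=2, dt=dt, duration=duration,
                        seed=seed, burn_in=2.0, conductance_scale=1.0)
    rec, _ = run_simulation(cfg)
    isis = [np.diff(rec.times[rec.units == u]) for u in range(cfg.N)]
    isis = np.concatenate([d for d in isis if d.size]) if any(
        d.size for d in isis) else np.zeros(0)
    if isis.size < min_spikes:
        return math.inf, int(isis.size)
    return float(isis.mean()), int(isis.size)


def calibrate_sigma(target_isi: float = 2.0, tol: float = 0.05,
                    lo: float = 4.0, hi: float = 10.0, seed: int = 0,
                    duration: float = 1200.0, dt: float = 0.025,
                    max_iter: int = 20) -> tuple[float, float]:
    """Bisect sigma until the isolated-neuron mean ISI hits the target.

    The mean ISI is monotonically decreasing in sigma (stronger membrane
    noise shortens the first passage to threshold).  Returns
    (sigma, achieved mean ISI).
    """
    if not math.isfinite(target_isi) or target_isi <= 0:
        raise ValueError("target_isi must be a positive finite time")
    isi_lo, _ = isolated_mean_isi(lo, duration, seed, dt)
    isi_hi, _ = isolated_mean_isi(hi, duration, seed, dt)
    if not (isi_lo > target_isi > isi_hi):
        raise ValueError(
            f"initial range does not bracket the target: "
            f"ISI({lo})={isi_lo:.3g}, ISI({hi})={isi_hi:.3g}, "
            f"target={target_isi}")
    sigma, isi = hi, isi_hi
    for _ in range(max_iter):
        sigma = 0.5 * (lo + hi)
        isi, _ = isolated_mean_isi(sigma, duration, seed, dt)
        if abs(isi - target_isi) <= tol * target_isi:
            return sigma, isi
        if isi > target_isi:
            lo = sigma
        else:
            hi = sigma
    return sigma, isi


def _bns_summary(config: NetworkConfig):
    rec, traces = run_simulation(config)
    ns = events.detect_ns_record(rec, bin=config.ns_bin,
                                 threshold_fraction=config.ns_threshold)
    bns = events.partition_bns(ns, gap_threshold=config.bns_gap)
    return rec, traces, ns, bns


def calibrate_adaptation(config: NetworkConfig,
                         grid: Sequence[float] = (0.025, 0.05, 0.1, 0.2, 0.4),
                         ns_per_bns_range=(2.0, 6.0),
                         ibnsi_range=(10.0, 60.0)) -> float:
    """Grid-search dg_a so the baseline produces realistic BNS trains.

    Accepts the first dg_a whose runs yield a median of 2–6 network
    spikes per BNS and a median inter-BNS interval of 10–60 s.
    """
    misses = []
    for dg in grid:
        ad = replace(config.params.adaptation, dg_a=dg)
        cfg = replace(config, params=config.params.replace(adaptation=ad))
        _, _, _, bns = _bns_summary(cfg)
        ib = events.ibnsi(bns)
        med_ns = float(np.median([b.n_ns for b in bns])) if bns else 0.0
        med_ib = float(np.median(ib)) if ib.size else math.inf
        ok_ns = ns_per_bns_range[0] <= med_ns <= ns_per_bns_range[1]
        ok_ib = ibnsi_range[0] <= med_ib <= ibnsi_range[1]
        logger.info("calibrate_adaptation dg_a=%g: median NS/BNS=%.2f, "
                    "median IBNSI=%.1f s", dg, med_ns, med_ib)
        if ok_ns and ok_ib:
            return dg
        misses.append((dg, med_ns, med_ib))
    raise RuntimeError(
        "no dg_a on the grid satisfies the BNS criteria; nearest misses "
        f"(dg_a, median NS/BNS, median IBNSI): {misses}")


def scenario_battery(config: Optional[NetworkConfig] = None, seed: int = 0,
                     duration: float = 300.0, strong_factor: float = 8.0,
                     long_tau_x: float = 4.0,
                     presence_cutoff: float = 1.5,
                     min_bursts: int = 3) -> list:
    """Run the four-mechanism battery ruling fatigue scenarios in or out.

    A: adaptation only (STP off — efficacy frozen at the baseline
       utilization level — with the per-spike increment scaled up so that
       adaptation alone quenches activity);
    B: depression only, with a long recovery timescale (facilitation and
       adaptation off);
    C: the full model (short STD, longer STF, slow adaptation);
    D: long-timescale depression plus adaptation (facilitation off).

    A scenario is scored as producing BNSs when the mean number of NSs
    per BNS reaches ``presence_cutoff`` *and* at least ``min_bursts``
    silence-delimited series occur: a burst is a series terminated by a
    long silent gap on both sides, so a continuous NS train that never
    pauses for the 6 s gap threshold does not count as bursting, and
    neither do purely isolated NSs.
    """
    if config is None:
        config = scaled_config(duration=duration, seed=seed)
    else:
        config = replace(config, duration=duration, seed=seed)
    p = config.params
    scenarios = {
        "A": p.replace(stp_enabled=False,
                       adaptation=replace(p.adaptation,
                                          dg_a=p.adaptation.dg_a * strong_factor)),
        "B": p.replace(facilitation_enabled=False,
                       stp=replace(p.stp, tau_x=long_tau_x),
                       adaptation=replace(p.adaptation, dg_a=0.0)),
        "C": p,
        "D": p.replace(facilitation_enabled=False,
                       stp=replace(p.stp, tau_x=long_tau_x)),
    }
    outcomes = []
    for name, params in scenarios.items():
        cfg = replace(config, params=params)
        _, _, ns, bns = _bns_summary(cfg)
        mean_ns = float(np.mean([b.n_ns for b in bns])) if bns else 0.0
        outcomes.append(ScenarioOutcome(
            scenario=name,
            toggles={"stp_enabled": params.stp_enabled,
                     "facilitation_enabled": params.facilitation_enabled,
                     "tau_x": params.stp.tau_x,
                     "dg_a": params.adaptation.dg_a},
            mean_ns_per_bns=mean_ns,
            n_bns=len(bns),
            bns_present=(mean_ns >= presence_cutoff
                         and len(bns) >= min_bursts)))
    return outcomes


def timescale_separation_study(tau_ca_list: Sequence[float] = (1.2, 1.6),
                               config: Optional[NetworkConfig] = None,
                               seed: int = 0, duration: float = 300.0) -> dict:
    """Distribution of NSs-per-BNS and BNS durations across tau_ca values.

    dg_a is rescaled as 1/tau_ca from the baseline so the global
    adaptation level is maintained; below ~1.6 s the adaptation
    conductance can no longer accumulate across successive NSs and BNS
    termination becomes stochastic, producing abnormally long bursts.
    """
    if config is None:
        config = scaled_config(duration=duration, seed=seed)
    else:
        config = replace(config, duration=duration, seed=seed)
    out = {}
    for tau in tau_ca_list:
        cfg = _with_adaptation(config, tau, dg_ref=BASELINE_DG_A,
                               tau_ref=BASELINE_TAU_CA)
        _, _, ns, bns = _bns_summary(cfg)
        out[tau] = {
            "ns_per_bns": np.array([b.n_ns for b in bns]),
            "bns_duration": np.array([b.offset - b.onset for b in bns]),
            "n_bns": len(bns),
        }
    return out


def sweep_w0(tau_ca_list: Sequence[float] = (2.0, 4.0, 8.0),
             w0_grid: Sequence[float] = tuple(np.round(np.arange(8.3, 9.11, 0.1), 2)),
             config: Optional[NetworkConfig] = None,
             stop_bns: int = 300, cap: float = 18000.0,
             discard_below: int = 100, seed: int = 0,
             boot_seed: int = 0) -> list:
    """Map each (tau_ca, W0) to (mean IBNSI, CV) and fit T per curve.

    Each run halts at ``stop_bns`` recorded BNSs or the simulated-time
    cap; grid points with fewer than ``discard_below`` BNSs are excluded
    from the refractory-period fit.  Returns one SweepCurve per tau_ca.
    """
    if not len(w0_grid) or not len(tau_ca_list):
        raise ValueError("sweep grids must be non-empty")
    if config is None:
        config = scaled_config()
    curves = []
    for tau in tau_ca_list:
        curve = SweepCurve(tau_ca=tau)
        for W0 in w0_grid:
            cfg = _with_adaptation(_with_w0(config, W0), tau,
                                   dg_ref=BASELINE_DG_A,
                                   tau_ref=BASELINE_TAU_CA)
            cfg = replace(cfg, stop_bns=stop_bns, duration=cap,
                          sim_time_cap=cap, seed=seed)
            _, _, ns, bns = _bns_summary(cfg)
            ib = events.ibnsi(bns)
            if len(bns) < discard_below or ib.size < 3:
                logger.info("sweep tau_ca=%g W0=%g: %d BNSs (discarded)",
                            tau, W0, len(bns))
                curve.discarded.append(W0)
                continue
            st = events.interval_cv(ib, seed=boot_seed,
                                    min_n=min(10, ib.size))
            curve.w0.append(float(W0))
            curve.n_bns.append(len(bns))
            curve.stats.append(st)
            logger.info("sweep tau_ca=%g W0=%g: n=%d mean=%.1f cv=%.2f",
                        tau, W0, len(bns), st.mean, st.cv)
        if len(curve.stats) >= 3:
            curve.fit = events.fit_refractory_period(curve.stats)
        curves.append(curve)
    return curves


def infer_working_point(mean_ibnsi: float, cv: float, curves: Sequence,
                        culture_id: Optional[str] = None) -> WorkingPoint:
    """Place a culture on the curve family and read off (tau_ca, W0).

    For each curve the CV and W0 are interpolated at the query mean
    (linear in log-mean); the adaptation timescale is then interpolated
    linearly in CV between the two bracketing curves.  A query outside
    the family raises ExtrapolationError carrying the clipped estimate.
    """
    usable = [c for c in curves if len(c.stats) >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 curves with >= 2 points each")
    logm = math.log(mean_ibnsi)
    per_curve = []
    edge = False
    for c in sorted(usable, key=lambda c: c.tau_ca):
        means = np.array([s.mean for s in c.stats])
        cvs = np.array([s.cv for s in c.stats])
        w0s = np.array(c.w0, dtype=float)
        order = np.argsort(means)
        lm = np.log(means[order])
        if not lm[0] <= logm <= lm[-1]:
            edge = True
        cv_at = float(np.interp(logm, lm, cvs[order]))
        w0_at = float(np.interp(logm, lm, w0s[order]))
        per_curve.append((c.tau_ca, cv_at, w0_at))
    # CV decreases with tau_ca at fixed mean (longer dead time, more regular)
    per_curve.sort(key=lambda t: t[1])
    cvs_sorted = [t[1] for t in per_curve]
    if not cvs_sorted[0] <= cv <= cvs_sorted[-1]:
        # clip to the nearest curve
        nearest = min(per_curve, key=lambda t: abs(t[1] - cv))
        est = WorkingPoint(tau_ca=nearest[0], W0=nearest[2],
                           mean_ibnsi=mean_ibnsi, cv=cv, extrapolated=True,
                           culture_id=culture_id)
        raise ExtrapolationError(
            f"query point (mean={mean_ibnsi:.3g}, cv={cv:.3g}) lies outside "
            "the curve family", est)
    for (tau_a, cv_a, w0_a), (tau_b, cv_b, w0_b) in zip(per_curve,
                                                        per_curve[1:]):
        if cv_a <= cv <= cv_b:
            frac = 0.0 if cv_b == cv_a else (cv - cv_a) / (cv_b - cv_a)
            return WorkingPoint(
                tau_ca=tau_a + frac * (tau_b - tau_a),
                W0=w0_a + frac * (w0_b - w0_a),
                mean_ibnsi=mean_ibnsi, cv=cv, extrapolated=edge,
                culture_id=culture_id)
    raise AssertionError("unreachable: cv inside range but no bracket found")


def adaptation_triggered_average(traces: StateTraces, onsets: Sequence[float],
                                 window: float = 20.0,
                                 min_events: int = 10) -> dict:
    """Time-locked average of the population g_a preceding BNS onsets.

    Returns lag grid (s, negative = before onset), mean trajectory and a
    95% confidence band for the mean.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < min_events:
        raise ValueError(f"need at least {min_events} BNS onsets")
    dt = float(np.median(np.diff(traces.t)))
    n_lag = int(round(window / dt))
    if n_lag >= traces.t.size:
        raise ValueError("window longer than the recorded traces")
    segs = []
    for t0 in onsets:
        i = int(np.searchsorted(traces.t, t0))
        if i - n_lag < 0 or i > traces.t.size:
            continue
        segs.append(traces.g_a[i - n_lag:i])
    if len(segs) < min_events:
        raise ValueError("too few onsets with a full preceding window")
    segs = np.array(segs)
    mean = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / math.sqrt(segs.shape[0])
    lags = -(np.arange(n_lag)[::-1] + 1) * dt
    return {"lag": lags, "mean": mean,
            "ci_low": mean - 1.96 * sem, "ci_high": mean + 1.96 * sem,
            "n": segs.shape[0]}
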