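"""Network-spike detection and interval statistics.

A network spike (NS) is a brief episode in which most units fire
together; it is detected by binning all spikes in 50 ms bins and
thresholding at a quarter of the session maximum.  NSs cluster into
bursts (BNS) delimited by long silent gaps.  This module detects NSs,
partitions them into BNSs, and computes the interval statistics used to
place a preparation on the model's working-point plane: INSI/IBNSI
samples, CV with bootstrap confidence intervals, the weighted fit of the
Poisson-with-refractory-period relation CV = (mean - T)/mean, and a
goodness-of-fit comparison of exponential versus power-law interval
tails.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .engine import SpikeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NSEvent:
    """One detected network spike."""

    peak_time: float   # s, center of the run's maximum bin
    onset: float       # s, left edge of the first supra-threshold bin
    offset: float      # s, right edge of the last supra-threshold bin
    magnitude: float   # total spikes within [onset, offset]
    peak_rate: float   # spikes/unit/s in the maximum bin

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BNS:
    """A maximal series of network spikes separated by short gaps."""

    events: list          # ordered NSEvents

    @property
    def onset(self) -> float:
        return self.events[0].peak_time

    @property
    def offset(self) -> float:
        return self.events[-1].peak_time

    @property
    def n_ns(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class IntervalStats:
    """Mean/CV of an interval sample with bootstrap 95% intervals."""

    n: int
    mean: float
    cv: float
    ci_mean: Optional[tuple] = None
    ci_cv: Optional[tuple] = None


@dataclass(frozen=True)
class RefractoryFit:
    """Result of the Poisson-with-refractory-period fit CV = (mean - T)/mean."""

    T: float
    r_squared: float
    weights: tuple = ()


@dataclass(frozen=True)
class TailTestResult:
    """Verdicts of the interval-tail goodness-of-fit tests."""

    exponential_reject: bool
    power_law_reject: bool
    p_exponential: float
    p_power_law: float
    ks_exponential: float
    ks_power_law: float
    exp_scale: float       # fitted shifted-exponential scale (s)
    pl_alpha: float        # fitted power-law exponent
    n_tail: int


def bin_counts_from_times(times: np.ndarray, bin: float = 0.05,
                          t_end: Optional[float] = None) -> tuple[np.ndarray, float]:
    """Population spike counts in right-open bins [k*bin, (k+1)*bin).

    Returns (counts, bin).  ``t_end`` extends the trace to cover a known
    recording duration; a spike landing exactly on the final edge is kept
    in the last bin.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    times = np.asarray(times, dtype=float)
    if t_end is None:
        t_end = times.max() + bin if times.size else bin
    n_bins = max(1, int(math.ceil(t_end / bin - 1e-9)))
    edges = np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(times, bins=edges)
    counts[-1] += int(np.sum(times >= edges[-1]))
    return counts.astype(np.int64), bin


def bin_counts(record: SpikeRecord, bin: float = 0.05) -> tuple[np.ndarray, float]:
    """Spike counts over all units of a record in 50 ms (default) bins."""
    return bin_counts_from_times(record.times, bin=bin, t_end=record.duration)


def detect_ns(counts: np.ndarray, bin: float = 0.05,
              threshold_fraction: float = 0.25,
              n_units: int = 1) -> list:
    """Detect network spikes as maximal runs of supra-threshold bins.

    The threshold is ``threshold_fraction`` times the maximum bin count of
    the session.  Each maximal run of contiguous bins with count >=
    threshold is one NS; its magnitude is the summed count over the run
    and its reference time the center of the run's maximum bin.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts must be non-empty")
    cmax = counts.max()
    if cmax <= 0:
        return []
    thr = threshold_fraction * cmax
    supra = counts >= thr
    # run boundaries
    padded = np.concatenate(([False], supra, [False]))
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]  # exclusive
    events = []
    for s, e in zip(starts, ends):
        run = counts[s:e]
        ipeak = s + int(np.argmax(run))
        events.append(NSEvent(
            peak_time=(ipeak + 0.5) * bin,
            onset=s * bin,
            offset=e * bin,
            magnitude=float(run.sum()),
            peak_rate=float(counts[ipeak]) / (n_units * bin),
        ))
    return events


def detect_ns_record(record: SpikeRecord, bin: float = 0.05,
                     threshold_fraction: float = 0.25) -> list:
    """Convenience wrapper: bin a SpikeRecord and detect its network spikes."""
    counts, _ = bin_counts(record, bin=bin)
    return detect_ns(counts, bin=bin, threshold_fraction=threshold_fraction,
                     n_units=record.n_units)


def partition_bns(events: Sequence, gap_threshold: float = 6.0) -> list:
    """Split a time-sorted NS sequence into BNSs at peak-to-peak gaps > threshold."""
    events = list(events)
    if not events:
        return []
    groups = [[events[0]]]
    for prev, cur in zip(events, events[1:]):
        if cur.peak_time - prev.peak_time > gap_threshold:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return [BNS(events=g) for g in groups]


def insi(events: Sequence) -> np.ndarray:
    """Inter-network-spike intervals (peak-to-peak), empty for < 2 events."""
    peaks = np.array([e.peak_time for e in events])
    return np.diff(peaks) if peaks.size >= 2 else np.zeros(0)


def ibnsi(bns_list: Sequence, convention: str = "onset") -> np.ndarray:
    """Inter-BNS intervals.

    ``onset`` (default): onset-to-onset between consecutive BNSs, the
    natural observable for an event-initiation point process;
    ``offset_to_onset``: silent-gap durations.
    """
    if convention not in ("onset", "offset_to_onset"):
        raise ValueError("convention must be 'onset' or 'offset_to_onset'")
    if len(bns_list) < 2:
        return np.zeros(0)
    onsets = np.array([b.onset for b in bns_list])
    if convention == "onset":
        return np.diff(onsets)
    offsets = np.array([b.offset for b in bns_list])
    return onsets[1:] - offsets[:-1]


def ns_magnitude_stats(bns_list: Sequence, first_only: bool = True,
                       duration: Optional[float] = None
                       ) -> tuple[float, float, float]:
    """Mean, sample s.d. and relative s.d. of NS magnitudes.

    By default only the first NS of each BNS is counted, since later NSs
    in a series are weakened by fatigue.  When the recording ``duration``
    is given, events truncated by the recording edge (offset at or past
    the end) are excluded — a cut-off event reports a partial magnitude.
    """
    if first_only:
        cand = [b.events[0] for b in bns_list]
    else:
        cand = [e for b in bns_list for e in b.events]
    if duration is not None:
        cand = [e for e in cand if e.offset < duration - 1e-9]
    mags = np.array([e.magnitude for e in cand])
    if mags.size < 2:
        raise ValueError("need at least 2 qualifying network spikes")
    mean = float(mags.mean())
    sd = float(mags.std(ddof=1))
    return mean, sd, sd / mean


def interval_cv(sample: np.ndarray, n_boot: int = 1000, seed: int = 0,
                min_n: int = 10) -> IntervalStats:
    """Mean and CV of an interval sample with percentile bootstrap 95% CIs.

    CV uses the sample (n-1) standard deviation.  Below ``min_n``
    intervals the bootstrap is skipped and the CIs are None.
    """
    sample = np.asarray(sample, dtype=float)
    n = sample.size
    if n < 2:
        raise ValueError("need at least 2 intervals")
    mean = float(sample.mean())
    if mean <= 0:
        raise ValueError("interval mean must be positive")
    cv = float(sample.std(ddof=1) / mean)
    ci_mean = ci_cv = None
    if n >= min_n:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        res = sample[idx]
        b_means = res.mean(axis=1)
        b_cvs = res.std(axis=1, ddof=1) / np.where(b_means > 0, b_means, np.nan)
        ci_mean = tuple(np.percentile(b_means, [2.5, 97.5]))
        ci_cv = tuple(np.nanpercentile(b_cvs, [2.5, 97.5]))
    return IntervalStats(n=n, mean=mean, cv=cv, ci_mean=ci_mean, ci_cv=ci_cv)


def _point_weights(points) -> np.ndarray:
    widths = []
    for p in points:
        ci_m = p[2] if len(p) > 2 else None
        ci_c = p[3] if len(p) > 3 else None
        if ci_m is None or ci_c is None:
            widths.append(0.0)
            continue
        wm = float(ci_m[1] - ci_m[0])
        wc = float(ci_c[1] - ci_c[0])
        widths.append(wm * wc)
    widths = np.asarray(widths)
    if np.any(widths <= 0):
        logger.warning("degenerate confidence boxes; falling back to equal weights")
        return np.ones(len(points))
    return 1.0 / widths


def fit_refractory_period(points: Sequence) -> RefractoryFit:
    """Weighted least-squares fit of CV = (mean - T)/mean over T >= 0.

    ``points`` is a sequence of (mean, cv) or (mean, cv, ci_mean, ci_cv)
    tuples (or IntervalStats); each point's weight is the inverse of its
    95% confidence-box area, with equal weights as fallback when boxes
    are degenerate.  The model is linear in T, so the minimizer is closed
    form; the reported R² is the weighted coefficient of determination.
    """
    pts = []
    for p in points:
        if isinstance(p, IntervalStats):
            pts.append((p.mean, p.cv, p.ci_mean, p.ci_cv))
        else:
            pts.append(tuple(p))
    if len(pts) < 3:
        raise ValueError("need at least 3 points to fit")
    m = np.array([p[0] for p in pts], dtype=float)
    cv = np.array([p[1] for p in pts], dtype=float)
    if np.any(m <= 0):
        raise ValueError("means must be positive")
    w = _point_weights(pts)
    # residual r_i = cv_i - (1 - T/m_i) is linear in T
    T = float(np.sum(w * (1.0 - cv) / m) / np.sum(w / m ** 2))
    T = max(0.0, T)
    pred = 1.0 - T / m
    ss_res = float(np.sum(w * (cv - pred) ** 2))
    cv_bar = float(np.sum(w * cv) / np.sum(w))
    ss_tot = float(np.sum(w * (cv - cv_bar) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    r2 = min(1.0, max(0.0, r2))
    return RefractoryFit(T=T, r_squared=r2, weights=tuple(w))


def _ks_exponential(tail: np.ndarray, xmin: float) -> tuple[float, float]:
    scale = float(np.mean(tail - xmin))
    d = sps.kstest(tail - xmin, "expon", args=(0, scale)).statistic
    return d, scale


def _ks_power_law(tail: np.ndarray, xmin: float) -> tuple[float, float]:
    alpha = 1.0 + tail.size / float(np.sum(np.log(tail / xmin)))
    d = sps.kstest(tail, "pareto", args=(alpha - 1.0, 0, xmin)).statistic
    return d, alpha


def tail_test(sample: np.ndarray, xmin: float, n_boot: int = 500,
              seed: int = 0, alpha_level: float = 0.05) -> TailTestResult:
    """Exponential vs power-law goodness of fit for the interval tail.

    Fits a shifted exponential and a continuous power law to the tail
    (x >= xmin) by maximum likelihood, then applies a one-sample KS test
    to each with the null distribution obtained by parametric bootstrap
    (refitting on each synthetic sample).  A hypothesis is rejected at
    ``alpha_level`` when the observed KS statistic exceeds the bootstrap
    (1 - alpha) quantile.
    """
    sample = np.asarray(sample, dtype=float)
    tail = sample[sample >= xmin]
    n = tail.size
    if n < 10:
        raise ValueError(f"insufficient tail mass: {n} samples >= xmin")
    rng = np.random.default_rng(seed)
    d_exp, scale = _ks_exponential(tail, xmin)
    d_pl, pl_alpha = _ks_power_law(tail, xmin)
    boot_exp = np.empty(n_boot)
    boot_pl = np.empty(n_boot)
    for b in range(n_boot):
        synth = xmin + rng.exponential(scale, size=n)
        boot_exp[b] = _ks_exponential(synth, xmin)[0]
        synth = xmin * (1.0 - rng.random(n)) ** (-1.0 / (pl_alpha - 1.0))
        boot_pl[b] = _ks_power_law(synth, xmin)[0]
    p_exp = float(np.mean(boot_exp >= d_exp))
    p_pl = float(np.mean(boot_pl >= d_pl))
    return TailTestResult(
        exponential_reject=p_exp < alpha_level,
        power_law_reject=p_pl < alpha_level,
        p_exponential=p_exp, p_power_law=p_pl,
        ks_exponential=d_exp, ks_power_law=d_pl,
        exp_scale=scale, pl_alpha=pl_alpha, n_tail=n)
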