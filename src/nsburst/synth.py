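"""Synthetic MEA-like raster generation.

Emulates what a 60-electrode multi-electrode array records from a
disinhibited culture: a sparse baseline of ~1 spike/electrode/s of
uncorrelated activity, punctuated by network spikes during which the
population rate transiently climbs to 100 spikes/electrode/s or more.
Each scheduled network spike contributes a half-cosine rate bump of
given width and peak; spikes are drawn per unit from the resulting
inhomogeneous Poisson intensity.  These rasters exercise every
statistics path without running the network simulator.
"""
from __future__ import annotations

import numpy as np

from .engine import SpikeRecord


def _sample_half_cosine(rng: np.random.Generator, n: int, center: float,
                        width: float) -> np.ndarray:
    """Draw n times from the density ∝ 1 + cos(2π (t - center)/width) on
    [center - width/2, center + width/2] by rejection sampling."""
    out = np.empty(0)
    while out.size < n:
        need = n - out.size
        t = rng.uniform(-0.5, 0.5, size=2 * need + 8)
        accept = rng.random(t.size) < 0.5 * (1.0 + np.cos(2.0 * np.pi * t))
        out = np.concatenate([out, t[accept][:need]])
    return center + width * out


def synth_raster(ns_times, ns_peak_rates, n_units: int = 60,
                 baseline_rate: float = 1.0, ns_width: float = 0.1,
                 duration: float = 60.0, seed: int = 0) -> SpikeRecord:
    """Generate a synthetic raster with planted network spikes.

    Parameters
    ----------
    ns_times : sequence of s
        Scheduled NS centers; must lie within [0, duration].
    ns_peak_rates : float or sequence
        Peak rate of each bump (spikes/unit/s); bumps that overlap add.
    n_units, baseline_rate, ns_width, duration, seed
        Raster geometry; baseline is homogeneous Poisson per unit.
    """
    ns_times = np.atleast_1d(np.asarray(ns_times, dtype=float))
    peaks = np.broadcast_to(np.atleast_1d(np.asarray(ns_peak_rates, dtype=float)),
                            ns_times.shape).astype(float)
    if baseline_rate < 0 or np.any(peaks < 0):
        raise ValueError("rates must be non-negative")
    if np.any((ns_times < 0) | (ns_times > duration)):
        raise ValueError("scheduled NS times must lie within the recording")
    rng = np.random.default_rng(seed)
    times = []
    units = []
    for u in range(n_units):
        n_base = rng.poisson(baseline_rate * duration)
        times.append(rng.uniform(0.0, duration, size=n_base))
        units.append(np.full(n_base, u, dtype=np.int64))
        for t0, pk in zip(ns_times, peaks):
            # bump integral per unit: peak/2 * width (mean of 1+cos is 1,
            # amplitude peak/2)
            n_ns = rng.poisson(0.5 * pk * ns_width)
            if n_ns:
                t = _sample_half_cosine(rng, n_ns, t0, ns_width)
                t = np.clip(t, 0.0, duration)
                times.append(t)
                units.append(np.full(n_ns, u, dtype=np.int64))
    times = np.concatenate(times) if times else np.zeros(0)
    units = np.concatenate(units) if units else np.zeros(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    meta = {"source": "synthetic", "seed": seed, "n_units": n_units,
            "duration": duration, "baseline_rate": baseline_rate,
            "ns_width": ns_width, "ns_times": ns_times.tolist(),
            "ns_peak_rates": peaks.tolist()}
    return SpikeRecord(times=times[order], units=units[order],
                       n_units=n_units, duration=duration, meta=meta)
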