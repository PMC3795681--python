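# nsburst

Spiking-network model and statistics pipeline for spontaneous network
bursting in excitatory cortical cultures.

Dissociated cortical cultures grown on multi-electrode arrays (MEAs)
are spontaneously active: every few seconds to minutes, nearly every
cell fires within a brief (~0.1–0.2 s) window — a *network spike* (NS).
With inhibition pharmacologically blocked, NSs are all-or-none events
that typically arrive in series ("bursts of network spikes", BNS): a
few NSs separated by ~1–3 s, with tens of seconds of silence between
bursts, producing bimodal inter-NS-interval distributions.  `nsburst`
is for computational and experimental neuroscientists who want to
reproduce these statistics in a minimal model and, conversely, to read
network parameters off recorded interval statistics.

The model couples N fully connected conductance-based
leaky-integrate-and-fire neurons

    C_m dV/dt = -g_m (V - V_L) - I_syn - I_AHP + σ-scaled white noise

through AMPA and Mg-block-gated NMDA synapses whose efficacy
W₀·u_j(t)·x_j(t) carries Tsodyks–Markram short-term plasticity
(depression x, recovery τ_x = 0.8 s; facilitation u, recovery
τ_u = 1.6 s), plus a spike-triggered adaptation conductance g_a
(decay τ_Ca of seconds) driving the after-hyperpolarization current
I_AHP = g_a (V − E_AHP).  Depression quenches each NS, facilitation
promotes the next NS of a burst, and slowly accumulating adaptation
terminates the series and enforces the long inter-burst intervals
(IBNSIs).  Burst initiation is well described by a Poisson process with
refractory period: CV = (mean − T)/mean, with T set by adaptation.

The statistics pipeline detects NSs on any raster (50 ms bins, ¼-of-max
threshold), partitions them into BNSs (6 s gaps), computes interval
means/CVs with bootstrap confidence intervals, fits the
refractory-Poisson relation with confidence-box weighting, tests
exponential vs power-law interval tails, and infers a culture's
*working point* — its apparent adaptation timescale τ_Ca and recurrent
weight W₀ — from its (mean IBNSI, CV) alone.

See `docs/methods.md` for model details, calibration of the unprinted
parameters, and numerical choices.

## Worked example

Simulate the baseline network at the reduced problem size and analyze
its bursts:

```python
from nsburst import ModelParams, NetworkConfig, run_simulation
from nsburst import events

cfg = NetworkConfig(params=ModelParams(), N=200, dt=0.1,
                    duration=220.0, seed=11)
record, _ = run_simulation(cfg)
ns = events.detect_ns_record(record)
bns = events.partition_bns(ns)
ib = events.ibnsi(bns)
stats = events.interval_cv(ib, seed=0)
print(f"{len(ns)} NSs in {len(bns)} BNSs")
print(f"mean IBNSI {stats.mean:.1f} s, CV {stats.cv:.2f}")
```

prints

```
48 NSs in 12 BNSs
mean IBNSI 19.8 s, CV 0.80
```

i.e. in 220 s the 200-neuron network produced 48 network spikes grouped
into 12 bursts recurring every ~20 s on average.  A CV near 0 would
mean clock-like bursting (strong excitability), near 1 a Poisson
process (weak excitability); on a short recording like this one the CV
estimate is coarse — longer runs at this baseline settle around
CV ≈ 0.4–0.6, the semi-regular, weakly-synchronized regime where
experimental cultures operate.

The same pipeline runs from the shell:

```
nsburst synth --out raster.csv --ns-times 5,15,25 --peak-rate 120 --duration 40
nsburst detect --raster raster.csv --out events.csv
nsburst stats --raster raster.csv --out stats.json
```

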