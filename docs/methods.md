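# Methods

## The model

`nsburst` simulates spontaneous synchronization in disinhibited (GABA_A
blocked) cultures of cortical neurons as a fully connected network of N
conductance-based leaky integrate-and-fire neurons with three adaptive
mechanisms, and provides the statistics pipeline that turns spike
rasters — simulated or recorded on a multi-electrode array (MEA) — into
network-spike (NS) and burst (BNS) interval statistics.

Membrane potential of each neuron:

    C_m dV/dt = -g_m (V - V_L) - I_syn - I_AHP + noise,

with spike emission at V_thr = -50 mV, reset to V_reset = -55 mV and a
2 ms absolute refractory period.  The white-noise term is scaled so that
the leak-only stationary standard deviation of V equals a parameter
sigma (discretized as `sigma * sqrt(2 dt / tau_m) * N(0,1)` per Euler
step) — a contract on the stationary statistics rather than on the
increments.

Recurrent excitation is glutamatergic only (inhibition is
pharmacologically blocked in the experiments the model emulates):

    I_syn = g_ampa (V - V_E) S_ampa + g_nmda (V - V_E) B(V) S_nmda,
    B(V)  = 1 / (1 + 0.28 exp(-0.062 V)),

where `S` are sums over presynaptic sources of gating variables weighted
by the instantaneous synaptic efficacy `W0 * u_j(t) * x_j(t)`.  AMPA
gating decays with 2 ms; NMDA gating uses a two-variable scheme (2 ms
rise, 100 ms decay, 0.5 kHz saturation rate) that saturates at 1.
Spikes reach all postsynaptic targets after a homogeneous 10 ms
conduction delay.  With the default conductances (0.104 nS AMPA,
0.327 nS NMDA) a unitary event near firing threshold carries roughly
ten times more NMDA than AMPA charge; the optional mixing parameter r
(`g_nmda_eff = r g_nmda`, `g_ampa_eff = 10 (1-r) g_ampa`) re-balances
the two components at approximately constant total charge, and is unset
(unmixed) by default.

Three adaptive mechanisms generate the burst statistics:

- **Short-term depression (STD)** — each presynaptic spike consumes a
  fraction `u` of the available resource `x`, which recovers with
  tau_x = 0.8 s.  STD is the force that quenches each NS.
- **Short-term facilitation (STF)** — the utilization `u` jumps by
  `U (1-u)` per spike and decays with tau_u = 1.6 s > tau_x, so the net
  modulation u*x is transiently *above* baseline after an NS, promoting
  the short (~seconds) intervals inside a burst.
- **Spike-frequency adaptation** — a potassium-like conductance g_a
  (reversal -80 mV) increments by dg_a per spike and decays with
  tau_ca (seconds).  It accumulates across the NSs of a burst,
  terminates the series, and enforces the long inter-burst intervals.

The separation tau_ca >> tau_u > tau_x is essential: with tau_ca at or
below tau_u the adaptation conductance cannot accumulate across
successive NSs and burst termination becomes stochastic, producing
unrealistically long bursts (`experiments.timescale_separation_study`).

## Calibration of unprinted parameters

Four parameters are not fixed by electrophysiology and are set by
calibration (`experiments.calibrate_sigma`, `calibrate_adaptation`),
with the shipped defaults being the calibration outputs:

- **sigma = 6.5 mV** — bisected so that an isolated neuron (W0 = 0)
  fires with ~2 s mean inter-spike interval (measured 2.06 s).
- **U = 0.05** — baseline utilization.  Small U is required by the
  mechanism itself: the quiescent-state depolarization from recurrent
  drive scales as `N * rate * W0 * U * q_unit / g_m` (q_unit ≈ 130 fC is
  the unitary charge).  With U in the depressing-synapse range (~0.5)
  this exceeds the 20 mV distance to threshold at ~1 Hz background
  rates, locking the network in a tonic asynchronous state with no
  all-or-none events.  U ≈ 0.05 (the facilitating-synapse range of the
  short-term plasticity literature, consistent with the ~1.8 s
  facilitation time constant adopted here) gives a stable ~1
  spike/unit/s quiescent state, several-fold facilitation within a
  burst, and all-or-none NSs with peak rates above 100 spikes/unit/s.
- **W0 = 6.5 baseline** — with the calibrated U, the bursting regime
  spans W0 ≈ 5.4–7.2: below, network spikes become vanishingly rare;
  above, the quiescent state destabilizes into tonic firing.  The
  baseline sits mid-range and yields 2–6 NSs per BNS with inter-burst
  intervals of 10–60 s.
- **dg_a = 0.1 nS at tau_ca = 4 s** — grid-searched so the baseline
  produces that same regime.  When comparing adaptation timescales the
  product `dg_a * tau_ca` is held constant, which preserves the
  steady-state adaptation conductance per unit firing rate.

## Detection and statistics

Spikes from all units are counted in 50 ms bins; an NS is a maximal run
of contiguous bins at or above one quarter of the session-maximum bin
count.  The NS reference time is the center of the run's peak bin, its
magnitude the summed count over the run (no flank extension — the
simplest rule consistent with "total spikes emitted").  NSs separated
by peak-to-peak gaps above 6 s are split into separate bursts; the
inter-BNS interval (IBNSI) is measured onset-to-onset (the natural
observable for an event-initiation point process; offset-to-onset is
available as an option).  In the all-or-none regime detection is
insensitive to the threshold fraction (0.2 vs 0.3 changes nothing on
baseline runs).

Interval samples get sample-sd (n-1) CVs with percentile-bootstrap 95%
confidence intervals (B = 1000, seeded; skipped below 10 intervals).
The Poisson-with-refractory-period relation `CV = (mean - T)/mean` is
fitted by weighted least squares with weights inverse to the
confidence-box area (equal weights, with a logged warning, when boxes
are degenerate); the model is linear in T, so the constrained minimizer
(T >= 0) is closed-form and exact on noiseless inputs.  Interval-tail
hypotheses (shifted exponential vs continuous power law above a fixed
xmin, default the 6 s gap threshold) are fitted by maximum likelihood
and tested with one-sample KS statistics whose null distributions come
from a parametric bootstrap with refitting (B = 500); the exact test
variant behind the original analysis is not identifiable from its
citation, so this standard procedure is used and documented.

Working-point inference inverts the sweep curve family: for each
tau_ca-curve the CV and W0 are interpolated at the query mean (linear in
log-mean), then tau_ca is interpolated linearly in CV between the two
bracketing curves.  Queries outside the family raise an error carrying
the clipped estimate.

## Numerical choices

- Forward Euler, default step 25 µs (full fidelity); gating and slow
  variables use exact per-step exponential factors; the NMDA open
  fraction uses an exponential-Euler step (rise variable frozen over the
  step), unconditionally bounded in [0, 1].
- Conduction delays are rounded to the nearest integer number of steps
  (minimum one); spikes affect STP and adaptation at emission and gating
  one delay later.
- Full homogeneous connectivity makes the weighted gating sums shared
  across postsynaptic neurons up to each neuron's own term, which keeps
  the cost per step O(N); autapses are excluded.  The optional sparse
  mode (p < 1) uses explicit in-neighbor lists; p = 1 routes to the
  full-connectivity path.
- When N != 800, conductances scale by 800/N to preserve the total
  recurrent drive.
- One seeded RNG stream per execution chunk with a fixed draw order
  (one normal per neuron per step) makes runs bit-deterministic given
  (config, seed).
- Initial state: V uniform in [V_L, V_thr), u = U, x = 1, g_a = 0; the
  first 5 s are discarded.
- Runs with a BNS-count stopping rule execute in 20 s chunks and re-run
  detection on the accumulated raster after each chunk, counting only
  completed bursts.

## Problem sizes

Full fidelity is N = 800 at dt = 25 µs.  The package's default test and
experiment profile scales this down to N = 200 (conductances x4) at
dt = 0.1 ms, which preserves the regime (quiescent ~1 Hz, NS peaks
>100 spikes/unit/s, 2-6 NSs/BNS, IBNSIs of tens of seconds) at roughly
1/30 the cost.  The acceptance script runs the magnitude-statistics
baseline at N = 800, dt = 0.1 ms.  The first-NS magnitude distribution
has a tight core (spread of a few percent of the mean) plus occasional
half-magnitude outliers — weak re-ignitions just past the 6 s gap
threshold, while the network is still partially adapted — so its
sd/mean statistic varies severalfold between runs with the number of
such events.

## What the synthetic rasters do and do not emulate

`synth.synth_raster` plants half-cosine rate bumps (default 100 ms wide)
on a ~1 spike/unit/s homogeneous Poisson background across 60 units,
emulating the shape of a disinhibited-culture MEA recording.  It
exercises every detection/statistics path with known ground truth, but
its spikes are independent across units and carry no refractoriness,
no STP and no adaptation — passing round-trip tests on it validates the
statistics pipeline, not the network model.

## Known limitations

- Homogeneous neurons and weights: no "privileged" early-firing units,
  no modular connectivity, no power-law NS magnitudes.
- Inhibitory conductance parameters are parsed and carried but never
  simulated (the modeled preparations have GABA_A blocked).
- The scaled profile's W0 axis is not numerically comparable to a
  different (N, U, r) parameterization; curves must be regenerated per
  configuration before working-point inference.
- Euler integration at 0.1 ms slightly smooths within-NS dynamics
  relative to 25 µs; NS rates per unit time remain statistically
  consistent between the two steps.
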