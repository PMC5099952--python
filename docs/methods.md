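# Methods

This note documents the models, defaults and numerical choices behind
`neurosync`, and what the synthetic benchmark does and does not show about
real recordings.

## The synthetic session model

A session is a realisation of a three-layer generative model.

**Burst schedule.** Time alternates between silences and entire bursts,
both drawn uniformly from configured ranges (silences 2–40 s, entire bursts
0.05–5 s by default). Each entire burst is tiled with sub-bursts (30–300 ms)
separated by gaps (20–80 ms); the last sub-burst is truncated at the burst
end, and a sub-burst is kept whenever its onset precedes that end. Uniform
draws are the least-assumptive choice given that only ranges are known for
these timescales. All intervals are half-open `[onset, offset)` in seconds
from the session origin. Within-sub-burst rate profiles are flat by default
(an `envelope_gain` multiplier per sub-burst is available for ramped or
heterogeneous bursts); real cultures presumably have richer within-burst
structure, which nothing downstream depends on.

**Network spikes.** Each electrode is an independent inhomogeneous Poisson
process with a piecewise-constant intensity: 0.02 Hz per electrode in
silences ("vanishing" background activity) and 100 Hz per electrode inside
sub-bursts. The peak value represents dense-culture *multi-unit* activity
seen by one extracellular electrode during a network burst; it also keeps
the 20 Hz network-rate crossing threshold far below the in-burst rate, so
crossing statistics are dominated by burst edges rather than shot noise.
With the default duty cycle this yields session-mean rates of a few Hz per
electrode, the scale observed in spontaneously active cultures.

**Membrane potential.** Vm = baseline (−70 mV; −75 mV is common in some
preparations and available via `vm_baseline_mv`) + EPSP envelope +
stereotyped action potentials. The envelope is the network intensity *in
excess of baseline*, convolved with a causal exponential kernel
(τ = 30 ms, unit area), delayed by the network→neuron lag (default 16 ms,
configurable 0–50 ms), and scaled by 0.3 mV/Hz — about +30 mV at the
100 Hz peak, matching the tens-of-mV depolarizations seen during bursts.
Action potentials are ~2 ms Gaussian bumps of 100 mV amplitude, so they
always overshoot 0 mV and are the only crossings of the −25 mV detection
threshold.

**Evoked spikes.** In *correlated* mode each sub-burst evokes one
onset-locked spike at `onset + lag + Exp(2 ms)` (truncated to the window)
plus Poisson extras (10 Hz) inside the lag-shifted sub-burst. The one-sided
exponential response jitter keeps every spike inside the lag-shifted
interval and makes the crossing-delay statistic an estimator of the lag.
In *anti-correlated* mode spikes are drawn (20 Hz) only in
`[sub-burst offset + lag, next sub-burst onset)` within an entire burst:
the neuron fires when the network packet releases it, a lag after each
packet ends, and is silenced again once the next packet begins. This
construction guarantees zero spikes inside any sub-burst whether or not a
downstream classifier compensates the lag.

**Clocks and triggers.** Network data live on the array clock (origin 0).
Patch timestamps are mapped through an affine clock model
`t' = (1 + drift)·t + offset` (defaults: drift 1e-5, offset 0.3 s). The
array emits one trigger per second; the patch system records it with 5 μs
Gaussian timing jitter. Only trigger *observations* are jittered — the
clock mapping itself is deterministic — which is why corrected event
timestamps are far more accurate than a single trigger.

**Determinism.** All randomness derives from one seed through named
sub-streams (schedule, per-channel spikes, per-channel noise, per-patch,
triggers), so identical `(config, seed)` give bit-identical sessions and
adding a channel or patch never shifts other components' draws.

## What the benchmark does not emulate

Spatial structure (the lag is a single scalar, not a propagating wave),
electrode-to-electrode rate heterogeneity beyond independent Poisson draws,
biophysical spike shapes and adaptation, bursts initiated at varying
locations, non-stationarity over minutes, and electrode drift or artifacts.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to every pathology of real recordings.

## Analysis choices

- **Spike detection.** Threshold = 6 × SD of the smoothed, mean-subtracted
  trace, SD taken over the entire trace (a median-based robust scale is
  available but not default). Polarity defaults to `both` (absolute value).
  Events are local extrema of the detection signal above threshold; events
  closer than the 1 ms dead time to a larger event are suppressed,
  largest first. Processing extrema in descending amplitude makes the
  detector provably monotone in the threshold (raising it can never create
  detections), which a run-based event definition does not guarantee when a
  supra-threshold run splits in two. The event timestamp is the extremum
  time (`timestamp="crossing"` selects the first supra-threshold sample
  instead). Near-coincident spikes within the dead time are reported as one
  event; overlap resolution is out of scope.
- **Smoothing.** Unit-sum sampled Gaussian kernel truncated at ±5 SD,
  symmetric edge padding; equivalent to direct-sum convolution to better
  than 1e-9 relative (enforced by test).
- **Rate estimation.** Exact per-spike Gaussian evaluation on a uniform
  grid (dt = 0.5 ms, ≥ 4 samples per 2 ms kernel SD), kernel truncated at
  ±5 SD (mass deficit < 1e-6). Division is by the *configured* electrode
  count, not the active count, so silent channels do not inflate the rate.
- **Crossings.** Upward crossing = transition from strictly below to
  at-or-above threshold, instant linearly interpolated; a series starting
  above threshold contributes no crossing. Vm crossings use the raw trace
  with a 1 ms dead time.
- **Delay distribution.** Signed delta = target − reference (membrane
  minus network); nearest-neighbour pairing with no censoring window, so
  every reference crossing contributes. Histogram bins 2 ms. The headline
  statistic is the mean of |delta|.
- **Conditional densities.** Strict `>` for "above the mean"; ties count
  as below. Bins 1 mV. Normalisation by total sample count makes the two
  densities jointly (not individually) integrate to 1.
- **Burst detection.** Onset threshold 5 Hz; `merge_gap` exposes the two
  burst scales through one algorithm. The pipeline applies a 20 ms minimum
  burst duration — shorter than any configured sub-burst — because a chance
  coincidence of two background spikes can lift a 2 ms sliver of `r(t)`
  above 5 Hz, which no practitioner would call a burst. `detect_bursts`
  itself defaults to no minimum.
- **Mode classification.** The ±0.5 index cutoffs are this package's
  definition (symmetric, scale-free); the underlying phenomenon is
  qualitative. Spikes outside entire bursts are ignored. A lag estimate
  may be supplied to shift the sub-burst intervals; the anti-correlated
  generator construction keeps the classification correct for any
  compensation between 0 and the minimum gap.
- **Clock sync.** Leader = array clock, triggers paired by order. Affine
  least-squares fit by default (the leader times are centred before the
  fit for conditioning); a piecewise-linear model through the trigger pairs
  (zero residual at knots) handles slow drift wander when the affine
  residual SD exceeds tolerance. Dropped-trigger recovery is out of scope
  by default. Forward/inverse mapping round-trips to 1e-12 s.
- **I/O.** Sessions round-trip through an HDF5 container (extracellular
  voltage as int16 with a 0.1 μV scale attribute, everything else float);
  voltage arrays are loaded eagerly — synthetic sessions are small and this
  lets the file handle close. Spike lists round-trip as `channel,time_s`
  CSV; unsorted rows are sorted on load with a warning.

## Problem sizes

The test and acceptance workloads use sessions of 8–120 s with 6–60
electrodes, voltage sampled at 1–20 kHz where traces are needed (schedule
and spike generation are independent of the sampling rate, so a reduced
rate only coarsens rendered waveforms), and 50 × 600 s trigger simulations
for the clock study. These sizes give stable statistics for every assertion
(e.g. ≥ 20 crossings per delay estimate, ≥ 3000 Poisson counts per
calibration check) while keeping the full suite to a few minutes on one
CPU.

## Known limitations

The anti-correlated index depends on detected sub-burst edges, which extend
a few ms beyond the true intervals (kernel rise time); gap spikes very near
a sub-burst edge can therefore be counted as in-burst, biasing the index
toward 0 by roughly `2·(edge width)/(mean gap)`. The delay statistic is
upward-biased by the evoked-spike response jitter (~+2 ms) and the rate
rise time (~+1–3 ms); it estimates the lag's scale, not its exact value.
Electrodes are statistically identical; per-electrode rate maps carry no
information in this benchmark.
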