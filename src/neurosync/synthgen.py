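"""Synthetic dual-modality recording sessions with known ground truth.

Cultured cortical networks on a multi-electrode array fire in hierarchical
bursts: seconds-long "entire bursts" separated by silences of up to dozens of
seconds, each composed of sub-bursts of a few dozen to a few hundred
milliseconds separated by a few dozen milliseconds of near-silence.  A
patched neuron tracks this cooperative activity: its membrane potential is
depolarised tens of mV above baseline throughout an entire burst (summed
EPSPs), and its evoked spikes fall either inside the sub-bursts (correlated
mode, with a synaptic/propagation lag of up to ~50 ms) or only in the gaps
between them (anti-correlated mode).

This module generates such sessions — burst schedule, per-electrode spike
trains, raw extracellular voltage, membrane-potential traces, and trigger
streams on two drifting clocks — together with the full ground truth, so
that every downstream estimator can be validated against known answers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from .clocksync import ClockModel, apply_clock_model
from .types import SpikeTrainSet, VoltageTrace

__all__ = [
    "SessionConfig",
    "BurstSchedule",
    "GroundTruth",
    "PatchRecording",
    "SessionBundle",
    "sample_burst_schedule",
    "generate_network_spikes",
    "render_extracellular",
    "render_intracellular",
    "coverage_fraction",
    "generate_session",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent sub-stream for one component of the simulation.

    Derived from the session seed via a spawn key so that adding a channel
    or a patch does not shift any other component's draws.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# spawn-key domains
_DOM_SCHEDULE = 0
_DOM_NETWORK = 1
_DOM_NOISE = 2
_DOM_PATCH = 3
_DOM_TRIGGER = 4


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one synthetic session.

    Durations of entire bursts, silences, sub-bursts and gaps are drawn
    uniformly within the configured (low, high) ranges.  Rates are per
    electrode (multi-unit); the sub-burst peak rate of 100 Hz/electrode
    reflects dense-culture multi-unit activity during network bursts, the
    0.02 Hz baseline the near-vanishing activity between bursts.
    """

    n_electrodes: int = 60
    fs: float = 50_000.0
    duration: float = 60.0
    entire_burst_s: tuple[float, float] = (0.05, 5.0)
    silence_s: tuple[float, float] = (2.0, 40.0)
    sub_burst_ms: tuple[float, float] = (30.0, 300.0)
    gap_ms: tuple[float, float] = (20.0, 80.0)
    baseline_rate_hz: float = 0.02
    peak_rate_hz: float = 100.0
    envelope_gain_range: tuple[float, float] = (1.0, 1.0)
    vm_baseline_mv: float = -70.0
    epsp_gain_mv_per_hz: float = 0.3
    epsp_tau_ms: float = 30.0
    patch_modes: tuple[str, ...] = ("correlated",)
    patch_rate_hz: float = 10.0
    lag_ms: float = 16.0
    ap_amplitude_mv: float = 100.0
    spike_amplitude_uv: float = 80.0
    noise_sd_uv: float = 5.0
    clock_drift: float = 1e-5
    clock_offset_s: float = 0.3
    trigger_period_s: float = 1.0
    trigger_jitter_us: float = 5.0
    blockers: bool = False
    render_voltage: bool = False

    def __post_init__(self) -> None:
        for name in ("entire_burst_s", "silence_s", "sub_burst_ms", "gap_ms",
                     "envelope_gain_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= low <= high")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.lag_ms < 0:
            raise ValueError("lag must be non-negative")
        if self.baseline_rate_hz < 0 or self.peak_rate_hz < 0 or self.patch_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        for mode in self.patch_modes:
            if mode not in ("correlated", "anticorrelated"):
                raise ValueError(f"unknown patch mode {mode!r}")


@dataclass(frozen=True)
class BurstSchedule:
    """Two-level burst timing: entire bursts and their nested sub-bursts.

    ``entire_bursts`` is a list of ``(onset, offset)`` pairs in seconds;
    ``sub_bursts`` a list of ``(onset, offset, parent_index)``;
    ``envelope_gain`` one rate multiplier per sub-burst.  All intervals are
    half-open, sorted, disjoint within a level, and sub-bursts are nested
    inside their parent entire burst.
    """

    entire_bursts: tuple[tuple[float, float], ...]
    sub_bursts: tuple[tuple[float, float, int], ...]
    envelope_gain: tuple[float, ...]

    def __post_init__(self) -> None:
        prev = -np.inf
        for on, off in self.entire_bursts:
            if off <= on or on < prev:
                raise ValueError("entire bursts must be sorted, disjoint, non-empty")
            prev = off
        prev = -np.inf
        for on, off, parent in self.sub_bursts:
            if off <= on or on < prev:
                raise ValueError("sub-bursts must be sorted, disjoint, non-empty")
            p_on, p_off = self.entire_bursts[parent]
            if on < p_on - 1e-12 or off > p_off + 1e-12:
                raise ValueError("sub-burst not nested in its parent burst")
            prev = off
        if len(self.envelope_gain) != len(self.sub_bursts):
            raise ValueError("one envelope gain per sub-burst required")

    @property
    def n_entire(self) -> int:
        return len(self.entire_bursts)

    @property
    def n_sub(self) -> int:
        return len(self.sub_bursts)

    def sub_intervals(self) -> np.ndarray:
        """(n_sub, 2) array of sub-burst [onset, offset) pairs."""
        if not self.sub_bursts:
            return np.empty((0, 2))
        return np.array([(on, off) for on, off, _ in self.sub_bursts])

    def gap_intervals(self) -> list[tuple[float, float]]:
        """Within-burst gaps between consecutive sub-bursts of one parent."""
        gaps = []
        for i in range(len(self.sub_bursts) - 1):
            on0, off0, p0 = self.sub_bursts[i]
            on1, _off1, p1 = self.sub_bursts[i + 1]
            if p0 == p1 and on1 > off0:
                gaps.append((off0, on1))
        return gaps


@dataclass(frozen=True)
class PatchRecording:
    """One patched neuron: membrane potential and true evoked spikes."""

    spike_times: np.ndarray
    mode: str
    voltage: Optional[VoltageTrace] = None
    clock_id: str = "patch"

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_times", np.asarray(self.spike_times, dtype=float))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows: the answers the estimators must find."""

    schedule: BurstSchedule
    network_spikes: SpikeTrainSet
    patch_spikes: tuple[np.ndarray, ...]      # session-clock times per patch
    patch_modes: tuple[str, ...]
    lag_ms: float
    clock_model: ClockModel
    vm_envelopes: tuple[Optional[VoltageTrace], ...] = ()


@dataclass(frozen=True)
class SessionBundle:
    """A complete dual-modality recording session.

    Network data live on ``leader_clock`` (the array clock, session time
    origin 0); patch data are timestamped on ``patch_clock`` until
    :func:`neurosync.clocksync.synchronize_session` is applied.
    """

    config: SessionConfig
    mea_spikes: SpikeTrainSet
    patches: tuple[PatchRecording, ...]
    triggers: dict
    mea_traces: tuple[VoltageTrace, ...] = ()
    ground_truth: Optional[GroundTruth] = None
    leader_clock: str = "mea"
    patch_clock: str = "patch"
    clock_model: Optional[ClockModel] = None
    sync_report: Optional[dict] = None


# ---------------------------------------------------------------------------
# schedule


def sample_burst_schedule(config: SessionConfig, seed: int) -> BurstSchedule:
    """Draw the alternating silence / entire-burst / sub-burst structure.

    The session starts with a silence; silences and entire-burst durations
    are drawn uniformly from the configured ranges, and each entire burst is
    tiled with sub-bursts and gaps (uniform draws) until its duration is
    filled, truncating the final interval at the burst (or session) end.
    Deterministic given ``(config, seed)``.
    """
    rng = _rng(seed, _DOM_SCHEDULE)
    duration = config.duration
    if config.blockers:
        return BurstSchedule((), (), ())
    entire: list[tuple[float, float]] = []
    subs: list[tuple[float, float, int]] = []
    gains: list[float] = []
    t = 0.0
    while True:
        t += rng.uniform(*config.silence_s)
        if t >= duration:
            break
        burst_dur = rng.uniform(*config.entire_burst_s)
        offset = min(t + burst_dur, duration)
        parent = len(entire)
        entire.append((t, offset))
        s = t
        while s < offset:
            e = min(s + rng.uniform(*config.sub_burst_ms) * 1e-3, offset)
            subs.append((s, e, parent))
            gains.append(rng.uniform(*config.envelope_gain_range))
            s = e + rng.uniform(*config.gap_ms) * 1e-3
        t = offset
    if duration > 0 and not entire and not config.blockers:
        warnings.warn("degenerate config: session too short for a single burst; "
                      "schedule is empty", stacklevel=2)
    return BurstSchedule(tuple(entire), tuple(subs), tuple(gains))


# ---------------------------------------------------------------------------
# spikes


def _intensity_segments(schedule: BurstSchedule, config: SessionConfig
                        ) -> list[tuple[float, float, float]]:
    """Piecewise-constant network intensity (start, stop, rate Hz/electrode)."""
    base = config.baseline_rate_hz
    segs: list[tuple[float, float, float]] = []
    t = 0.0
    for (on, off, _parent), gain in zip(schedule.sub_bursts, schedule.envelope_gain):
        if on > t:
            segs.append((t, on, base))
        segs.append((on, off, config.peak_rate_hz * gain))
        t = off
    if t < config.duration:
        segs.append((t, config.duration, base))
    return segs


def generate_network_spikes(schedule: BurstSchedule, config: SessionConfig,
                            seed: int) -> SpikeTrainSet:
    """Per-electrode inhomogeneous Poisson spikes from the burst schedule.

    Intensity is the baseline rate outside sub-bursts and
    ``peak_rate_hz * envelope_gain`` inside each sub-burst.  Each channel
    uses its own RNG sub-stream.
    """
    if config.baseline_rate_hz < 0 or config.peak_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    segments = _intensity_segments(schedule, config)
    trains = []
    for ch in range(config.n_electrodes):
        rng = _rng(seed, _DOM_NETWORK, ch)
        times = []
        for start, stop, rate in segments:
            if rate <= 0 or stop <= start:
                continue
            n = rng.poisson(rate * (stop - start))
            if n:
                times.append(start + rng.random(n) * (stop - start))
        train = np.sort(np.concatenate(times)) if times else np.empty(0)
        trains.append(train)
    return SpikeTrainSet(tuple(trains), clock_id="mea")


# ---------------------------------------------------------------------------
# voltage rendering


def _biphasic_template(fs: float, amplitude_uv: float) -> tuple[np.ndarray, int]:
    """Stereotyped ~1 ms extracellular spike: sharp negative lobe, slower
    positive rebound.  Returns (template, index of the negative peak)."""
    t = np.arange(-0.5e-3, 1.0e-3, 1.0 / fs)
    neg = np.exp(-0.5 * (t / 0.1e-3) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((t - 0.35e-3) / 0.25e-3) ** 2)
    shape = -neg + pos
    shape /= np.abs(shape).max()
    template = amplitude_uv * shape
    return template, int(np.argmin(template))


def _ap_template(fs: float, amplitude_mv: float) -> tuple[np.ndarray, int]:
    """Stereotyped ~2 ms intracellular action potential (depolarising bump)."""
    t = np.arange(-1.0e-3, 1.0e-3, 1.0 / fs)
    shape = np.exp(-0.5 * (t / 0.3e-3) ** 2)
    return amplitude_mv * shape, int(np.argmax(shape))


def _add_templates(signal: np.ndarray, fs: float, times: np.ndarray,
                   template: np.ndarray, peak_idx: int) -> None:
    """Add ``template`` to ``signal`` with its peak at each event time,
    truncating templates that overhang the trace edges."""
    n = signal.size
    m = template.size
    for t in np.asarray(times, dtype=float):
        centre = int(round(t * fs))
        start = centre - peak_idx
        lo = max(start, 0)
        hi = min(start + m, n)
        if hi <= lo:
            continue
        signal[lo:hi] += template[lo - start:hi - start]


def render_extracellular(spikes: SpikeTrainSet, config: SessionConfig,
                         seed: int, channels: Optional[Sequence[int]] = None
                         ) -> list[VoltageTrace]:
    """Raw per-channel voltage: Gaussian noise plus a biphasic spike template
    centred (negative peak) at each spike time."""
    n_samples = int(round(config.duration * config.fs))
    template, peak_idx = _biphasic_template(config.fs, config.spike_amplitude_uv)
    if channels is None:
        channels = range(len(spikes.trains))
    traces = []
    for ch in channels:
        train = spikes.trains[ch]
        if train.size and train.max() >= config.duration:
            raise ValueError("spike times must lie within the session duration")
        rng = _rng(seed, _DOM_NOISE, int(ch))
        sig = rng.normal(0.0, config.noise_sd_uv, n_samples) if config.noise_sd_uv > 0 \
            else np.zeros(n_samples)
        _add_templates(sig, config.fs, train, template, peak_idx)
        traces.append(VoltageTrace(sig, fs=config.fs, t0=0.0, unit="uV", clock_id="mea"))
    return traces


def _network_intensity_trace(schedule: BurstSchedule, config: SessionConfig,
                             n_samples: int) -> np.ndarray:
    """Per-electrode network intensity (Hz) sampled on the voltage grid."""
    intensity = np.full(n_samples, config.baseline_rate_hz)
    for (on, off, _p), gain in zip(schedule.sub_bursts, schedule.envelope_gain):
        i0 = int(round(on * config.fs))
        i1 = min(int(round(off * config.fs)), n_samples)
        intensity[i0:i1] = config.peak_rate_hz * gain
    return intensity


def sample_patch_spikes(schedule: BurstSchedule, mode: str, config: SessionConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """True evoked spike times of the patched neuron, on the session clock.

    Correlated mode: one onset-locked spike per sub-burst at
    ``onset + lag + Exp(2 ms)`` (truncated to the lag-shifted window), plus
    Poisson extras inside the lag-shifted sub-burst.  Anti-correlated mode:
    Poisson spikes only in ``[sub-burst offset + lag, next sub-burst onset)``
    within an entire burst, so no spike falls inside any sub-burst whether
    or not the lag is compensated downstream.
    """
    lag = config.lag_ms * 1e-3
    times: list[float] = []
    if mode == "correlated":
        for on, off, _p in schedule.sub_bursts:
            w0, w1 = on + lag, off + lag
            first = w0 + rng.exponential(2e-3)
            if first < w1:
                times.append(first)
            n = rng.poisson(config.patch_rate_hz * (w1 - w0))
            times.extend(w0 + rng.random(n) * (w1 - w0))
    elif mode == "anticorrelated":
        for g0, g1 in schedule.gap_intervals():
            w0, w1 = g0 + lag, g1
            if w1 <= w0:
                continue
            n = rng.poisson(2.0 * config.patch_rate_hz * (w1 - w0))
            times.extend(w0 + rng.random(n) * (w1 - w0))
    else:
        raise ValueError(f"unknown patch mode {mode!r}")
    t = np.sort(np.asarray(times, dtype=float))
    return t[(t >= 0) & (t < config.duration)]


def render_intracellular(schedule: BurstSchedule, mode: str, config: SessionConfig,
                         seed: int, patch_index: int = 0,
                         spike_times: Optional[np.ndarray] = None
                         ) -> tuple[VoltageTrace, np.ndarray, VoltageTrace]:
    """Membrane potential of one patched neuron on the session clock.

    Vm = baseline + EPSP envelope + stereotyped action potentials.  The
    envelope is the network intensity convolved with an exponential synaptic
    kernel (``epsp_tau_ms``), delayed by the network-to-neuron lag and scaled
    by ``epsp_gain_mv_per_hz``, raising Vm tens of mV during bursts.

    Returns ``(vm_trace, true_spike_times, envelope_trace)``; the envelope
    trace (Vm without action potentials) is part of the ground truth.
    """
    if mode not in ("correlated", "anticorrelated"):
        raise ValueError(f"unknown patch mode {mode!r}")
    rng = _rng(seed, _DOM_PATCH, patch_index)
    n_samples = int(round(config.duration * config.fs))
    fs = config.fs
    # depolarizing drive: network intensity in excess of the silent baseline
    drive = _network_intensity_trace(schedule, config, n_samples) \
        - config.baseline_rate_hz

    # causal exponential synaptic kernel, unit area, truncated at 8 tau
    tau = config.epsp_tau_ms * 1e-3
    k_t = np.arange(0, 8 * tau, 1.0 / fs)
    kernel = np.exp(-k_t / tau)
    kernel /= kernel.sum()
    env = np.convolve(drive, kernel)[:n_samples]
    lag_samples = int(round(config.lag_ms * 1e-3 * fs))
    if lag_samples:
        env = np.concatenate([np.zeros(lag_samples), env[:-lag_samples]]) \
            if lag_samples < n_samples else np.zeros(n_samples)
    vm_env = config.vm_baseline_mv + config.epsp_gain_mv_per_hz * env

    if spike_times is None:
        spike_times = sample_patch_spikes(schedule, mode, config, rng)
    vm = vm_env.copy()
    ap, ap_peak = _ap_template(fs, config.ap_amplitude_mv)
    _add_templates(vm, fs, spike_times, ap, ap_peak)

    trace = VoltageTrace(vm, fs=fs, t0=0.0, unit="mV", clock_id="mea")
    env_trace = VoltageTrace(vm_env, fs=fs, t0=0.0, unit="mV", clock_id="mea")
    return trace, spike_times, env_trace


# ---------------------------------------------------------------------------
# geometry


def coverage_fraction(array_rows: int, array_cols: int, pitch_mm: float,
                      culture_area_cm2: float) -> float:
    """Percentage of the culture area covered by the electrode-array footprint.

    The footprint spans ``(rows - 1) * pitch`` by ``(cols - 1) * pitch``
    (electrode centres at the grid nodes), e.g. a 6 x 10 grid at 0.5 mm pitch
    covers 2.5 mm x 4.5 mm, about 2% of a 5 cm^2 culture.
    """
    if array_rows <= 0 or array_cols <= 0 or pitch_mm <= 0:
        raise ValueError("array dimensions and pitch must be positive")
    if culture_area_cm2 <= 0:
        raise ValueError("culture area must be positive")
    footprint_mm2 = ((array_rows - 1) * pitch_mm) * ((array_cols - 1) * pitch_mm)
    return 100.0 * footprint_mm2 / (culture_area_cm2 * 100.0)


# ---------------------------------------------------------------------------
# full session


def generate_session(config: SessionConfig, seed: int) -> tuple[SessionBundle, GroundTruth]:
    """Compose a full dual-modality session with ground truth.

    Network spikes (and optionally raw extracellular voltage) live on the
    array clock; patch spike times and traces are timestamped on the patch
    clock via the configured drift/offset model; periodic leader triggers are
    emitted on the array clock and observed (with timing jitter) on the patch
    clock.  Bit-reproducible given ``(config, seed)``.
    """
    schedule = sample_burst_schedule(config, seed)
    net_spikes = generate_network_spikes(schedule, config, seed)

    clock = ClockModel(offset=config.clock_offset_s, drift=config.clock_drift)
    trig_rng = _rng(seed, _DOM_TRIGGER)
    leader_triggers = np.arange(0.0, config.duration, config.trigger_period_s)
    jitter = trig_rng.normal(0.0, config.trigger_jitter_us * 1e-6, leader_triggers.size)
    laggard_triggers = apply_clock_model(leader_triggers, clock) + jitter

    patches = []
    truth_spikes = []
    envelopes = []
    for k, mode in enumerate(config.patch_modes):
        vm, spikes_true, env = render_intracellular(schedule, mode, config, seed,
                                                    patch_index=k)
        # timestamp patch data on its own (drifting) clock
        patch_spike_times = apply_clock_model(spikes_true, clock)
        vm_patch = replace(vm, t0=float(apply_clock_model(np.array([0.0]), clock)[0]),
                           fs=config.fs / (1.0 + config.clock_drift), clock_id="patch")
        patches.append(PatchRecording(spike_times=patch_spike_times, mode=mode,
                                      voltage=vm_patch, clock_id="patch"))
        truth_spikes.append(spikes_true)
        envelopes.append(env)

    mea_traces: tuple[VoltageTrace, ...] = ()
    if config.render_voltage:
        mea_traces = tuple(render_extracellular(net_spikes, config, seed))

    truth = GroundTruth(schedule=schedule, network_spikes=net_spikes,
                        patch_spikes=tuple(truth_spikes),
                        patch_modes=tuple(config.patch_modes),
                        lag_ms=config.lag_ms, clock_model=clock,
                        vm_envelopes=tuple(envelopes))
    bundle = SessionBundle(config=config, mea_spikes=net_spikes,
                           patches=tuple(patches),
                           triggers={"mea": leader_triggers, "patch": laggard_triggers},
                           mea_traces=mea_traces, ground_truth=truth)
    return bundle, truth
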