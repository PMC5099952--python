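"""Correspondence statistics between network rate and the patched neuron.

Implements the threshold-crossing statistics that quantify how a single
neuron reflects network activity: upward threshold crossings of the rate
(20 Hz) and of the membrane potential (-25 mV), the distribution of shortest
time differences between the two crossing streams, the membrane-potential
density conditioned on the rate being above or below its mean, burst
detection at the 5 Hz onset criterion, and classification of a patched
neuron as correlated or anti-correlated with the network's sub-bursts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .types import BurstEvent, RateSeries, VoltageTrace

__all__ = [
    "CrossingSet",
    "DelayDistribution",
    "ConditionalDensityPair",
    "CorrelationReport",
    "upward_crossings",
    "detect_bursts",
    "delay_distribution",
    "conditional_vm_density",
    "classify_mode",
]


@dataclass(frozen=True)
class CrossingSet:
    """Sorted times of upward threshold crossings."""

    times: np.ndarray
    threshold: float
    direction: str = "up"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("crossing times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DelayDistribution:
    """Signed shortest delays (ms) from reference to nearest target crossing."""

    deltas_ms: np.ndarray
    bin_edges_ms: np.ndarray
    probabilities: np.ndarray
    mean_abs_delay_ms: float

    def __post_init__(self) -> None:
        if self.probabilities.size and not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("histogram probabilities must sum to 1")
        if self.mean_abs_delay_ms < 0:
            raise ValueError("mean absolute delay must be non-negative")


@dataclass(frozen=True)
class ConditionalDensityPair:
    """Membrane-potential densities conditioned on the network rate.

    Both densities are normalised by the total sample count, so they
    integrate to 1 jointly (not individually): the integral of each equals
    the fraction of time the rate spends on that side of the split.
    """

    bin_edges_mv: np.ndarray
    density_above: np.ndarray
    density_below: np.ndarray
    split_hz: float

    def joint_integral(self) -> float:
        widths = np.diff(self.bin_edges_mv)
        return float(np.sum((self.density_above + self.density_below) * widths))


@dataclass(frozen=True)
class CorrelationReport:
    """Correlated / anti-correlated classification of one patched neuron."""

    index: float
    n_in: int
    n_out: int
    label: str

    def __post_init__(self) -> None:
        total = self.n_in + self.n_out
        if total > 0:
            expected = (self.n_in - self.n_out) / total
            if not np.isclose(self.index, expected):
                raise ValueError("index inconsistent with counts")


SeriesLike = Union[RateSeries, VoltageTrace]


def _times_values(series: SeriesLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, RateSeries):
        return series.times, series.values
    return series.times, series.samples


def upward_crossings(series: SeriesLike, threshold: float,
                     dead_time_ms: float = 0.0) -> CrossingSet:
    """Times where the signal transitions from below to at-or-above threshold.

    The crossing instant is linearly interpolated between the bracketing
    samples.  A series that starts at or above threshold contributes no
    crossing until it first drops below.  ``dead_time_ms`` optionally
    suppresses crossings closer than the dead time to the previous kept one
    (used for membrane-potential crossings, where one action potential must
    count once).
    """
    t, v = _times_values(series)
    below = v < threshold
    idx = np.flatnonzero(below[:-1] & ~below[1:])
    if idx.size == 0:
        return CrossingSet(np.empty(0), threshold)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    if dead_time_ms > 0:
        dead = dead_time_ms * 1e-3
        kept = [times[0]]
        for x in times[1:]:
            if x - kept[-1] >= dead:
                kept.append(x)
        times = np.asarray(kept)
    return CrossingSet(times, threshold)


def detect_bursts(rate: RateSeries, onset_threshold: float = 5.0,
                  merge_gap_ms: float = 0.0, min_duration_ms: float = 0.0,
                  level: Optional[str] = None) -> list[BurstEvent]:
    """Maximal intervals where the rate stays at or above ``onset_threshold``.

    Interval edges are linearly interpolated threshold crossings.  Intervals
    separated by less than ``merge_gap_ms`` are merged: a small merge gap
    (0-10 ms) resolves sub-bursts, a large one (~200 ms) entire bursts.
    Intervals shorter than ``min_duration_ms`` after merging are dropped.
    """
    t, v = rate.times, rate.values
    above = v >= onset_threshold
    if not np.any(above):
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(v))

    def onset_time(i: int) -> float:
        if i == 0:
            return float(t[0])
        frac = (onset_threshold - v[i - 1]) / (v[i] - v[i - 1])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    def offset_time(i: int) -> float:
        if i >= len(v):
            return float(t[-1])
        frac = (v[i - 1] - onset_threshold) / (v[i - 1] - v[i])
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    intervals = [(onset_time(i0), offset_time(i1)) for i0, i1 in zip(starts, stops)]
    gap = merge_gap_ms * 1e-3
    merged: list[list[float]] = []
    for on, off in intervals:
        if merged and on - merged[-1][1] < gap:
            merged[-1][1] = off
        else:
            merged.append([on, off])
    min_dur = min_duration_ms * 1e-3
    lvl = level if level is not None else ("entire" if merge_gap_ms >= 100 else "sub")
    return [BurstEvent(on, off, level=lvl) for on, off in merged
            if off - on >= min_dur]


def delay_distribution(ref: CrossingSet, target: CrossingSet,
                       bin_ms: float = 2.0) -> DelayDistribution:
    """Shortest signed delay from each reference crossing to the target stream.

    For every reference crossing the signed difference (target minus
    reference) to the nearest target crossing is recorded; deltas are
    histogrammed into ``bin_ms`` bins normalised to probabilities, and the
    mean absolute delay is reported.  No censoring window is applied: every
    reference crossing is paired with its nearest target however far away.
    """
    if ref.n == 0:
        raise ValueError("no reference events")
    if target.n == 0:
        raise ValueError("no target events")
    pos = np.searchsorted(target.times, ref.times)
    left = np.clip(pos - 1, 0, target.n - 1)
    right = np.clip(pos, 0, target.n - 1)
    d_left = target.times[left] - ref.times
    d_right = target.times[right] - ref.times
    deltas = np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right) * 1e3

    lo = np.floor(deltas.min() / bin_ms) * bin_ms
    hi = np.ceil(deltas.max() / bin_ms) * bin_ms
    if hi <= lo:
        hi = lo + bin_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    counts, edges = np.histogram(deltas, bins=edges)
    probs = counts / deltas.size
    return DelayDistribution(deltas_ms=deltas, bin_edges_ms=edges,
                             probabilities=probs,
                             mean_abs_delay_ms=float(np.mean(np.abs(deltas))))


def conditional_vm_density(vm: VoltageTrace, rate: RateSeries,
                           split: Optional[float] = None,
                           bin_mv: float = 1.0) -> ConditionalDensityPair:
    """Membrane-potential density split by the network rate at each sample.

    The rate is linearly interpolated onto the membrane-potential sample
    times; samples with rate strictly above ``split`` (default: the grid
    mean of the rate) populate ``density_above``, the rest
    ``density_below``.  Both histograms are normalised by the TOTAL sample
    count and the bin width, so the pair integrates to one jointly.
    """
    if split is None:
        split = float(rate.values.mean())
    r = np.interp(vm.times, rate.times, rate.values)
    above = r > split
    v = vm.samples
    lo = np.floor(v.min() / bin_mv) * bin_mv
    hi = np.ceil(v.max() / bin_mv) * bin_mv
    if hi <= lo:
        hi = lo + bin_mv
    edges = np.arange(lo, hi + bin_mv / 2, bin_mv)
    n_total = v.size
    counts_above, edges = np.histogram(v[above], bins=edges)
    counts_below, _ = np.histogram(v[~above], bins=edges)
    width = np.diff(edges)
    return ConditionalDensityPair(
        bin_edges_mv=edges,
        density_above=counts_above / (n_total * width),
        density_below=counts_below / (n_total * width),
        split_hz=float(split),
    )


def _in_any(times: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean mask: which times fall inside any half-open interval."""
    mask = np.zeros(times.size, dtype=bool)
    for on, off in intervals:
        mask |= (times >= on) & (times < off)
    return mask


def classify_mode(patch_spikes: np.ndarray,
                  sub_bursts: Sequence[BurstEvent],
                  entire_bursts: Sequence[BurstEvent],
                  lag_ms: float = 0.0) -> CorrelationReport:
    """Label a patched neuron correlated or anti-correlated with sub-bursts.

    Only spikes inside entire bursts are considered (the phenomenon is
    defined within bursts; sustained firing in long silences is ignored).
    ``n_in`` counts spikes inside lag-compensated sub-burst intervals,
    ``n_out`` the remaining in-burst spikes; the index
    ``(n_in - n_out) / (n_in + n_out)`` is +1 when every in-burst spike sits
    in a sub-burst and -1 when all fall in the gaps.  Labels: correlated if
    index >= +0.5, anticorrelated if <= -0.5, else indeterminate.
    """
    spikes = np.asarray(patch_spikes, dtype=float)
    lag = lag_ms * 1e-3
    entire_iv = [(b.onset, b.offset + lag) for b in entire_bursts]
    in_burst = spikes[_in_any(spikes, entire_iv)]
    if in_burst.size == 0:
        return CorrelationReport(index=0.0, n_in=0, n_out=0, label="indeterminate")
    sub_iv = [(b.onset + lag, b.offset + lag) for b in sub_bursts]
    inside = _in_any(in_burst, sub_iv)
    n_in = int(inside.sum())
    n_out = int(in_burst.size - n_in)
    index = (n_in - n_out) / (n_in + n_out)
    if index >= 0.5:
        label = "correlated"
    elif index <= -0.5:
        label = "anticorrelated"
    else:
        label = "indeterminate"
    return CorrelationReport(index=float(index), n_in=n_in, n_out=n_out, label=label)
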