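"""Spike detection from raw voltage traces.

The raw extracellular signal is smoothed by convolution with a narrow
Gaussian (0.1 ms standard deviation) and action potentials are detected
where the smoothed signal exceeds a threshold of 6 times its standard
deviation, with a short dead time to suppress multiple detections of one
waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import SpikeTrainSet, VoltageTrace

__all__ = ["DetectionParams", "smooth", "detect_spikes", "build_raster"]

_TRUNCATE_SD = 5.0


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the threshold detector.

    kernel_std_ms:
        Standard deviation of the Gaussian smoothing kernel (default 0.1 ms).
    threshold_multiplier:
        Threshold in units of the standard deviation of the smoothed,
        mean-subtracted trace (default 6).
    dead_time_ms:
        Minimum separation between detected events (default 1 ms).
    polarity:
        ``"negative"``, ``"positive"`` or ``"both"`` (absolute value).
    robust_sd:
        If True, estimate the noise scale as ``median(|x|) / 0.6745`` instead
        of the full-trace standard deviation.
    timestamp:
        ``"extremum"`` (peak of the detection signal, default) or
        ``"crossing"`` (first supra-threshold sample).
    """

    kernel_std_ms: float = 0.1
    threshold_multiplier: float = 6.0
    dead_time_ms: float = 1.0
    polarity: str = "both"
    robust_sd: bool = False
    timestamp: str = "extremum"

    def __post_init__(self) -> None:
        if self.kernel_std_ms <= 0 or self.threshold_multiplier <= 0 or self.dead_time_ms <= 0:
            raise ValueError("detection parameters must be positive")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.timestamp not in ("extremum", "crossing"):
            raise ValueError(f"unknown timestamp convention {self.timestamp!r}")


def smooth(trace: VoltageTrace, kernel_std_ms: float) -> VoltageTrace:
    """Convolve with a unit-area Gaussian truncated at +/- 5 SD.

    Output length equals input length; edges use symmetric (mirror) padding,
    so a constant trace and the interior of a linear ramp pass unchanged.
    """
    if kernel_std_ms <= 0:
        raise ValueError("kernel_std_ms must be positive")
    sigma = kernel_std_ms * 1e-3 * trace.fs
    radius = int(_TRUNCATE_SD * sigma + 0.5)
    if 2 * radius + 1 > trace.n_samples:
        raise ValueError("smoothing kernel wider than the trace")
    out = gaussian_filter1d(trace.samples, sigma, mode="reflect", truncate=_TRUNCATE_SD)
    return trace.with_samples(out)


def _detection_signal(smoothed: np.ndarray, polarity: str) -> np.ndarray:
    x = smoothed - smoothed.mean()
    if polarity == "negative":
        return -x
    if polarity == "positive":
        return x
    return np.abs(x)


def detect_spikes(trace: VoltageTrace, params: DetectionParams = DetectionParams()
                  ) -> np.ndarray:
    """Detect spike times (seconds) in one voltage trace.

    The trace is smoothed, mean-subtracted, rectified according to
    ``polarity``, and events are taken at local extrema of the detection
    signal exceeding ``threshold_multiplier`` times its standard deviation.
    Events closer than the dead time to a larger event are suppressed
    (largest first), so raising the threshold can never increase the number
    of detections.  A zero-variance trace yields no spikes.
    """
    smoothed = smooth(trace, params.kernel_std_ms)
    y = _detection_signal(smoothed.samples, params.polarity)
    centred = smoothed.samples - smoothed.samples.mean()
    if params.robust_sd:
        scale = np.median(np.abs(centred)) / 0.6745
    else:
        scale = centred.std()
    if scale == 0:
        return np.empty(0)
    threshold = params.threshold_multiplier * scale

    above = y >= threshold
    if not np.any(above):
        return np.empty(0)
    # local maxima of the detection signal (plateaus: first sample)
    interior = np.zeros_like(above)
    interior[1:-1] = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])
    interior[0] = y[0] > y[1] if y.size > 1 else True
    interior[-1] = y[-1] > y[-2] if y.size > 1 else True
    peaks = np.flatnonzero(above & interior)
    if peaks.size == 0:
        return np.empty(0)

    dead = params.dead_time_ms * 1e-3
    order = peaks[np.argsort(y[peaks], kind="stable")[::-1]]
    times = order / trace.fs
    kept: list[float] = []
    for t in times:
        if all(abs(t - k) >= dead for k in kept):
            kept.append(t)
    kept_arr = np.sort(np.asarray(kept))

    if params.timestamp == "crossing":
        # walk back from each kept extremum to the first supra-threshold sample
        idx = np.sort(order[np.isin(order / trace.fs, kept_arr)])
        starts = []
        for i in idx:
            j = i
            while j > 0 and y[j - 1] >= threshold:
                j -= 1
            starts.append(j / trace.fs)
        kept_arr = np.asarray(starts)
    return trace.t0 + kept_arr


def build_raster(traces: Sequence[VoltageTrace],
                 params: DetectionParams = DetectionParams()) -> SpikeTrainSet:
    """Detect spikes on every channel, preserving channel order."""
    if traces:
        fs0 = traces[0].fs
        if any(tr.fs != fs0 for tr in traces):
            raise ValueError("all channels must share one sampling rate")
    trains = tuple(detect_spikes(tr, params) for tr in traces)
    clock = traces[0].clock_id if traces else "mea"
    return SpikeTrainSet(trains, clock_id=clock)
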