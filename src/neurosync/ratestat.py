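"""Network temporal rate estimation.

The instantaneous network rate is

    r(t) = (1 / N) * sum over spikes t* of f(t - t*),

with f a unit-area Gaussian of 2 ms standard deviation and N the number of
electrodes, so that the time average of r(t) equals the average number of
recorded spikes per second per electrode.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import RateSeries, SpikeTrainSet

__all__ = ["temporal_rate", "mean_rate"]

_TRUNCATE_SD = 5.0


def temporal_rate(spikes: SpikeTrainSet, kernel_std_ms: float = 2.0,
                  n_electrodes: int = 60, dt: float = 0.5e-3,
                  t_start: Optional[float] = None,
                  t_stop: Optional[float] = None) -> RateSeries:
    """Kernel-smoothed, per-electrode-averaged network rate on a uniform grid.

    Each spike contributes a Gaussian of standard deviation ``kernel_std_ms``
    (truncated at +/- 5 SD), evaluated exactly at the grid points; the sum is
    divided by ``n_electrodes``.  The grid spans ``[t_start, t_stop]``;
    by default it covers all spikes plus the kernel support, so integrating
    ``r`` over the grid times ``n_electrodes`` recovers the spike count.

    ``n_electrodes`` is the configured array size, not the number of active
    channels: sessions with silent electrodes still divide by the full count.
    """
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    if kernel_std_ms <= 0 or dt <= 0:
        raise ValueError("kernel_std_ms and dt must be positive")
    sd = kernel_std_ms * 1e-3
    half = _TRUNCATE_SD * sd
    times = spikes.all_times()
    if t_start is None:
        t_start = (times.min() - half) if times.size else 0.0
    if t_stop is None:
        t_stop = (times.max() + half) if times.size else t_start + dt

    n_grid = int(np.floor((t_stop - t_start) / dt)) + 1
    grid = t_start + np.arange(n_grid) * dt
    values = np.zeros(n_grid)
    if times.size:
        norm = 1.0 / (np.sqrt(2.0 * np.pi) * sd)
        half_pts = int(np.ceil(half / dt))
        # scatter-add each spike's truncated kernel onto the grid, all spikes at once
        centre = (times - t_start) / dt
        base = np.ceil(centre).astype(np.int64) - half_pts
        idx = base[:, None] + np.arange(2 * half_pts + 1)[None, :]
        x = idx * dt + t_start - times[:, None]
        contrib = norm * np.exp(-0.5 * (x / sd) ** 2)
        contrib[np.abs(x) > half] = 0.0
        valid = (idx >= 0) & (idx < n_grid)
        np.add.at(values, idx[valid], contrib[valid])
        values /= n_electrodes
    return RateSeries(times=grid, values=values, kernel_std_ms=kernel_std_ms,
                      n_electrodes=n_electrodes)


def mean_rate(series: RateSeries) -> float:
    """Arithmetic mean of the rate over its grid (Hz per electrode)."""
    if series.values.size == 0:
        raise ValueError("empty rate series")
    return float(series.values.mean())
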