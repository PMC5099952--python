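"""Alignment of timestamps recorded on two independent acquisition clocks.

The extracellular array and the patch amplifier digitise on separate clocks
that differ by an offset and a slow linear drift.  The array interface emits
periodic leader triggers which the patch digitiser timestamps on its own
clock (leader-laggard configuration); fitting laggard trigger times against
leader trigger times recovers the clock mapping, after which every
patch-clock timestamp can be re-expressed on the array clock to within a few
microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = ["ClockModel", "apply_clock_model", "fit_clock_model", "synchronize_session"]


@dataclass(frozen=True)
class ClockModel:
    """Mapping from a leader timebase to a laggard timebase.

    Affine form: ``t_laggard = (1 + drift) * t_leader + offset``.  If
    ``knots`` is set, the mapping is instead piecewise-linear through the
    paired trigger times (leader_knots, laggard_knots), extrapolating with
    the end segments.
    """

    offset: float = 0.0
    drift: float = 0.0
    knots: Optional[tuple[np.ndarray, np.ndarray]] = None
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.drift <= -1.0:
            raise ValueError("drift must exceed -1 for a monotone mapping")
        if self.knots is not None:
            leader = np.asarray(self.knots[0], dtype=float)
            laggard = np.asarray(self.knots[1], dtype=float)
            if leader.shape != laggard.shape or leader.size < 2:
                raise ValueError("knots must be two equal-length arrays with >= 2 points")
            if np.any(np.diff(leader) <= 0) or np.any(np.diff(laggard) <= 0):
                raise ValueError("knot sequences must be strictly increasing")
            object.__setattr__(self, "knots", (leader, laggard))
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


def apply_clock_model(times, model: ClockModel, inverse: bool = False) -> np.ndarray:
    """Map ``times`` between the two timebases.

    Forward maps leader time to laggard time; ``inverse=True`` maps laggard
    time back to leader time (the exact inverse of the forward map).
    """
    t = np.asarray(times, dtype=float)
    if model.knots is None:
        slope = 1.0 + model.drift
        if inverse:
            return (t - model.offset) / slope
        return slope * t + model.offset
    leader, laggard = model.knots
    x, y = (laggard, leader) if inverse else (leader, laggard)
    # piecewise-linear with linear extrapolation using the end segments
    out = np.interp(t, x, y)
    lo_slope = (y[1] - y[0]) / (x[1] - x[0])
    hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
    below = t < x[0]
    above = t > x[-1]
    if np.any(below):
        out = np.where(below, y[0] + (t - x[0]) * lo_slope, out)
    if np.any(above):
        out = np.where(above, y[-1] + (t - x[-1]) * hi_slope, out)
    return out


def fit_clock_model(leader_triggers, laggard_triggers, mode: str = "affine") -> ClockModel:
    """Fit a :class:`ClockModel` from paired trigger timestamps.

    Triggers are paired by order (k-th leader to k-th laggard).  ``affine``
    performs a least-squares fit of laggard on leader; ``piecewise``
    interpolates exactly through the trigger pairs (zero residual at knots).
    """
    leader = np.asarray(leader_triggers, dtype=float)
    laggard = np.asarray(laggard_triggers, dtype=float)
    if leader.shape != laggard.shape or leader.ndim != 1:
        raise ValueError("trigger lists must be equal-length 1-D arrays")
    if leader.size < 2:
        raise ValueError("at least 2 trigger pairs are required")
    if np.any(np.diff(leader) == 0):
        raise ValueError("duplicated leader trigger times")
    if mode == "affine":
        # centre the leader times for numerical conditioning of the fit
        mu = leader.mean()
        slope, intercept = np.polyfit(leader - mu, laggard, 1)
        offset = intercept - slope * mu
        residuals = laggard - (slope * leader + offset)
        return ClockModel(offset=float(offset), drift=float(slope - 1.0),
                          residual_sd=float(np.std(residuals)))
    if mode == "piecewise":
        if np.any(np.diff(laggard) <= 0):
            raise ValueError("laggard triggers must be strictly increasing for a monotone model")
        slope = (laggard[-1] - laggard[0]) / (leader[-1] - leader[0])
        return ClockModel(offset=float(laggard[0] - slope * leader[0]),
                          drift=float(slope - 1.0),
                          knots=(leader.copy(), laggard.copy()),
                          residual_sd=0.0)
    raise ValueError(f"unknown mode {mode!r}")


def synchronize_session(bundle, mode: str = "affine", tolerance_us: float = 20.0):
    """Re-express all patch-clock data of a session bundle on the array clock.

    Fits the clock model from the bundle's two trigger streams, maps every
    patch spike time and patch voltage-trace timebase onto the leader (array)
    clock, and attaches a sync report.  Raises if the fitted mapping is not
    monotone over the session (gross trigger misalignment).
    """
    # local import: session containers live in synthgen to avoid a cycle
    leader = bundle.triggers.get(bundle.leader_clock)
    laggard = bundle.triggers.get(bundle.patch_clock)
    if leader is None or laggard is None:
        raise ValueError("bundle is missing trigger streams for one of the clocks")
    model = fit_clock_model(leader, laggard, mode=mode)
    if 1.0 + model.drift <= 0:
        raise ValueError("fitted clock mapping is not monotone; triggers misaligned")

    corrected = bundle.triggers.copy()
    patches = []
    for patch in bundle.patches:
        spike_times = apply_clock_model(patch.spike_times, model, inverse=True)
        trace = patch.voltage
        if trace is not None:
            t0 = float(apply_clock_model(np.array([trace.t0]), model, inverse=True)[0])
            trace = replace(trace, t0=t0, fs=trace.fs * (1.0 + model.drift), clock_id=bundle.leader_clock)
        patches.append(replace(patch, spike_times=spike_times, voltage=trace,
                               clock_id=bundle.leader_clock))

    trig_resid = apply_clock_model(laggard, model, inverse=True) - leader
    report = {
        "mode": mode,
        "offset_s": model.offset,
        "drift": model.drift,
        "residual_sd_s": model.residual_sd,
        "max_trigger_residual_s": float(np.max(np.abs(trig_resid))) if leader.size else 0.0,
        "tolerance_us": tolerance_us,
        "within_tolerance": bool(np.max(np.abs(trig_resid)) * 1e6 <= tolerance_us),
    }
    out = replace(bundle, patches=tuple(patches), triggers=corrected,
                  clock_model=model, sync_report=report)
    return out
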