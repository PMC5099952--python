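"""HDF5 session container and CSV spike-list readers/writers.

Layout of the HDF5 container (schema version 1):

    /mea/voltage            (channels x samples, int16 with `scale_uv` attr)  [optional]
    /mea/spikes/<ch>        float64 spike times (s) per channel
    /patch/<k>/voltage      float64 membrane potential (mV) with fs/t0 attrs
    /patch/<k>/spike_times  float64 (s, patch clock)
    /triggers/<clock>       float64 trigger times (s)
    /ground_truth/*         schedule, true spikes, clock parameters          [optional]

The session configuration is echoed as a JSON attribute on the root group.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .clocksync import ClockModel
from .synthgen import (BurstSchedule, GroundTruth, PatchRecording,
                       SessionBundle, SessionConfig)
from .types import SpikeTrainSet, VoltageTrace

__all__ = ["write_session", "read_session", "write_spike_csv", "read_spike_csv"]

SCHEMA_VERSION = 1
_VOLT_SCALE_UV = 0.1  # int16 LSB for extracellular storage


def write_session(bundle: SessionBundle, path) -> None:
    """Write a session bundle to an HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(bundle.config))
        f.attrs["leader_clock"] = bundle.leader_clock
        f.attrs["patch_clock"] = bundle.patch_clock

        mea = f.create_group("mea")
        spikes = mea.create_group("spikes")
        for ch, train in enumerate(bundle.mea_spikes.trains):
            spikes.create_dataset(str(ch), data=train, dtype="float64")
        if bundle.mea_traces:
            stacked = np.stack([tr.samples for tr in bundle.mea_traces])
            ds = mea.create_dataset(
                "voltage", data=np.round(stacked / _VOLT_SCALE_UV).astype(np.int16))
            ds.attrs["scale_uv"] = _VOLT_SCALE_UV
            ds.attrs["fs"] = bundle.mea_traces[0].fs
            ds.attrs["t0"] = bundle.mea_traces[0].t0

        patch_grp = f.create_group("patch")
        for k, patch in enumerate(bundle.patches):
            g = patch_grp.create_group(str(k))
            g.attrs["mode"] = patch.mode
            g.attrs["clock_id"] = patch.clock_id
            g.create_dataset("spike_times", data=patch.spike_times, dtype="float64")
            if patch.voltage is not None:
                ds = g.create_dataset("voltage", data=patch.voltage.samples,
                                      dtype="float32")
                ds.attrs["fs"] = patch.voltage.fs
                ds.attrs["t0"] = patch.voltage.t0
                ds.attrs["unit"] = patch.voltage.unit

        trig = f.create_group("triggers")
        for clock, times in bundle.triggers.items():
            trig.create_dataset(clock, data=np.asarray(times), dtype="float64")

        if bundle.ground_truth is not None:
            _write_ground_truth(f.create_group("ground_truth"), bundle.ground_truth)


def _write_ground_truth(g: h5py.Group, truth: GroundTruth) -> None:
    sched = truth.schedule
    g.create_dataset("entire_bursts", data=np.asarray(sched.entire_bursts,
                                                      dtype=float).reshape(-1, 2))
    g.create_dataset("sub_bursts", data=np.asarray(
        [(on, off, float(p)) for on, off, p in sched.sub_bursts],
        dtype=float).reshape(-1, 3))
    g.create_dataset("envelope_gain", data=np.asarray(sched.envelope_gain, dtype=float))
    spikes = g.create_group("network_spikes")
    for ch, train in enumerate(truth.network_spikes.trains):
        spikes.create_dataset(str(ch), data=train, dtype="float64")
    patch = g.create_group("patch_spikes")
    for k, train in enumerate(truth.patch_spikes):
        ds = patch.create_dataset(str(k), data=train, dtype="float64")
        ds.attrs["mode"] = truth.patch_modes[k]
    g.attrs["lag_ms"] = truth.lag_ms
    g.attrs["clock_offset_s"] = truth.clock_model.offset
    g.attrs["clock_drift"] = truth.clock_model.drift


def read_session(path) -> SessionBundle:
    """Read a session bundle from an HDF5 container.

    Validates the schema version and basic invariants (positive sampling
    rates, sorted spike lists) and raises a clear error naming any missing
    required group.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable session container: {path} ({exc})") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unrecognised schema version {version!r}")
        for group in ("mea", "mea/spikes", "patch", "triggers"):
            if group not in f:
                raise ValueError(f"session container missing required group '/{group}'")
        config = SessionConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(f.attrs["config_json"]).items()})
        leader_clock = str(f.attrs.get("leader_clock", "mea"))
        patch_clock = str(f.attrs.get("patch_clock", "patch"))

        spike_grp = f["mea/spikes"]
        trains = [np.asarray(spike_grp[k][...])
                  for k in sorted(spike_grp, key=int)]
        mea_spikes = SpikeTrainSet(tuple(trains), clock_id=leader_clock)

        mea_traces: tuple[VoltageTrace, ...] = ()
        if "voltage" in f["mea"]:
            ds = f["mea/voltage"]
            fs = float(ds.attrs["fs"])
            if fs <= 0:
                raise ValueError("invalid sampling rate in container")
            scale = float(ds.attrs["scale_uv"])
            raw = ds[...]
            mea_traces = tuple(
                VoltageTrace(raw[ch].astype(float) * scale, fs=fs,
                             t0=float(ds.attrs["t0"]), unit="uV",
                             clock_id=leader_clock)
                for ch in range(raw.shape[0]))

        patches = []
        patch_grp = f["patch"]
        for k in sorted(patch_grp, key=int):
            g = patch_grp[k]
            voltage = None
            if "voltage" in g:
                ds = g["voltage"]
                fs = float(ds.attrs["fs"])
                if fs <= 0:
                    raise ValueError("invalid sampling rate in container")
                voltage = VoltageTrace(ds[...].astype(float), fs=fs,
                                       t0=float(ds.attrs["t0"]),
                                       unit=str(ds.attrs.get("unit", "mV")),
                                       clock_id=str(g.attrs["clock_id"]))
            patches.append(PatchRecording(
                spike_times=np.asarray(g["spike_times"][...]),
                mode=str(g.attrs["mode"]), voltage=voltage,
                clock_id=str(g.attrs["clock_id"])))

        triggers = {clock: np.asarray(f["triggers"][clock][...])
                    for clock in f["triggers"]}

        truth = None
        if "ground_truth" in f:
            truth = _read_ground_truth(f["ground_truth"], patches)

    return SessionBundle(config=config, mea_spikes=mea_spikes,
                         patches=tuple(patches), triggers=triggers,
                         mea_traces=mea_traces, ground_truth=truth,
                         leader_clock=leader_clock, patch_clock=patch_clock)


def _read_ground_truth(g: h5py.Group, patches) -> GroundTruth:
    entire = tuple((float(on), float(off)) for on, off in g["entire_bursts"][...])
    subs = tuple((float(on), float(off), int(p)) for on, off, p in g["sub_bursts"][...])
    schedule = BurstSchedule(entire, subs, tuple(g["envelope_gain"][...]))
    spikes = g["network_spikes"]
    trains = tuple(np.asarray(spikes[k][...]) for k in sorted(spikes, key=int))
    pg = g["patch_spikes"]
    patch_spikes = tuple(np.asarray(pg[k][...]) for k in sorted(pg, key=int))
    modes = tuple(str(pg[k].attrs["mode"]) for k in sorted(pg, key=int))
    clock = ClockModel(offset=float(g.attrs["clock_offset_s"]),
                       drift=float(g.attrs["clock_drift"]))
    return GroundTruth(schedule=schedule, network_spikes=SpikeTrainSet(trains),
                       patch_spikes=patch_spikes, patch_modes=modes,
                       lag_ms=float(g.attrs["lag_ms"]), clock_model=clock)


def write_spike_csv(spikes: SpikeTrainSet, path) -> None:
    """Write a spike list as CSV with columns ``channel,time_s``."""
    rows = [(ch, t) for ch, train in enumerate(spikes.trains) for t in train]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_spike_csv(path, n_channels: int | None = None) -> SpikeTrainSet:
    """Read a ``channel,time_s`` CSV spike list; unsorted rows are sorted
    with a warning."""
    df = pd.read_csv(path)
    if not {"channel", "time_s"} <= set(df.columns):
        raise ValueError("spike CSV must have columns 'channel' and 'time_s'")
    if n_channels is None:
        n_channels = int(df["channel"].max()) + 1 if len(df) else 0
    trains = []
    for ch in range(n_channels):
        t = df.loc[df["channel"] == ch, "time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            warnings.warn(f"channel {ch}: unsorted spike times sorted on load",
                          stacklevel=2)
            t = np.sort(t)
        trains.append(t)
    return SpikeTrainSet(tuple(trains))
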