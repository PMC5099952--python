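"""Overview figure: raster, network rate, membrane potential on shared time axes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .ratestat import temporal_rate

__all__ = ["plot_overview"]


def plot_overview(bundle, report=None, path=None, rate=None):
    """Three-panel session overview (raster / rate / Vm), Fig-2-style.

    Panels share the time axis.  Returns the matplotlib figure; if ``path``
    is given the figure is also written there.
    """
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7))
    ax_raster, ax_rate, ax_vm = axes

    for ch, train in enumerate(bundle.mea_spikes.trains):
        if train.size:
            ax_raster.plot(train, ch * (1 + 0 * train), "|", color="k", markersize=2)
    ax_raster.set_ylabel("electrode")
    ax_raster.set_ylim(-1, max(bundle.mea_spikes.n_channels, 1))

    if rate is None:
        rate = temporal_rate(bundle.mea_spikes,
                             n_electrodes=bundle.config.n_electrodes,
                             t_start=0.0, t_stop=bundle.config.duration)
    ax_rate.plot(rate.times, rate.values, color="C0", lw=0.8)
    ax_rate.set_ylabel("rate (Hz)")

    for patch in bundle.patches:
        if patch.voltage is not None:
            tr = patch.voltage
            ax_vm.plot(tr.times, tr.samples, lw=0.5)
    ax_vm.set_ylabel("Vm (mV)")
    ax_vm.set_xlabel("time (s)")
    fig.align_ylabels(axes)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
    return fig
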