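"""Generate a synthetic dual-modality session and inspect its ground truth.

The generator emulates a bursting cortical culture on a 60-electrode array
recorded simultaneously with one patched neuron: entire bursts separated by
long silences, sub-bursts inside each entire burst, per-electrode Poisson
spiking, a membrane potential that depolarizes during bursts, and two
acquisition clocks with a linear drift.
"""

import numpy as np

from neurosync import SessionConfig, generate_session

config = SessionConfig(duration=60.0, n_electrodes=60, fs=20_000.0,
                       patch_modes=("correlated",))
bundle, truth = generate_session(config, seed=1)

schedule = truth.schedule
print(f"entire bursts: {schedule.n_entire}, sub-bursts: {schedule.n_sub}")
for on, off in schedule.entire_bursts:
    print(f"  burst [{on:7.2f}, {off:7.2f}) s, "
          f"{sum(1 for *_ , p in schedule.sub_bursts if schedule.entire_bursts[p] == (on, off))} sub-bursts")
print(f"network spikes: {bundle.mea_spikes.n_spikes} on "
      f"{bundle.mea_spikes.n_channels} electrodes")
print(f"patch spikes (true): {truth.patch_spikes[0].size}, "
      f"mode {truth.patch_modes[0]}, lag {truth.lag_ms} ms")
vm = bundle.patches[0].voltage
print(f"membrane potential: min {vm.samples.min():.1f} mV, "
      f"max {vm.samples.max():.1f} mV (baseline {config.vm_baseline_mv} mV)")
# The Vm maximum overshoots 0 mV (action potentials); between bursts it sits
# at the -70 mV baseline; during bursts the EPSP envelope lifts it by ~30 mV.
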