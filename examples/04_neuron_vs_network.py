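"""Quantify how a single patched neuron reflects the network's activity.

Three statistics: (1) the distribution of shortest delays between upward
20 Hz crossings of the network rate and -25 mV crossings of the membrane
potential; (2) the membrane-potential density conditioned on the rate being
above or below its mean; (3) the correlated/anti-correlated classification
of the neuron's evoked spikes against the network's sub-bursts.
"""

import numpy as np

from neurosync import (SessionConfig, classify_mode, conditional_vm_density,
                       delay_distribution, detect_bursts, generate_session,
                       synchronize_session, temporal_rate, upward_crossings)

for mode in ("correlated", "anticorrelated"):
    config = SessionConfig(duration=120.0, n_electrodes=60, fs=20_000.0,
                           patch_modes=(mode,), lag_ms=16.0)
    bundle, truth = generate_session(config, seed=42)
    bundle = synchronize_session(bundle)

    rate = temporal_rate(bundle.mea_spikes, n_electrodes=60,
                         t_start=0.0, t_stop=config.duration)
    rate_cross = upward_crossings(rate, 20.0)
    vm = bundle.patches[0].voltage
    vm_cross = upward_crossings(vm, -25.0, dead_time_ms=1.0)

    print(f"--- {mode} neuron ---")
    if rate_cross.n and vm_cross.n:
        dist = delay_distribution(rate_cross, vm_cross)
        print(f"mean |delay| rate->Vm crossings: {dist.mean_abs_delay_ms:.1f} ms "
              f"(injected lag {config.lag_ms} ms)")

    pair = conditional_vm_density(vm, rate)
    print(f"joint integral of conditional Vm densities: {pair.joint_integral():.6f}")

    subs = detect_bursts(rate, 5.0, merge_gap_ms=10.0, min_duration_ms=20.0)
    entire = detect_bursts(rate, 5.0, merge_gap_ms=200.0, min_duration_ms=20.0)
    report = classify_mode(vm_cross.times, subs, entire, lag_ms=config.lag_ms)
    print(f"classification: {report.label} (index {report.index:+.2f}, "
          f"{report.n_in} in / {report.n_out} out)")
# The correlated neuron recovers the injected ~16 ms lag and index +1;
# the anti-correlated neuron fires only between sub-bursts (index near -1)
# while its membrane potential still tracks the burst envelope.
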