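"""Detect spikes on rendered raw voltage and score them against ground truth.

Raw extracellular traces are smoothed with a 0.1 ms Gaussian; events are
detected where the smoothed signal exceeds 6 times its standard deviation.
"""

import numpy as np

from neurosync import (SessionConfig, build_raster, generate_network_spikes,
                       render_extracellular, sample_burst_schedule)

config = SessionConfig(duration=8.0, n_electrodes=6, fs=20_000.0,
                       silence_s=(1.0, 3.0), entire_burst_s=(0.5, 2.0),
                       peak_rate_hz=10.0)
schedule = sample_burst_schedule(config, seed=6)
truth = generate_network_spikes(schedule, config, seed=6)
traces = render_extracellular(truth, config, seed=6)
raster = build_raster(traces)

for ch, (true_train, det) in enumerate(zip(truth.trains, raster.trains)):
    hits = sum(1 for t in true_train if det.size and np.abs(det - t).min() <= 0.5e-3)
    recall = hits / max(true_train.size, 1)
    print(f"channel {ch}: {true_train.size:3d} true, {det.size:3d} detected, "
          f"recall {recall:.2f}")
# Recall is near 1: at 80 uV spike amplitude over 5 uV noise the 6-SD
# threshold finds essentially every planted spike within 0.5 ms.
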