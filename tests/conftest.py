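import numpy as np
import pytest

from neurosync import SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_config() -> SessionConfig:
    """A compact session: short, few electrodes, reduced sampling rate.

    Schedule and spike generation do not depend on fs, so a lower sampling
    rate only affects rendered voltage traces.
    """
    return SessionConfig(duration=30.0, n_electrodes=20, fs=20_000.0,
                         silence_s=(2.0, 10.0), entire_burst_s=(0.5, 3.0),
                         patch_modes=("correlated", "anticorrelated"))


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, seed=7)


def match_fraction(true_times, detected_times, window_s):
    """Fraction of true events matched one-to-one to a detected event within
    the window (optimal bipartite matching on |time difference|)."""
    from scipy.optimize import linear_sum_assignment

    true_times = np.asarray(true_times, dtype=float)
    detected = np.asarray(detected_times, dtype=float)
    if true_times.size == 0:
        return 1.0
    if detected.size == 0:
        return 0.0
    cost = np.abs(true_times[:, None] - detected[None, :])
    big = 10 * window_s
    cost = np.where(cost <= window_s, cost, big)
    rows, cols = linear_sum_assignment(cost)
    hits = int(np.sum(cost[rows, cols] <= window_s))
    return hits / true_times.size
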