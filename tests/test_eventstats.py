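"""Crossing statistics, burst detection, delay distributions, conditional
membrane-potential densities and correlation-mode classification."""

import numpy as np
import pytest

from neurosync import (BurstEvent, RateSeries, SessionConfig, VoltageTrace,
                       classify_mode, conditional_vm_density, delay_distribution,
                       detect_bursts, generate_network_spikes,
                       render_intracellular, sample_burst_schedule,
                       temporal_rate, upward_crossings)
from neurosync.eventstats import CrossingSet

from conftest import match_fraction


def _series(values, dt=0.001):
    values = np.asarray(values, dtype=float)
    return RateSeries(np.arange(values.size) * dt, values, 2.0, 60)


class TestUpwardCrossings:
    def test_constant_below_threshold(self):
        assert upward_crossings(_series([1, 1, 1, 1]), 20.0).n == 0

    def test_two_rises_counted(self):
        series = _series([0, 30, 0, 30])
        assert upward_crossings(series, 20.0).n == 2

    def test_start_above_threshold_not_counted(self):
        series = _series([25, 26, 27, 28])
        assert upward_crossings(series, 20.0).n == 0

    def test_crossing_instant_interpolated(self):
        # rises linearly from 0 at t=0 to 40 at t=1 ms: crosses 20 at 0.5 ms
        series = _series([0.0, 40.0])
        times = upward_crossings(series, 20.0).times
        assert times[0] == pytest.approx(0.5e-3)

    def test_dead_time_suppresses_rebounds(self):
        v = np.zeros(100)
        v[10] = v[12] = v[40] = 30.0
        series = _series(v)
        assert upward_crossings(series, 20.0).n == 3
        assert upward_crossings(series, 20.0, dead_time_ms=5.0).n == 2


class TestDetectBursts:
    def test_zero_rate_no_bursts(self):
        assert detect_bursts(_series(np.zeros(100)), 5.0) == []

    def test_merge_gap_fuses_nearby_runs(self):
        v = np.zeros(400)
        v[100:110] = 30.0
        v[160:170] = 30.0  # 50 ms apart
        series = _series(v)
        assert len(detect_bursts(series, 5.0, merge_gap_ms=0.0)) == 2
        assert len(detect_bursts(series, 5.0, merge_gap_ms=200.0)) == 1

    def test_min_duration_filters_blips(self):
        v = np.zeros(400)
        v[100:102] = 30.0
        v[200:260] = 30.0
        series = _series(v)
        bursts = detect_bursts(series, 5.0, min_duration_ms=20.0)
        assert len(bursts) == 1 and bursts[0].onset > 0.15

    def test_output_disjoint_sorted(self):
        rng = np.random.default_rng(0)
        series = _series(np.abs(rng.normal(0, 10, 2000)))
        bursts = detect_bursts(series, 5.0, merge_gap_ms=5.0)
        for b0, b1 in zip(bursts, bursts[1:]):
            assert b0.offset <= b1.onset

    def test_subburst_onsets_recovered_on_synthetic_session(self):
        cfg = SessionConfig(duration=60.0, n_electrodes=20,
                            silence_s=(2.0, 10.0))
        schedule = sample_burst_schedule(cfg, seed=8)
        spikes = generate_network_spikes(schedule, cfg, seed=8)
        rate = temporal_rate(spikes, n_electrodes=20, t_start=0.0, t_stop=60.0)
        detected = detect_bursts(rate, 5.0, merge_gap_ms=10.0,
                                 min_duration_ms=20.0)
        true_onsets = [on for on, _off, _p in schedule.sub_bursts]
        det_onsets = [b.onset for b in detected]
        assert match_fraction(true_onsets, det_onsets, 10e-3) >= 0.90


class TestDelayDistribution:
    def test_identical_streams_zero_delay(self):
        c = CrossingSet(np.array([1.0, 2.0, 3.0]), 20.0)
        dist = delay_distribution(c, c)
        assert np.all(dist.deltas_ms == 0.0)
        assert dist.mean_abs_delay_ms == 0.0

    def test_nearest_neighbour_by_hand(self):
        ref = CrossingSet(np.array([0.100]), 20.0)
        target = CrossingSet(np.array([0.084, 0.150]), -25.0)
        dist = delay_distribution(ref, target)
        assert dist.deltas_ms[0] == pytest.approx(-16.0)
        assert dist.mean_abs_delay_ms == pytest.approx(16.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        ref = CrossingSet(np.sort(rng.uniform(0, 100, 50)), 20.0)
        target = CrossingSet(np.sort(rng.uniform(0, 100, 70)), -25.0)
        dist = delay_distribution(ref, target, bin_ms=2.0)
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_empty_target_rejected(self):
        ref = CrossingSet(np.array([1.0]), 20.0)
        with pytest.raises(ValueError, match="target"):
            delay_distribution(ref, CrossingSet(np.empty(0), -25.0))

    def test_injected_lag_shifts_modal_delta(self):
        rng = np.random.default_rng(2)
        base = np.sort(rng.uniform(0, 200, 80))
        base = base[np.diff(np.concatenate([[-1.0], base])) > 0.5]
        lag = 0.016
        ref = CrossingSet(base, 20.0)
        target = CrossingSet(base + lag, -25.0)
        dist = delay_distribution(ref, target, bin_ms=2.0)
        modal_bin = np.argmax(dist.probabilities)
        centre = 0.5 * (dist.bin_edges_ms[modal_bin] + dist.bin_edges_ms[modal_bin + 1])
        assert abs(centre - 16.0) <= 2.0


class TestConditionalDensity:
    def test_degenerate_split_all_below(self):
        vm = VoltageTrace(np.linspace(-75, -65, 1000), fs=1000.0, unit="mV")
        rate = RateSeries(np.arange(1000) * 0.001, np.zeros(1000), 2.0, 60)
        pair = conditional_vm_density(vm, rate, split=0.0)
        assert np.all(pair.density_above == 0.0)
        assert pair.joint_integral() == pytest.approx(1.0, abs=1e-9)

    def test_joint_normalization_on_session(self, small_session):
        bundle, _truth = small_session
        vm = bundle.ground_truth.vm_envelopes[0]
        rate = temporal_rate(bundle.mea_spikes, n_electrodes=20,
                             t_start=0.0, t_stop=30.0)
        pair = conditional_vm_density(vm, rate)
        assert pair.joint_integral() == pytest.approx(1.0, abs=1e-6)

    def test_burst_conditioned_vm_is_depolarized(self):
        cfg = SessionConfig(duration=40.0, n_electrodes=20, fs=5000.0,
                            silence_s=(2.0, 8.0), entire_burst_s=(1.0, 3.0))
        schedule = sample_burst_schedule(cfg, seed=9)
        spikes = generate_network_spikes(schedule, cfg, seed=9)
        _vm, _s, env = render_intracellular(schedule, "correlated", cfg, seed=9)
        rate = temporal_rate(spikes, n_electrodes=20, t_start=0.0, t_stop=40.0)
        pair = conditional_vm_density(env, rate)
        centres = 0.5 * (pair.bin_edges_mv[:-1] + pair.bin_edges_mv[1:])
        mean_above = np.sum(centres * pair.density_above) / pair.density_above.sum()
        mean_below = np.sum(centres * pair.density_below) / pair.density_below.sum()
        assert mean_above - mean_below >= 10.0


class TestClassifyMode:
    entire = [BurstEvent(0.0, 2.0, level="entire")]
    subs = [BurstEvent(0.0, 0.2), BurstEvent(0.5, 0.7), BurstEvent(1.0, 1.2)]

    def test_all_inside_subbursts(self):
        report = classify_mode(np.array([0.1, 0.55, 1.1]), self.subs, self.entire)
        assert report.index == 1.0 and report.label == "correlated"

    def test_all_in_gaps(self):
        report = classify_mode(np.array([0.3, 0.8, 0.9]), self.subs, self.entire)
        assert report.index == -1.0 and report.label == "anticorrelated"

    def test_three_in_one_out(self):
        report = classify_mode(np.array([0.1, 0.55, 1.1, 0.3]), self.subs,
                               self.entire)
        assert report.index == pytest.approx(0.5)
        assert report.label == "correlated"

    def test_no_in_burst_spikes_indeterminate(self):
        report = classify_mode(np.array([5.0, 6.0]), self.subs, self.entire)
        assert report.label == "indeterminate"
        assert report.n_in == 0 and report.n_out == 0

    def test_lag_compensation_recovers_shifted_spikes(self):
        spikes = np.array([0.1, 0.55, 1.1]) + 0.016
        report = classify_mode(spikes, self.subs, self.entire, lag_ms=16.0)
        assert report.index == 1.0
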