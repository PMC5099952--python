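"""Synthetic session generator: schedule structure, Poisson statistics,
voltage rendering, array geometry, and determinism."""

import dataclasses

import numpy as np
import pytest

from neurosync import (SessionConfig, coverage_fraction, generate_network_spikes,
                       generate_session, render_extracellular,
                       render_intracellular, sample_burst_schedule)


def _config(**kw) -> SessionConfig:
    defaults = dict(n_electrodes=4, fs=20_000.0, duration=30.0)
    defaults.update(kw)
    return SessionConfig(**defaults)


class TestBurstSchedule:
    def test_zero_duration_yields_empty_schedule(self):
        schedule = sample_burst_schedule(_config(duration=0.0), seed=0)
        assert schedule.n_entire == 0 and schedule.n_sub == 0

    def test_degenerate_short_session_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            schedule = sample_burst_schedule(
                _config(duration=1.0, silence_s=(2.0, 2.0)), seed=0)
        assert schedule.n_entire == 0

    def test_fixed_ranges_enumerate_alternation(self):
        # silence exactly 10 s, entire burst exactly 2 s, 36 s session:
        # bursts at [10,12), [22,24), [34,36) - the last ends at the session end
        cfg = _config(duration=36.0, silence_s=(10.0, 10.0),
                      entire_burst_s=(2.0, 2.0))
        schedule = sample_burst_schedule(cfg, seed=0)
        onsets = [on for on, _ in schedule.entire_bursts]
        offsets = [off for _, off in schedule.entire_bursts]
        assert onsets == [10.0, 22.0, 34.0]
        assert offsets[-1] == 36.0

    def test_fixed_subburst_tiling_count(self):
        # 100 ms sub-bursts, 50 ms gaps tile a 2 s burst: onsets every 150 ms
        # at 0,150,...,1950 ms -> 14 sub-bursts, the last truncated
        cfg = _config(duration=14.0, silence_s=(10.0, 10.0),
                      entire_burst_s=(2.0, 2.0), sub_burst_ms=(100.0, 100.0),
                      gap_ms=(50.0, 50.0))
        schedule = sample_burst_schedule(cfg, seed=0)
        assert schedule.n_entire == 1
        assert schedule.n_sub == 14
        on0, off0, _ = schedule.sub_bursts[0]
        assert on0 == pytest.approx(10.0) and off0 == pytest.approx(10.1)
        assert schedule.sub_bursts[-1][1] == pytest.approx(12.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_intervals_sorted_disjoint_nested(self, seed):
        schedule = sample_burst_schedule(_config(duration=120.0), seed=seed)
        entire = np.asarray(schedule.entire_bursts).reshape(-1, 2)
        assert np.all(entire[:, 1] > entire[:, 0])
        assert np.all(entire[1:, 0] >= entire[:-1, 1])
        subs = schedule.sub_intervals()
        assert np.all(subs[:, 1] > subs[:, 0])
        assert np.all(subs[1:, 0] >= subs[:-1, 1])
        for on, off, parent in schedule.sub_bursts:
            p_on, p_off = schedule.entire_bursts[parent]
            assert p_on <= on and off <= p_off


class TestNetworkSpikes:
    def test_zero_baseline_empty_schedule_is_silent(self):
        cfg = _config(duration=10.0, baseline_rate_hz=0.0, blockers=True)
        schedule = sample_burst_schedule(cfg, seed=0)
        spikes = generate_network_spikes(schedule, cfg, seed=0)
        assert spikes.n_spikes == 0

    def test_subburst_poisson_count(self):
        # one 1 s sub-burst at 50 Hz/electrode on 60 electrodes: mean 3000
        cfg = _config(duration=3.0, n_electrodes=60, silence_s=(1.0, 1.0),
                      entire_burst_s=(1.0, 1.0), sub_burst_ms=(1000.0, 1000.0),
                      gap_ms=(20.0, 20.0), peak_rate_hz=50.0,
                      baseline_rate_hz=0.0)
        schedule = sample_burst_schedule(cfg, seed=1)
        assert schedule.n_sub == 1
        spikes = generate_network_spikes(schedule, cfg, seed=1)
        assert abs(spikes.n_spikes - 3000) <= 3 * np.sqrt(3000)

    def test_baseline_poisson_count(self):
        cfg = _config(duration=100.0, n_electrodes=1, baseline_rate_hz=0.1,
                      blockers=True)
        schedule = sample_burst_schedule(cfg, seed=2)
        spikes = generate_network_spikes(schedule, cfg, seed=2)
        assert abs(spikes.n_spikes - 10) <= 3 * np.sqrt(10)

    def test_spikes_confined_to_session_and_sorted(self):
        cfg = _config(duration=60.0)
        schedule = sample_burst_schedule(cfg, seed=3)
        spikes = generate_network_spikes(schedule, cfg, seed=3)
        for train in spikes.trains:
            assert np.all(np.diff(train) >= 0)
            if train.size:
                assert train[0] >= 0 and train[-1] < cfg.duration


class TestRenderExtracellular:
    def test_silent_noiseless_trace_is_zero(self):
        cfg = _config(duration=1.0, noise_sd_uv=0.0, blockers=True)
        schedule = sample_burst_schedule(cfg, seed=0)
        spikes = generate_network_spikes(schedule, cfg, seed=0)
        traces = render_extracellular(spikes, cfg, seed=0, channels=[0])
        assert np.all(traces[0].samples == 0.0)

    def test_single_spike_extremum_at_spike_sample(self):
        from neurosync.types import SpikeTrainSet
        cfg = _config(duration=1.0, noise_sd_uv=0.0, n_electrodes=1)
        spikes = SpikeTrainSet.from_lists([[0.5]])
        trace = render_extracellular(spikes, cfg, seed=0)[0]
        assert np.argmin(trace.samples) == round(0.5 * cfg.fs)
        assert np.abs(trace.samples).max() == pytest.approx(cfg.spike_amplitude_uv)

    def test_noise_sd_calibration(self):
        from neurosync.types import SpikeTrainSet
        cfg = _config(duration=10.0, noise_sd_uv=5.0, n_electrodes=1)
        trace = render_extracellular(SpikeTrainSet.from_lists([[]]), cfg, seed=0)[0]
        assert trace.samples.std() == pytest.approx(5.0, rel=0.02)


class TestRenderIntracellular:
    def test_empty_schedule_constant_baseline(self):
        cfg = _config(duration=1.0, blockers=True)
        schedule = sample_burst_schedule(cfg, seed=0)
        vm, spikes, env = render_intracellular(schedule, "correlated", cfg, seed=0)
        assert spikes.size == 0
        assert np.allclose(vm.samples, cfg.vm_baseline_mv)

    def test_correlated_spikes_in_lag_shifted_subbursts(self):
        cfg = _config(duration=60.0, lag_ms=16.0)
        schedule = sample_burst_schedule(cfg, seed=4)
        _vm, spikes, _env = render_intracellular(schedule, "correlated", cfg, seed=4)
        lag = cfg.lag_ms * 1e-3
        assert spikes.size > 0
        for t in spikes:
            assert any(on + lag <= t < off + lag
                       for on, off, _ in schedule.sub_bursts)

    def test_anticorrelated_spikes_avoid_subbursts(self):
        cfg = _config(duration=60.0, lag_ms=16.0)
        schedule = sample_burst_schedule(cfg, seed=5)
        _vm, spikes, _env = render_intracellular(schedule, "anticorrelated", cfg,
                                                 seed=5)
        assert spikes.size > 0
        for t in spikes:
            assert not any(on <= t < off for on, off, _ in schedule.sub_bursts)

    def test_envelope_depolarizes_during_bursts(self):
        cfg = _config(duration=30.0, silence_s=(2.0, 8.0),
                      entire_burst_s=(1.0, 3.0))
        schedule = sample_burst_schedule(cfg, seed=6)
        _vm, _spikes, env = render_intracellular(schedule, "correlated", cfg, seed=6)
        assert env.samples.min() >= cfg.vm_baseline_mv - 1e-9
        # peak depolarization reaches tens of mV above baseline
        assert env.samples.max() - cfg.vm_baseline_mv > 20.0


class TestCoverage:
    def test_reference_array_covers_two_percent(self):
        pct = coverage_fraction(6, 10, 0.5, 5.0)
        assert pct == pytest.approx(2.25)
        assert round(pct) == 2

    def test_full_coverage(self):
        # footprint equal to the culture area
        pct = coverage_fraction(2, 2, 10.0, 1.0)
        assert pct == pytest.approx(100.0)

    def test_zero_culture_area_rejected(self):
        with pytest.raises(ValueError):
            coverage_fraction(6, 10, 0.5, 0.0)


class TestSessionComposition:
    def test_same_seed_identical_bundles(self, small_config):
        b1, t1 = generate_session(small_config, seed=11)
        b2, t2 = generate_session(small_config, seed=11)
        for a, b in zip(b1.mea_spikes.trains, b2.mea_spikes.trains):
            assert np.array_equal(a, b)
        for p1, p2 in zip(b1.patches, b2.patches):
            assert np.array_equal(p1.spike_times, p2.spike_times)
            assert np.array_equal(p1.voltage.samples, p2.voltage.samples)
        assert np.array_equal(b1.triggers["patch"], b2.triggers["patch"])

    def test_blockers_session_is_burst_free(self):
        cfg = _config(duration=30.0, blockers=True)
        bundle, truth = generate_session(cfg, seed=0)
        assert truth.schedule.n_entire == 0
        assert all(p.spike_times.size == 0 for p in bundle.patches)

    def test_default_config_reports_sixty_channels(self):
        cfg = SessionConfig(duration=2.0, fs=2000.0, silence_s=(0.5, 0.5),
                            entire_burst_s=(0.5, 0.5))
        bundle, _ = generate_session(cfg, seed=0)
        assert bundle.mea_spikes.n_channels == 60

    def test_adding_channels_preserves_existing_draws(self):
        cfg20 = _config(duration=20.0, n_electrodes=20, silence_s=(2.0, 6.0))
        cfg30 = dataclasses.replace(cfg20, n_electrodes=30)
        s20 = generate_network_spikes(sample_burst_schedule(cfg20, 1), cfg20, 1)
        s30 = generate_network_spikes(sample_burst_schedule(cfg30, 1), cfg30, 1)
        for a, b in zip(s20.trains, s30.trains):
            assert np.array_equal(a, b)
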