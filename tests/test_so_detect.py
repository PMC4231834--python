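"""Slow-oscillation detector: filter chain, candidate segmentation,
acceptance criteria, peristimulus binning and rates."""

import numpy as np
import pytest

from sleepentrain.core import make_event_log
from sleepentrain.so_detect import (
    SlowOscillation,
    apply_criteria,
    bin_up_states,
    find_candidates,
    so_filter_chain,
    up_state_rate,
    z_normalize,
)

FS = 250.0


def _sine_trace(freq, amps, fs=FS):
    """Concatenated full cycles of a sine, one amplitude per cycle,
    starting on the positive half-wave."""
    n_cycle = int(round(fs / freq))
    t = np.arange(n_cycle) / fs
    return np.concatenate([a * np.sin(2 * np.pi * freq * t) for a in amps])


def _events(onsets):
    n = len(onsets)
    return make_event_log(onsets, range(n), np.zeros(n), np.full(n, 50.0))


class TestFilterChain:
    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            so_filter_chain(np.zeros(100), 100.0)

    def test_output_rate_is_250(self):
        y, fs = so_filter_chain(np.zeros(5000), 500.0)
        assert fs == 250.0
        assert y.size == 2500

    def test_dc_rejected(self):
        y, _ = so_filter_chain(np.ones(int(120 * 500)), 500.0)
        mid = y[int(30 * 250): int(90 * 250)]
        assert np.abs(mid).max() < 1e-6

    @pytest.mark.parametrize("freq,lo,hi", [
        (1.0, 0.95, 1.05),     # passband: within 5% of unity
        (10.0, 0.0, 0.01),     # stopband: strongly attenuated
        (0.05, 0.0, 0.05),
    ])
    def test_frequency_response(self, freq, lo, hi):
        t = np.arange(int(200 * 500)) / 500.0
        y, fs = so_filter_chain(np.sin(2 * np.pi * freq * t), 500.0)
        gain = np.abs(y[int(50 * fs): int(150 * fs)]).max()
        assert lo <= gain <= hi


class TestCandidates:
    def test_pure_0p8hz_sine_durations_equal_period(self):
        cands = find_candidates(_sine_trace(0.8, np.ones(40)))
        assert len(cands) >= 35
        assert np.allclose([c.duration for c in cands], 1.25, atol=0.01)

    def test_3hz_sine_durations_one_third_second(self):
        cands = find_candidates(_sine_trace(3.0, np.ones(30)))
        assert np.allclose([c.duration for c in cands], 1 / 3, atol=0.01)

    def test_all_positive_signal_yields_no_candidates(self):
        assert find_candidates(np.ones(1000) + 0.1) == []

    def test_candidate_peaks_and_transition(self):
        cands = find_candidates(_sine_trace(0.8, np.ones(10)))
        c = cands[0]
        assert c.neg_peak_amp == pytest.approx(-1.0, abs=0.01)
        assert c.pos_peak_amp == pytest.approx(1.0, abs=0.01)
        assert c.neg_peak_time < c.transition_time < c.pos_peak_time
        assert c.start <= c.neg_peak_time <= c.end


class TestCriteria:
    def test_uniform_sine_train_all_accepted(self):
        cands = find_candidates(_sine_trace(0.8, np.ones(20)))
        assert len(apply_criteria(cands)) == len(cands)

    def test_half_amplitude_cycle_rejected_by_hand_thresholds(self):
        # negative-half-first cycles so each candidate (positive-to-negative
        # crossing pair) contains exactly one cycle's trough and peak; a
        # leading positive half-wave provides the opening crossing
        amps = np.ones(13)
        amps[6] = 0.5
        n_half = int(round(FS / 0.8 / 2))
        lead = np.sin(np.pi * np.arange(n_half) / n_half)
        trace = np.concatenate([lead] + [
            -a * np.sin(2 * np.pi * 0.8 * np.arange(2 * n_half) / FS)
            for a in amps] + [lead, -lead])  # closing crossing at the end
        cands = find_candidates(trace)
        pool = [c for c in cands if 0.9 <= c.duration <= 2.0]
        assert len(pool) == 13
        # hand-recomputed thresholds over the pool
        mean_neg = np.mean([c.neg_peak_amp for c in pool])
        mean_ptp = np.mean([c.ptp for c in pool])
        weak = min(pool, key=lambda c: c.ptp)
        assert weak.neg_peak_amp > (2 / 3) * mean_neg      # fails criterion 2
        assert weak.ptp < (2 / 3) * mean_ptp               # fails criterion 3
        accepted = apply_criteria(cands)
        assert weak not in accepted
        assert len(accepted) == len(pool) - 1

    def test_3hz_sine_rejected_by_duration(self):
        assert apply_criteria(find_candidates(_sine_trace(3.0,
                                                          np.ones(30)))) == []

    def test_scaling_trace_leaves_accepted_set_unchanged(self, rng):
        amps = rng.uniform(0.4, 1.6, 25)
        base = _sine_trace(0.8, amps)
        a1 = apply_criteria(find_candidates(base))
        a2 = apply_criteria(find_candidates(7.3 * base))
        assert [(c.start, c.end) for c in a1] == [(c.start, c.end)
                                                  for c in a2]

    def test_clean_burst_count_recovery(self):
        k = 17
        accepted = apply_criteria(find_candidates(_sine_trace(0.8,
                                                              np.ones(k))))
        assert abs(len(accepted) - k) <= 1   # boundary cycles only


class TestBinning:
    def _so(self, pos_t, amp=1.0):
        return SlowOscillation(start=pos_t - 0.5, end=pos_t + 0.5,
                               neg_peak_time=pos_t - 0.3, neg_peak_amp=-amp,
                               pos_peak_time=pos_t, pos_peak_amp=amp)

    def test_peaks_fall_in_expected_bins(self):
        sos = [self._so(10.50), self._so(11.10)]
        series = bin_up_states(sos, _events([10.0]))
        expected = np.zeros(20, int)
        expected[7] = 1   # [0.4, 0.6)
        expected[10] = 1  # [1.0, 1.2)
        assert series.counts.tolist() == expected.tolist()
        assert np.isnan(series.mean_amp[0])
        assert series.mean_amp[7] == 1.0

    def test_peak_on_edge_goes_to_right_bin(self):
        series = bin_up_states([self._so(10.2)], _events([10.0]))
        assert series.counts[6] == 1      # bin [0.2, 0.4)
        assert series.counts[5] == 0

    def test_no_oscillations_all_zero(self):
        series = bin_up_states([], _events([10.0]))
        assert series.counts.sum() == 0
        assert np.isnan(series.mean_amp).all()

    def test_total_counts_equal_peaks_in_window(self, rng):
        sos = [self._so(t) for t in rng.uniform(0, 40, 60)]
        onsets = [10.0, 20.0, 30.0]
        series = bin_up_states(sos, _events(onsets))
        manual = sum(1 for s in sos for o in onsets
                     if -1 <= s.pos_peak_time - o < 3)
        assert series.counts.sum() == manual


class TestZNormalize:
    def test_constant_input_maps_to_zero(self):
        assert np.allclose(z_normalize(np.full(20, 4.0)), 0.0)

    def test_mean_zero_sd_one(self, rng):
        z = z_normalize(rng.normal(size=20))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_population_sd_convention(self):
        z = z_normalize(np.array([0.0, 1.0, 2.0]))
        assert np.allclose(z, [-1.224745, 0.0, 1.224745], atol=1e-5)

    def test_nan_preserved(self):
        z = z_normalize(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2]]).any()


class TestRate:
    def _so(self, pos_t):
        return SlowOscillation(start=pos_t - 0.5, end=pos_t + 0.5,
                               neg_peak_time=pos_t - 0.3, neg_peak_amp=-1,
                               pos_peak_time=pos_t, pos_peak_amp=1)

    def test_rate_arithmetic(self):
        # 1 peak in an 0.8 s window over 1 event -> 1.25 /s
        r = up_state_rate([self._so(10.5)], _events([10.0]), (100, 900))
        assert r == pytest.approx(1.25)

    def test_no_peaks_zero_rate(self):
        assert up_state_rate([], _events([10.0]), (0, 1000)) == 0.0

    def test_zero_events_error(self):
        ev = _events([10.0])
        ev["excluded"] = True
        with pytest.raises(ValueError):
            up_state_rate([], ev, (0, 1000))
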