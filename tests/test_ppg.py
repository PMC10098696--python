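import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from e4stress import (
    LabeledSegment,
    accept_ppg_segment,
    bandpass_filter_ppg,
    compute_pp_intervals,
    detect_pulse_peaks,
    segment_signal,
    validate_pp_intervals,
)
from e4stress.io import ProtocolSchedule, ScheduleInterval
from conftest import make_signal


def seg(values, rate=64.0, label=0):
    return LabeledSegment(values=np.asarray(values, float), rate_hz=rate, label=label)


class TestSegmentSignal:
    def test_tiling_counts_per_interval(self):
        sched = ProtocolSchedule(
            (ScheduleInterval(0, 180, 0, "rest"), ScheduleInterval(180, 780, 1, "task"))
        )
        sig = make_signal(np.zeros(64 * 780), 64.0)
        segments = segment_signal(sig, sched)
        rest = [s for s in segments if s.label == 0]
        task = [s for s in segments if s.label == 1]
        assert len(rest) == 3 and len(task) == 10
        assert all(s.values.size == 3840 for s in segments)
        assert [s.window_index for s in segments] == list(range(13))

    def test_interval_tail_is_discarded(self):
        sched = ProtocolSchedule((ScheduleInterval(0, 90, 1, "task"),))
        sig = make_signal(np.zeros(64 * 90), 64.0)
        assert len(segment_signal(sig, sched)) == 1

    def test_boundary_straddling_windows_dropped(self):
        # 90-s intervals: one window each, never a mixed-label window
        sched = ProtocolSchedule(
            (ScheduleInterval(0, 90, 0, "rest"), ScheduleInterval(90, 180, 1, "task"))
        )
        sig = make_signal(np.zeros(64 * 180), 64.0)
        segments = segment_signal(sig, sched)
        assert [s.label for s in segments] == [0, 1]
        assert segments[1].start_s == 90

    def test_empty_schedule_errors(self):
        with pytest.raises(ValueError):
            segment_signal(make_signal(np.zeros(64 * 60)), ProtocolSchedule(()))


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        out = bandpass_filter_ppg(seg(np.zeros(3840)))
        np.testing.assert_allclose(out.values, 0.0)

    @pytest.mark.parametrize(
        "freq,max_loss_db,min_loss_db",
        [(1.5, 3.0, None), (0.1, None, 20.0), (3.0, 3.0, None)],
    )
    def test_band_edges(self, freq, max_loss_db, min_loss_db):
        t = np.arange(3840) / 64.0
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass_filter_ppg(seg(x)).values
        # discard edge transients before comparing RMS
        core = slice(320, -320)
        loss_db = -20 * np.log10(
            np.sqrt(np.mean(y[core] ** 2)) / np.sqrt(np.mean(x[core] ** 2))
        )
        if max_loss_db is not None:
            assert loss_db < max_loss_db
        if min_loss_db is not None:
            assert loss_db >= min_loss_db

    def test_magnitude_response_from_impulse_dft(self):
        # independent oracle: DFT of the forward-backward impulse response
        n = 8192
        impulse = np.zeros(n)
        impulse[n // 2] = 1.0
        h = bandpass_filter_ppg(seg(impulse)).values
        freqs = np.fft.rfftfreq(n, 1 / 64.0)
        mag = np.abs(np.fft.rfft(h))
        passband = (freqs > 1.0) & (freqs < 4.0)
        stopband_lo = freqs <= 0.1
        assert mag[passband].min() > 10 ** (-3 / 20)
        assert mag[stopband_lo].max() < 10 ** (-20 / 20)

    def test_rate_too_low_errors(self):
        with pytest.raises(ValueError):
            bandpass_filter_ppg(seg(np.zeros(100), rate=8.0))


class TestDetectPulsePeaks:
    def test_constant_zero_has_no_peaks(self):
        assert detect_pulse_peaks(seg(np.zeros(3840))).size == 0

    def test_distance_rule_keeps_higher_peak(self):
        rate = 64.0
        x = np.zeros(int(rate * 2))
        x[32] = 1.0  # t = 0.5 s
        x[32 + int(0.3 * rate)] = 0.8  # 0.3 s later
        times = detect_pulse_peaks(seg(x, rate))
        assert times.size == 1
        assert times[0] == pytest.approx(0.5)

    def test_min_distance_respected_on_noise(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 3840)
        times = detect_pulse_peaks(seg(x))
        assert np.all(np.diff(times) >= 0.4 - 1e-12)

    def test_recovers_sixty_bpm_pulse_train(self, schedule, clean_recording):
        bvp, _, _, _ = clean_recording
        segments = segment_signal(bvp, schedule)
        filtered = bandpass_filter_ppg(segments[0])
        peaks = detect_pulse_peaks(filtered)
        # rest HR 65 bpm in the clean subject: ~65 peaks per minute
        assert 62 <= peaks.size <= 68


class TestPPIntervals:
    def test_successive_differences_in_ms(self):
        np.testing.assert_allclose(
            compute_pp_intervals(np.array([0.0, 0.8, 1.6])), [800.0, 800.0]
        )
        np.testing.assert_allclose(compute_pp_intervals(np.array([0.0, 0.45])), [450.0])

    def test_equally_spaced_61_peaks(self):
        intervals = compute_pp_intervals(np.linspace(0, 60, 61))
        assert intervals.size == 60
        np.testing.assert_allclose(intervals, 1000.0)

    def test_fewer_than_two_peaks_gives_empty(self):
        assert compute_pp_intervals(np.array([0.3])).size == 0
        assert compute_pp_intervals(np.array([])).size == 0


class TestValidatePPIntervals:
    def test_rule_application(self):
        pp = validate_pp_intervals(np.array([800.0, 450.0, 900.0, 1300.0, 750.0]))
        np.testing.assert_allclose(pp.pp_intervals_ms, [800, 900, 750])
        assert pp.abnormal_fraction == pytest.approx(0.4)

    def test_bounds_are_inclusive_and_map_to_hr(self):
        pp = validate_pp_intervals(np.array([500.0, 1200.0, 499.9, 1200.1]))
        np.testing.assert_allclose(pp.pp_intervals_ms, [500, 1200])
        # interval <-> instantaneous HR conversions
        assert 60000 / 500 == pytest.approx(120)
        assert 60000 / 1200 == pytest.approx(50)
        assert 60000 / 600 == pytest.approx(100)

    def test_all_abnormal(self):
        pp = validate_pp_intervals(np.array([1500.0, 400.0]))
        assert pp.pp_intervals_ms.size == 0
        assert pp.abnormal_fraction == 1.0

    @given(
        st.lists(st.floats(min_value=100, max_value=3000), min_size=1, max_size=200)
    )
    @settings(deadline=None, max_examples=50)
    def test_counts_conserved_and_fraction_bounded(self, raw):
        pp = validate_pp_intervals(np.array(raw))
        assert pp.pp_intervals_ms.size + pp.excluded_ms.size == len(raw)
        assert 0.0 <= pp.abnormal_fraction <= 1.0
        assert np.all((pp.pp_intervals_ms >= 500) & (pp.pp_intervals_ms <= 1200))


class TestAcceptSegment:
    def test_strictly_less_than_fifteen_percent(self):
        retained = np.full(86, 800.0)
        accept = validate_pp_intervals(np.r_[retained, np.full(14, 400.0)])
        reject = validate_pp_intervals(np.r_[np.full(85, 800.0), np.full(15, 400.0)])
        assert accept.abnormal_fraction == pytest.approx(0.14)
        assert reject.abnormal_fraction == pytest.approx(0.15)
        assert accept_ppg_segment(accept)
        assert not accept_ppg_segment(reject)

    def test_empty_retained_always_rejected(self):
        pp = validate_pp_intervals(np.array([400.0]))
        assert not accept_ppg_segment(pp)

    def test_duration_mode_bounds_retained_time(self):
        # duration-weighted rule: worst accepted 60-s segment keeps > 50 s
        pp = validate_pp_intervals(
            np.r_[np.full(51, 1000.0), np.full(3, 2999.0)]
        )
        assert pp.abnormal_fraction_duration < 0.15
        assert accept_ppg_segment(pp, fraction_mode="duration")
        assert pp.pp_intervals_ms.sum() / 1000 > 50

    def test_spurious_peak_injection_matches_brute_force(self):
        # oracle: straightforward re-application of the rules on the peak list
        rng = np.random.default_rng(3)
        clean = np.cumsum(rng.uniform(0.7, 0.9, 70))
        clean = clean[clean < 60]
        spurious = rng.uniform(5, 55, 4)
        peaks = np.sort(np.r_[clean, spurious])
        # package path
        pp = validate_pp_intervals(compute_pp_intervals(peaks))
        # brute force: diff, classify each interval
        diffs = (peaks[1:] - peaks[:-1]) * 1000
        n_abn = sum(1 for d in diffs if d < 500 or d > 1200)
        assert pp.excluded_ms.size == n_abn
        assert pp.abnormal_fraction == pytest.approx(n_abn / diffs.size)
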