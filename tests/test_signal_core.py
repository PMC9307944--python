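import numpy as np
import pytest

from hrvsuite.signal_core import (
    ADULT_BOUNDS,
    FETAL_BOUNDS,
    InsufficientBeatsError,
    NonMonotonePeaksError,
    PeakSeries,
    RRISeries,
    UncorrectableSeriesError,
    correct_artifacts,
    interpolate_rri,
    peaks_to_rri,
    read_peaks_csv,
    segment_series,
    trim_trailing_zeros,
)


def peaks(times, fs=1000.0):
    return PeakSeries(np.asarray(times), sampling_rate=fs)


class TestTrimTrailingZeros:
    def test_trailing_zeros_removed(self):
        out = trim_trailing_zeros(peaks([100, 900, 1700, 0, 0]))
        assert list(out.times) == [100, 900, 1700]

    def test_identity_without_zeros(self):
        out = trim_trailing_zeros(peaks([100, 900, 1700]))
        assert list(out.times) == [100, 900, 1700]

    def test_interior_zero_kept(self):
        out = trim_trailing_zeros(peaks([0, 900, 1700, 0]))
        assert list(out.times) == [0, 900, 1700]

    def test_all_zero_raises(self):
        with pytest.raises(InsufficientBeatsError):
            trim_trailing_zeros(peaks([0, 0, 0]))


class TestPeaksToRRI:
    def test_unit_spacing(self):
        rri = peaks_to_rri(peaks([0, 1000, 2000]))
        assert rri.intervals.tolist() == [1000.0, 1000.0]

    def test_direct_difference(self):
        rri = peaks_to_rri(peaks([0, 500, 1100]))
        assert rri.intervals.tolist() == [500.0, 600.0]

    def test_non_1000hz_rate(self):
        rri = peaks_to_rri(peaks([0, 250], fs=500.0))
        assert rri.intervals.tolist() == [500.0]

    def test_non_monotone_raises(self):
        with pytest.raises(NonMonotonePeaksError):
            peaks_to_rri(peaks([0, 1000, 900]))

    def test_too_few_raises(self):
        with pytest.raises(InsufficientBeatsError):
            peaks_to_rri(peaks([100]))

    def test_roundtrip_cumsum_identity(self, rng):
        intervals = rng.uniform(500, 1200, 200)
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        rri = peaks_to_rri(PeakSeries(times, sampling_rate=1000.0))
        np.testing.assert_allclose(rri.intervals, intervals)


class TestInterpolateRRI:
    def test_constant_preserved(self):
        p = peaks(np.arange(0, 80000, 800))
        rri = peaks_to_rri(p)
        signal, rate = interpolate_rri(rri, p, target_rate=10)
        np.testing.assert_allclose(signal, 800.0)

    def test_rate_promoted_to_floor(self):
        p = peaks(np.arange(0, 80000, 800))
        rri = peaks_to_rri(p)
        _, rate = interpolate_rri(rri, p, target_rate=4)
        assert rate == 10.0

    def test_linear_ramp_fixed_point(self):
        intervals = np.linspace(700, 900, 50)
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        p = PeakSeries(times, sampling_rate=1000.0)
        rri = peaks_to_rri(p)
        signal, rate = interpolate_rri(rri, p, target_rate=10)
        anchors = times[1:] / 1000.0
        grid = np.arange(signal.size) / rate
        inside = (grid >= anchors[0]) & (grid <= anchors[-1])
        expected = np.interp(grid[inside], anchors, intervals)
        np.testing.assert_allclose(signal[inside], expected)

    def test_too_few_peaks(self):
        p = peaks([0, 800])
        with pytest.raises(InsufficientBeatsError):
            interpolate_rri(peaks_to_rri(p), p)


def constant_peaks(interval_ms=800, n=100, anomalies=()):
    iv = [float(interval_ms)] * n
    for idx, val in anomalies:
        iv[idx] = val
    times = np.concatenate([[0.0], np.cumsum(iv)])
    return PeakSeries(times, sampling_rate=1000.0)


class TestCorrectArtifacts:
    def test_clean_input_unchanged(self):
        p = constant_peaks()
        out, report = correct_artifacts(p, 0.4, 1.5)
        np.testing.assert_array_equal(out.times, p.times.astype(np.int64))
        assert len(report) == 0

    def test_missed_beat_split(self):
        p = constant_peaks(anomalies=[(50, 1600.0)])
        out, report = correct_artifacts(p, 0.4, 1.5)
        kinds = {c.kind for c in report.corrections}
        assert kinds == {"missed_inserted"}
        iv = np.diff(out.times)
        assert len(out) == len(p) + 1  # one beat inserted
        assert np.all((iv >= 400) & (iv <= 1500))
        np.testing.assert_allclose(iv[50:52], 800.0, atol=1)

    def test_extra_beat_merged(self):
        p = constant_peaks(anomalies=[(50, 200.0)])
        out, report = correct_artifacts(p, 0.4, 1.5)
        kinds = {c.kind for c in report.corrections}
        assert kinds == {"extra_merged"}
        assert len(out) == len(p) - 1
        iv = np.diff(out.times)
        assert np.all((iv >= 400) & (iv <= 1500))

    def test_ectopic_pair_interpolated(self):
        # short+long adjacent pair summing to ~2x the local median
        p = constant_peaks(anomalies=[(50, 300.0), (51, 1300.0)])
        out, report = correct_artifacts(p, 0.4, 1.5)
        kinds = {c.kind for c in report.corrections}
        assert kinds == {"ectopic_interpolated"}
        assert len(out) == len(p)  # beat count preserved
        iv = np.diff(out.times)
        np.testing.assert_allclose(iv[50:52], 800.0, atol=1)

    def test_idempotent(self):
        p = constant_peaks(anomalies=[(20, 1600.0), (60, 200.0)])
        once, report1 = correct_artifacts(p, 0.4, 1.5)
        twice, report2 = correct_artifacts(once, 0.4, 1.5)
        assert len(report1) > 0
        assert len(report2) == 0
        np.testing.assert_array_equal(once.times, twice.times)

    def test_duration_conserved(self):
        p = constant_peaks(anomalies=[(20, 1600.0), (60, 200.0), (80, 250.0)])
        out, _ = correct_artifacts(p, 0.4, 1.5)
        assert abs(out.duration_s - p.duration_s) <= 1.5  # one interval_max

    def test_uncorrectable_raises(self):
        p = constant_peaks(interval_ms=800, n=20)
        with pytest.raises(UncorrectableSeriesError):
            correct_artifacts(p, 0.1, 0.25)

    def test_ectopic_count_matches_changed_positions(self):
        # ectopic corrections keep the interval count, so the report length
        # equals the number of positions whose value changed
        p = constant_peaks(anomalies=[(50, 300.0), (51, 1300.0)])
        out, report = correct_artifacts(p, 0.4, 1.5)
        changed = np.sum(np.abs(np.diff(out.times) - np.diff(p.times)) > 1)
        assert len(report) == changed

    def test_report_serializes(self):
        p = constant_peaks(anomalies=[(50, 1600.0)])
        _, report = correct_artifacts(p, 0.4, 1.5)
        frame = report.to_frame("subject1")
        assert list(frame.columns) == ["SubjectID", "index", "class", "before_ms", "after_ms"]
        assert (frame["SubjectID"] == "subject1").all()
        assert frame["index"].between(0, len(p)).all()

    def test_default_bounds_profiles(self):
        assert FETAL_BOUNDS == (0.33, 0.75)
        assert ADULT_BOUNDS == (0.4, 1.5)


class TestSegmentSeries:
    def _recording(self, minutes, interval_ms=1000.0):
        n = int(minutes * 60 * 1000 / interval_ms)
        times = np.arange(n + 1) * interval_ms
        p = PeakSeries(times, sampling_rate=1000.0)
        return p, peaks_to_rri(p)

    def test_25_minutes_gives_5_segments(self):
        p, rri = self._recording(25)
        segs = segment_series(p, rri, window_minutes=5)
        assert len(segs) == 5
        assert not segs.last_partial

    def test_identity_window(self):
        p, rri = self._recording(5)
        segs = segment_series(p, rri, window_minutes=5)
        assert len(segs) == 1
        assert not segs.last_partial

    def test_subwindow_input_single_partial(self):
        p, rri = self._recording(2)
        segs = segment_series(p, rri, window_minutes=5)
        assert len(segs) == 1
        assert segs.last_partial

    def test_conservation_of_beats_and_duration(self, stationary_recording):
        p, rri, _ = stationary_recording
        segs = segment_series(p, rri, window_minutes=5)
        total_beats = sum(len(sr) for _, sr in segs)
        assert total_beats == len(rri)
        total_duration = sum(sr.duration_s for _, sr in segs)
        np.testing.assert_allclose(total_duration, rri.duration_s, rtol=1e-12)

    def test_segments_are_contiguous(self, stationary_recording):
        p, rri, _ = stationary_recording
        segs = segment_series(p, rri, window_minutes=5)
        joined = np.concatenate([sr.intervals for _, sr in segs])
        np.testing.assert_array_equal(joined, rri.intervals)

    def test_whole_recording_mode(self, stationary_recording):
        p, rri, _ = stationary_recording
        segs = segment_series(p, rri, window_minutes=5, n_segments=1)
        assert len(segs) == 1


def test_read_peaks_csv(tmp_path):
    path = tmp_path / "peaks.csv"
    path.write_text("0\n800\n1600\n")
    p = read_peaks_csv(path, sampling_rate=1000.0)
    assert list(p.times) == [0, 800, 1600]
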