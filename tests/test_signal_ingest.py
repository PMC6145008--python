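"""Waveform IO, filtering, beat detection, screening, segmentation."""

import numpy as np
import pytest

from hrvc.signal_ingest import (
    IBISeries,
    IngestError,
    InsufficientDurationError,
    InvalidBandError,
    NonIncreasingBeatsError,
    NonMonotoneTimeError,
    TooFewBeatsError,
    WaveformParseError,
    WaveformRecord,
    WindowTooLargeError,
    BeatSequence,
    detect_beats,
    extract_segment,
    fft_filter,
    read_ibi,
    read_waveform,
    screen_ectopics,
    to_ibi,
    write_ibi,
)
from hrvc.synthetic import generate_ibi, SyntheticProfile, synthesize_ecg, synthesize_ppg


class TestReadWaveform:
    def test_single_column_with_rate(self, tmp_path):
        path = tmp_path / "w.csv"
        np.savetxt(path, np.sin(np.arange(3000) / 50.0))
        w = read_waveform(path, sampling_rate=500.0)
        assert w.n_samples == 3000
        assert w.duration == pytest.approx(6.0)

    def test_two_column_infers_rate(self, tmp_path):
        path = tmp_path / "w.csv"
        t = np.arange(1000) * 0.002
        np.savetxt(path, np.column_stack([t, np.sin(t)]), delimiter=",")
        w = read_waveform(path)
        assert w.sampling_rate == pytest.approx(500.0)

    def test_non_numeric_row_named(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("1.0\n2.0\noops\n4.0\n")
        with pytest.raises(WaveformParseError, match="row 3"):
            read_waveform(path, sampling_rate=100.0)

    def test_non_monotone_time_column(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("0.0,1\n0.2,2\n0.1,3\n0.3,4\n")
        with pytest.raises(NonMonotoneTimeError):
            read_waveform(path)

    def test_missing_rate_rejected(self, tmp_path):
        path = tmp_path / "w.csv"
        np.savetxt(path, np.arange(10.0))
        with pytest.raises(IngestError):
            read_waveform(path)


class TestIBIFileRoundTrip:
    def test_write_then_read(self, tmp_path):
        ibi = IBISeries([800.0, 810.0, 795.0], flags=["normal", "ectopic", "normal"])
        path = tmp_path / "s.rr"
        write_ibi(ibi, path)
        back = read_ibi(path)
        np.testing.assert_allclose(back.intervals, ibi.intervals)
        assert list(back.flags) == list(ibi.flags)

    def test_plain_interval_list(self, tmp_path):
        path = tmp_path / "s.rr"
        path.write_text("800\n820\n790\n")
        back = read_ibi(path)
        np.testing.assert_allclose(back.intervals, [800, 820, 790])
        assert (back.flags == "normal").all()


class TestFFTFilter:
    fs = 500.0

    def _tone(self, freq, n=5000):
        t = np.arange(n) / self.fs
        return WaveformRecord(np.sin(2 * np.pi * freq * t), self.fs)

    def test_stopband_tone_attenuated(self):
        w = self._tone(50.0)
        out = fft_filter(w, (0.5, 40.0))
        assert np.sum(out.samples**2) < 0.01 * np.sum(w.samples**2)

    def test_passband_tone_preserved(self):
        w = self._tone(10.0)
        out = fft_filter(w, (0.5, 40.0))
        corr = np.corrcoef(w.samples, out.samples)[0, 1]
        assert corr > 0.99

    def test_full_band_is_identity(self, rng):
        # odd length so every representable frequency lies below Nyquist
        w = WaveformRecord(rng.standard_normal(4095), self.fs)
        out = fft_filter(w, (0.0, self.fs / 2 - 1e-6))
        np.testing.assert_allclose(out.samples, w.samples, atol=1e-10)

    def test_preserves_length_and_linearity(self, rng):
        x = WaveformRecord(rng.standard_normal(1000), self.fs)
        y = WaveformRecord(rng.standard_normal(1000), self.fs)
        band = (1.0, 30.0)
        combo = WaveformRecord(2.0 * x.samples - 3.0 * y.samples, self.fs)
        lhs = fft_filter(combo, band).samples
        rhs = 2.0 * fft_filter(x, band).samples - 3.0 * fft_filter(y, band).samples
        assert lhs.size == 1000
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("band", [(40.0, 0.5), (-1.0, 40.0), (0.5, 400.0)])
    def test_invalid_bands_rejected(self, band):
        w = self._tone(10.0)
        with pytest.raises(InvalidBandError):
            fft_filter(w, band)


class TestDetectBeats:
    def test_recovers_known_beat_times_within_one_sample(self):
        ibi = IBISeries([800.0, 800.0, 900.0])
        wave = synthesize_ecg(ibi, sampling_rate=500.0)
        beats = detect_beats(wave)
        assert len(beats) == 4
        rel = beats.beat_times - beats.beat_times[0]
        np.testing.assert_allclose(rel, [0.0, 0.8, 1.6, 2.5], atol=1 / 500.0)

    def test_flatline_warns_and_returns_empty(self):
        w = WaveformRecord(np.zeros(5000), 500.0)
        with pytest.warns(RuntimeWarning, match="flatline"):
            beats = detect_beats(w)
        assert len(beats) == 0
        assert beats.warning is not None

    def test_ecg_and_ppg_renderings_agree(self):
        src = generate_ibi(SyntheticProfile(seed=5), duration=60)
        ibi = IBISeries(src.intervals[:60])
        i_ecg = to_ibi(detect_beats(synthesize_ecg(ibi), method="ecg_qrs"))
        i_ppg = to_ibi(detect_beats(synthesize_ppg(ibi), method="ppg_pulse"))
        assert i_ecg.n == i_ppg.n == 60
        assert np.max(np.abs(i_ecg.intervals - i_ppg.intervals)) <= 4.0

    def test_round_trip_on_noiseless_ecg(self):
        src = generate_ibi(SyntheticProfile(seed=9), duration=120)
        beats = detect_beats(synthesize_ecg(src))
        rec = to_ibi(beats)
        assert rec.n == src.n
        # within +-(2/fs)*1000 ms per interval on noiseless input
        assert np.max(np.abs(rec.intervals - src.intervals)) <= 4.0

    def test_unknown_method_rejected(self):
        w = WaveformRecord(np.random.default_rng(0).standard_normal(1000), 500.0)
        with pytest.raises(IngestError):
            detect_beats(w, method="nope")


class TestToIBI:
    def test_interval_arithmetic(self):
        beats = BeatSequence(np.array([0.0, 0.8, 1.6, 2.5]), "test", "ecg")
        ibi = to_ibi(beats)
        np.testing.assert_allclose(ibi.intervals, [800.0, 800.0, 900.0])
        assert (ibi.flags == "normal").all()

    def test_two_beats_give_one_interval(self):
        assert to_ibi(BeatSequence(np.array([0.0, 0.75]), "t", "ecg")).n == 1

    def test_too_few_beats_rejected(self):
        with pytest.raises(TooFewBeatsError):
            to_ibi(BeatSequence(np.array([1.0]), "t", "ecg"))

    def test_non_increasing_beats_rejected(self):
        with pytest.raises(NonIncreasingBeatsError):
            BeatSequence(np.array([0.0, 0.8, 0.8]), "t", "ecg")


class TestScreenEctopics:
    def test_single_doubled_interval_flagged(self):
        x = np.full(200, 800.0)
        x[100] = 1600.0
        out = screen_ectopics(IBISeries(x))
        assert (out.flags == "ectopic").sum() == 1
        assert out.flags[100] == "ectopic"

    def test_clean_series_unflagged(self):
        out = screen_ectopics(IBISeries(np.full(50, 800.0)))
        assert out.flagged_fraction == 0.0

    def test_planted_ectopics_all_and_only_flagged(self, rng):
        x = 800 + 10 * rng.standard_normal(300)
        planted = [40, 90, 150, 210, 280]
        x[planted] *= 2.0
        out = screen_ectopics(IBISeries(x), deviation_fraction=0.20)
        assert sorted(np.nonzero(out.flags == "ectopic")[0]) == planted

    def test_flag_action_is_idempotent(self, rng):
        x = 800 + 10 * rng.standard_normal(300)
        x[::37] *= 1.8
        once = screen_ectopics(IBISeries(x))
        twice = screen_ectopics(once)
        np.testing.assert_array_equal(once.flags, twice.flags)

    def test_interpolate_replaces_with_local_median(self):
        x = np.full(99, 800.0)
        x[50] = 1600.0
        out = screen_ectopics(IBISeries(x), action="interpolate")
        assert out.intervals[50] == pytest.approx(800.0)
        assert out.flags[50] == "edited"

    def test_delete_removes_interval(self):
        x = np.full(99, 800.0)
        x[50] = 1600.0
        out = screen_ectopics(IBISeries(x), action="delete")
        assert out.n == 98

    def test_oversized_window_rejected(self):
        with pytest.raises(WindowTooLargeError):
            screen_ectopics(IBISeries(np.full(5, 800.0)), window=11)


class TestExtractSegment:
    def test_ten_minutes_of_800ms_beats(self):
        ibi = IBISeries(np.full(900, 800.0))
        seg = extract_segment(ibi, duration=600.0)
        assert seg.n == 750

    def test_insufficient_recording_names_available_duration(self):
        ibi = IBISeries(np.full(375, 800.0))  # 300 s
        with pytest.raises(InsufficientDurationError, match="300.0 s"):
            extract_segment(ibi, duration=600.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(IngestError):
            extract_segment(IBISeries(np.full(10, 800.0)), duration=0.0)

    def test_cumulative_sum_lands_in_window(self, rng):
        for _ in range(10):
            x = rng.uniform(600, 1100, size=1200)
            seg = extract_segment(IBISeries(x), duration=600.0)
            total = seg.intervals.sum() / 1000.0
            assert 600.0 - x.max() / 1000.0 < total <= 600.0
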