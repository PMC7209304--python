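import numpy as np
import pytest

from heartbrain.preprocessing import mark_manual, segment_epochs
from heartbrain.signal_io import Recording, TimeWindowSpec
from heartbrain.spectral_analysis import (
    DEFAULT_BANDS,
    BandDefinition,
    BandPowerSeries,
    Spectrogram,
    band_power_series,
    compute_spectrogram,
    epoch_peak_frequency,
    median_band_power,
    median_peak_frequency,
    total_median_power,
)

RATE = 256.0


def _rec(x, t_inj=0.0):
    return Recording(np.asarray(x, float), rate_hz=RATE, t_injection_s=t_inj)


def _tone(freq, dur_s, amp=1.0, rate=RATE):
    t = np.arange(int(dur_s * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def _full_epochs(rec, dur):
    return segment_epochs(rec, TimeWindowSpec("H1", 0.0, dur), 60.0)


class TestComputeSpectrogram:
    def test_parseval_white_noise(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(int(120 * RATE))
        sg = compute_spectrogram(x, rate_hz=RATE)
        df = sg.freqs_hz[1] - sg.freqs_hz[0]
        total = np.sum(np.mean(sg.power, axis=0)) * df
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_tone_power_concentrates(self):
        sg = compute_spectrogram(_tone(6.0, 120.0, amp=10.0), rate_hz=RATE)
        mean_psd = np.mean(sg.power, axis=0)
        broad = (sg.freqs_hz >= 0.5) & (sg.freqs_hz < 35.0)
        near = (sg.freqs_hz >= 5.5) & (sg.freqs_hz <= 6.5)
        assert np.sum(mean_psd[near]) >= 0.90 * np.sum(mean_psd[broad])

    def test_zero_signal_zero_power(self):
        sg = compute_spectrogram(np.zeros(int(10 * RATE)), rate_hz=RATE)
        assert np.all(sg.power == 0)

    def test_default_hop_is_1_5_s(self):
        sg = compute_spectrogram(np.ones(int(20 * RATE)), rate_hz=RATE)
        assert np.allclose(np.diff(sg.frame_times_s), 1.5)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(np.zeros(100), rate_hz=RATE)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(30 * RATE))
        p1 = compute_spectrogram(x, rate_hz=RATE).power
        p3 = compute_spectrogram(3.0 * x, rate_hz=RATE).power
        assert np.allclose(p3, 9.0 * p1)


class TestSpectrogramCsvExport:
    def test_round_trips_through_csv(self, tmp_path):
        import pandas as pd

        sg = compute_spectrogram(_tone(6.0, 30.0), rate_hz=RATE)
        path = tmp_path / "spec.csv"
        sg.to_csv(path)
        df = pd.read_csv(path)
        assert df.shape == (sg.n_frames, sg.freqs_hz.size + 1)
        back = df.drop(columns="frame_time_s").to_numpy()
        assert np.allclose(back, sg.power)
        assert np.allclose(df["frame_time_s"], sg.frame_times_s)


class TestBandPowerSeries:
    def test_flat_spectrum_constant_series(self):
        freqs = np.arange(0.0, 128.5, 0.5)
        sg = Spectrogram(np.arange(5.0), freqs, np.full((5, freqs.size), 7.0))
        rec = _rec(np.zeros(int(300 * RATE)))
        es = _full_epochs(rec, 300.0)
        for band in DEFAULT_BANDS.values():
            assert np.allclose(band_power_series(sg, band, es).values, 7.0)

    def test_tone_lands_in_theta_not_alpha(self):
        rec = _rec(_tone(6.0, 120.0, amp=20.0))
        sg = compute_spectrogram(rec)
        es = _full_epochs(rec, 120.0)
        theta = band_power_series(sg, DEFAULT_BANDS["theta"], es).values.mean()
        alpha = band_power_series(sg, DEFAULT_BANDS["alpha"], es).values.mean()
        assert theta > 10 * alpha

    def test_band_without_bins_rejected(self):
        sg = compute_spectrogram(np.ones(int(10 * RATE)), rate_hz=RATE)
        with pytest.raises(ValueError, match="no frequency bins"):
            band_power_series(sg, BandDefinition("x", 10.1, 10.2), _full_epochs(_rec(np.zeros(int(60*RATE))), 60.0))

    def test_all_epochs_rejected_mask_false_values_present(self):
        rec = _rec(np.zeros(int(120 * RATE)))
        es = mark_manual(_full_epochs(rec, 120.0), [0, 1])
        sg = compute_spectrogram(rec)
        series = band_power_series(sg, DEFAULT_BANDS["theta"], es)
        assert not series.retained_mask.any()
        assert series.values.size == sg.n_frames


class TestMedianBandPower:
    def _series(self, values, times=None, mask=None):
        values = np.asarray(values, float)
        times = np.asarray(times if times is not None else 1.0 + np.arange(values.size), float)
        mask = np.asarray(mask if mask is not None else np.ones(values.size), bool)
        return BandPowerSeries(DEFAULT_BANDS["theta"], times, values, mask)

    def test_median_of_constants(self):
        assert median_band_power(self._series([3.0] * 9), (0.0, 100.0)) == 3.0

    def test_median_robust_to_outlier(self):
        assert median_band_power(self._series([1.0, 2.0, 100.0]), (0.0, 100.0)) == 2.0

    def test_rejected_frames_ignored(self):
        s = self._series([1.0, 2.0, 1e9], mask=[True, True, False])
        assert median_band_power(s, (0.0, 100.0)) == 1.5

    def test_no_retained_frames_absent(self):
        s = self._series([1.0], mask=[False])
        assert median_band_power(s, (0.0, 100.0)) is None

    def test_frames_outside_window_excluded(self):
        s = self._series([1.0, 2.0, 50.0], times=[1.0, 2.0, 99.5])
        assert median_band_power(s, (0.0, 10.0)) == 1.5


class TestPeakFrequency:
    def test_pure_tone_on_grid(self):
        assert epoch_peak_frequency(_tone(6.0, 1.0), RATE, DEFAULT_BANDS["theta"]) == 6.0

    def test_off_grid_tone_quantizes(self):
        pk = epoch_peak_frequency(_tone(6.1, 1.0), RATE, DEFAULT_BANDS["theta"])
        assert pk in (6.0, 6.25)

    def test_grid_spacing_is_quarter_hz(self):
        # 4x zero-padding of a 1-s epoch refines the native 1-Hz grid to 0.25 Hz
        pk = epoch_peak_frequency(_tone(5.25, 1.0), RATE, DEFAULT_BANDS["theta"])
        assert pk == 5.25

    def test_white_noise_stays_in_band(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            pk = epoch_peak_frequency(rng.standard_normal(int(RATE)), RATE, DEFAULT_BANDS["theta"])
            assert 4.0 <= pk < 7.0

    def test_all_zero_segment_absent(self):
        assert epoch_peak_frequency(np.zeros(int(RATE)), RATE, DEFAULT_BANDS["theta"]) is None

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            epoch_peak_frequency(np.zeros(100), RATE, DEFAULT_BANDS["theta"])


class TestMedianPeakFrequency:
    def test_constant_tone_recovered(self):
        rec = _rec(_tone(6.0, 120.0))
        es = _full_epochs(rec, 120.0)
        assert median_peak_frequency(rec, (0.0, 120.0), DEFAULT_BANDS["theta"], es) == 6.0

    def test_single_retained_epoch_still_works(self):
        rec = _rec(_tone(5.0, 120.0))
        es = mark_manual(_full_epochs(rec, 120.0), [1])
        assert median_peak_frequency(rec, (0.0, 120.0), DEFAULT_BANDS["theta"], es) == 5.0

    def test_nothing_retained_absent(self):
        rec = _rec(_tone(5.0, 120.0))
        es = mark_manual(_full_epochs(rec, 120.0), [0, 1])
        assert median_peak_frequency(rec, (0.0, 120.0), DEFAULT_BANDS["theta"], es) is None


class TestTotalMedianPower:
    def test_tone_total_equals_band_median(self):
        rec = _rec(_tone(6.0, 120.0, amp=15.0))
        sg = compute_spectrogram(rec)
        es = _full_epochs(rec, 120.0)
        total = total_median_power(sg, es, (0.0, 120.0))
        theta = median_band_power(
            band_power_series(sg, DEFAULT_BANDS["theta"], es), (0.0, 120.0)
        )
        # all power is the 6-Hz tone; total band has 69 bins vs theta's 6
        assert total == pytest.approx(theta * 6 / 69, rel=0.05)

    def test_zero_signal_zero(self):
        rec = _rec(np.zeros(int(120 * RATE)))
        sg = compute_spectrogram(rec)
        assert total_median_power(sg, _full_epochs(rec, 120.0), (0.0, 120.0)) == 0.0
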