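import numpy as np
import pytest

import heartbrain as hb
from heartbrain.preprocessing import apply_filters, reject_noisy_epochs, segment_epochs
from heartbrain.signal_io import TimeWindowSpec, session_windows
from heartbrain.spectral_analysis import DEFAULT_BANDS, band_power_series, compute_spectrogram, median_band_power
from heartbrain.synthetic_data import generate_cohort, generate_ecg, generate_ecog, inject_artifacts, make_preset

RATE = 256.0


class TestMakePreset:
    def test_control_identity(self):
        p = make_preset("control")
        assert p.st_magnitude_mv == 0.0
        assert all(g == 1.0 for per_w in p.window_gains.values() for g in per_w.values())

    def test_experimental_pattern(self):
        p = make_preset("experimental")
        assert p.window_gains["theta"]["H1"] > 1 and p.window_gains["theta"]["D1"] == 1
        assert p.window_gains["alpha"]["D1"] > 1 and p.window_gains["alpha"]["H1"] == 1
        assert p.window_gains["beta"]["H1"] > 1 and p.window_gains["beta"]["D1"] > 1
        assert all(p.window_gains[b]["D2"] == 1 for b in p.window_gains)
        assert p.theta_center_hz["H1"] > p.theta_center_hz["B"]
        assert p.st_onset_s == 840.0

    def test_override_passthrough(self):
        assert make_preset("experimental", {"st_onset_s": 600}).st_onset_s == 600

    def test_unknown_override_named(self):
        with pytest.raises(KeyError, match="bogus_field"):
            make_preset("experimental", {"bogus_field": 1})

    def test_invalid_theta_center_rejected(self):
        with pytest.raises(ValueError, match="theta_center"):
            make_preset("experimental", {"theta_center_hz": {"B": 8.0}})

    def test_control_with_gain_rejected(self):
        with pytest.raises(ValueError, match="unit gains"):
            make_preset("control", {"window_gains": {"beta": {"H1": 2.0}}})


class TestGenerateEcog:
    def test_deterministic(self, experimental_preset, tiny_windows):
        a = generate_ecog(experimental_preset, tiny_windows, seed=3, rate_hz=RATE)
        b = generate_ecog(experimental_preset, tiny_windows, seed=3, rate_hz=RATE)
        assert np.array_equal(a.samples, b.samples)

    def test_seed_changes_signal(self, experimental_preset, tiny_windows):
        a = generate_ecog(experimental_preset, tiny_windows, seed=3, rate_hz=RATE)
        b = generate_ecog(experimental_preset, tiny_windows, seed=4, rate_hz=RATE)
        assert not np.array_equal(a.samples, b.samples)

    def test_empty_windows_rejected(self, experimental_preset):
        with pytest.raises(ValueError, match="empty"):
            generate_ecog(experimental_preset, {}, seed=1)

    def test_units_and_anchor(self, experimental_preset, tiny_windows):
        rec = generate_ecog(experimental_preset, tiny_windows, seed=1, rate_hz=RATE)
        assert rec.units == "uV"
        assert rec.t_injection_s == pytest.approx(-tiny_windows["B"].start_s)

    def test_control_theta_ratio_near_unity(self, control_preset, small_windows):
        ratios = []
        for seed in range(3):
            rec = generate_ecog(control_preset, small_windows, seed=seed, rate_hz=RATE)
            f = apply_filters(rec)
            vals = {}
            for name in ("B", "H1"):
                span = f.window_span(small_windows[name])
                es = reject_noisy_epochs(f, segment_epochs(f, small_windows[name]))
                sl = f.samples[int(span[0] * RATE) : int(span[1] * RATE)]
                sg = compute_spectrogram(sl, rate_hz=RATE, t_offset_s=span[0])
                series = band_power_series(sg, DEFAULT_BANDS["theta"], es)
                vals[name] = median_band_power(series, span)
            ratios.append(vals["H1"] / vals["B"])
        assert all(0.8 <= r <= 1.2 for r in ratios)

    def test_beta_gain_squares_into_power(self, small_windows):
        """An amplitude gain g multiplies median beta power by ~g^2."""
        preset = make_preset("experimental")  # beta H1 gain 2.0
        ratios = []
        for seed in range(3):
            rec = generate_ecog(preset, small_windows, seed=seed, rate_hz=RATE)
            f = apply_filters(rec)
            vals = {}
            for name in ("B", "H1"):
                span = f.window_span(small_windows[name])
                es = reject_noisy_epochs(f, segment_epochs(f, small_windows[name]))
                sl = f.samples[int(span[0] * RATE) : int(span[1] * RATE)]
                sg = compute_spectrogram(sl, rate_hz=RATE, t_offset_s=span[0])
                series = band_power_series(sg, DEFAULT_BANDS["beta"], es)
                vals[name] = median_band_power(series, span)
            ratios.append(vals["H1"] / vals["B"])
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.15)


class TestGenerateEcg:
    def test_missing_baseline_window_rejected(self, experimental_preset):
        with pytest.raises(ValueError, match="baseline"):
            generate_ecg(experimental_preset, {"H1": TimeWindowSpec("H1", 0, 60)}, seed=1)

    @pytest.mark.parametrize("bpm", [200.0, 550.0])
    def test_unphysiological_heart_rate_rejected(self, bpm):
        preset = make_preset("experimental", {"heart_rate_bpm": bpm})
        ws = {"B": TimeWindowSpec("B", -10, 0), "H1": TimeWindowSpec("H1", 0, 10)}
        with pytest.raises(ValueError, match="physiological"):
            generate_ecg(preset, ws, seed=1)

    def test_deterministic(self, experimental_preset):
        ws = {"B": TimeWindowSpec("B", -30, 0), "H1": TimeWindowSpec("H1", 0, 30)}
        a = generate_ecg(experimental_preset, ws, seed=5, rate_hz=RATE)
        b = generate_ecg(experimental_preset, ws, seed=5, rate_hz=RATE)
        assert np.array_equal(a.samples, b.samples)

    def test_units_mv(self, experimental_preset):
        ws = {"B": TimeWindowSpec("B", -10, 0), "H1": TimeWindowSpec("H1", 0, 10)}
        assert generate_ecg(experimental_preset, ws, seed=1, rate_hz=RATE).units == "mV"


class TestGenerateCohort:
    def test_n_below_two_rejected(self, experimental_preset):
        with pytest.raises(ValueError, match="n >= 2"):
            generate_cohort(experimental_preset, 1, seed=1)

    def test_deterministic(self, experimental_preset, tiny_windows):
        a = generate_cohort(experimental_preset, 3, seed=2, windows=tiny_windows, rate_hz=RATE)
        b = generate_cohort(experimental_preset, 3, seed=2, windows=tiny_windows, rate_hz=RATE)
        for x, y in zip(a, b):
            assert np.array_equal(x.ecog.samples, y.ecog.samples)
            assert np.array_equal(x.ecg.samples, y.ecg.samples)

    def test_control_cohort_no_st(self, control_preset, tiny_windows):
        cohort = generate_cohort(control_preset, 4, seed=1, windows=tiny_windows, rate_hz=RATE)
        assert all(a.true_params.st_magnitude_mv == 0.0 for a in cohort)
        assert all(a.true_params.gain_increment == 0.0 for a in cohort)

    def test_noiseless_coupling_is_exactly_linear(self, tiny_windows):
        preset = make_preset("experimental", {"coupling_noise_sd": 0.0})
        cohort = generate_cohort(preset, 6, seed=3, windows=tiny_windows, rate_hz=RATE)
        st = np.array([a.true_params.st_magnitude_mv for a in cohort])
        incr = np.array([a.true_params.gain_increment for a in cohort])
        r = np.corrcoef(st, incr)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_st_magnitudes_in_stated_range(self, experimental_preset, tiny_windows):
        cohort = generate_cohort(experimental_preset, 6, seed=9, windows=tiny_windows, rate_hz=RATE)
        for a in cohort:
            assert 0.1 <= a.true_params.st_magnitude_mv <= 0.4

    def test_shared_injection_anchor(self, experimental_preset, tiny_windows):
        cohort = generate_cohort(experimental_preset, 2, seed=1, windows=tiny_windows, rate_hz=RATE)
        for a in cohort:
            assert a.ecog.t_injection_s == a.ecg.t_injection_s
            assert a.ecog.rate_hz == a.ecg.rate_hz


class TestInjectArtifacts:
    def _quiet_rec(self, control_preset):
        ws = {"B": TimeWindowSpec("B", -120, 0), "H1": TimeWindowSpec("H1", 0, 120)}
        return generate_ecog(control_preset, ws, seed=2, rate_hz=RATE), ws

    def test_600_uv_transient_rejects_exactly_its_epoch(self, control_preset):
        rec, ws = self._quiet_rec(control_preset)
        # times are seconds from recording start: land in epoch 1 of H1
        t = rec.t_injection_s + 95.0
        noisy = inject_artifacts(rec, [t], amplitude=600.0)
        f = apply_filters(noisy)
        es = reject_noisy_epochs(f, segment_epochs(f, ws["H1"], 60.0))
        assert list(es.retained) == [True, False]

    def test_100_uv_transient_rejects_nothing(self, control_preset):
        rec, ws = self._quiet_rec(control_preset)
        noisy = inject_artifacts(rec, [rec.t_injection_s + 95.0], amplitude=100.0)
        f = apply_filters(noisy)
        es = reject_noisy_epochs(f, segment_epochs(f, ws["H1"], 60.0))
        assert es.n_retained == 2

    def test_empty_times_identity(self, control_preset):
        rec, _ = self._quiet_rec(control_preset)
        out = inject_artifacts(rec, [], amplitude=600.0)
        assert np.array_equal(out.samples, rec.samples)

    def test_original_untouched(self, control_preset):
        rec, _ = self._quiet_rec(control_preset)
        before = rec.samples.copy()
        inject_artifacts(rec, [10.0], amplitude=600.0)
        assert np.array_equal(rec.samples, before)

    def test_time_outside_span_rejected(self, control_preset):
        rec, _ = self._quiet_rec(control_preset)
        with pytest.raises(ValueError, match="999"):
            inject_artifacts(rec, [999.0], amplitude=600.0)
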