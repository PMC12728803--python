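"""QRS detection, template construction and subtraction."""
import numpy as np
import pytest
from scipy import signal

import lfpclean as L
from lfpclean.ecg import design_qrs_bandpass, qrs_artifact_present
from lfpclean.exceptions import (InsufficientEventsError, InvalidArgumentError,
                                 TooShortError)
from lfpclean.simulate import qrs_waveform

FS = 250.0


def band_power(x, band):
    return L.welch_psd(np.asarray(x, float),
                       L.SpectralParams(FS, 500, method="hanning_welch")
                       ).band_power(band)


def match_rates(detected, true, tol=2):
    """(precision, recall) of detected apex samples against ground truth."""
    if len(detected) == 0:
        return 0.0, 0.0
    prec = np.mean([np.min(np.abs(true - e)) <= tol for e in detected])
    rec = np.mean([np.min(np.abs(detected - t)) <= tol for t in true])
    return prec, rec


def strong_qrs_recording(seed, amplitude=26.0, jitter=0.03, scales=(1.0, 0.1)):
    spec = L.SimulationSpec(
        duration=60.0, seed=seed,
        qrs=L.QrsSpec(amplitude=amplitude, rate_jitter=jitter,
                      channel_scales=scales))
    return L.assemble_recording(spec)


class TestBandpass:
    def test_midband_gain_near_unity(self):
        t = np.arange(int(FS * 20)) / FS
        rec = L.LfpRecording(np.sin(2 * np.pi * 15.0 * t), FS)
        out = L.bandpass_qrs(rec).channel(0)[500:-500]
        amp = np.max(np.abs(out))
        assert 0.95 <= amp <= 1.05
        assert L.bandpass_qrs(rec).n_samples == rec.n_samples

    def test_dc_rejected(self):
        rec = L.LfpRecording(np.full(5000, 100.0), FS)
        out = L.bandpass_qrs(rec).channel(0)
        assert np.max(np.abs(out)) < 1e-6 * 100.0

    def test_60hz_attenuated_20db(self):
        """Oracle: the designed filter's frequency response at 60 Hz."""
        sos = design_qrs_bandpass(FS)
        _, h = signal.sosfreqz(sos, worN=[60.0], fs=FS)
        # zero-phase application squares the magnitude response
        atten_db = -20.0 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20.0

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            L.bandpass_qrs(L.LfpRecording(np.zeros(50), FS))


class TestDetection:
    def test_min_peak_distance_is_125_samples_at_120bpm(self):
        assert int(round((60.0 / 120.0) * FS)) == 125
        # two spikes 100 samples apart: only one survives the distance rule
        x = np.zeros(5000)
        x[1000] = x[1100] = 50.0
        x += np.random.default_rng(0).standard_normal(5000) * 0.1
        ev = L.detect_r_peaks(L.LfpRecording(x, FS))
        close = [e for e in ev.event_samples if 990 <= e <= 1110]
        assert len(close) == 1

    def test_all_zero_gives_empty_list_positive_polarity(self):
        ev = L.detect_r_peaks(L.LfpRecording(np.zeros(5000), FS))
        assert len(ev) == 0
        assert ev.polarity == 1

    def test_ground_truth_match_at_10x_sd_no_jitter(self):
        spec = L.SimulationSpec(
            duration=60.0, seed=9,
            qrs=L.QrsSpec(heart_rate=60.0, rate_jitter=0.0, amplitude=26.0))
        rec, truth = L.assemble_recording(spec)
        ev = L.detect_r_peaks(L.bandpass_qrs(rec), channel=0)
        prec, rec_ = match_rates(ev.event_samples, truth.qrs_event_samples)
        assert prec == 1.0 and rec_ == 1.0

    def test_inverted_qrs_detected_with_negative_polarity(self):
        spec = L.SimulationSpec(
            duration=60.0, seed=2,
            qrs=L.QrsSpec(amplitude=26.0, polarity=-1))
        rec, truth = L.assemble_recording(spec)
        ev = L.detect_r_peaks(L.bandpass_qrs(rec), channel=0)
        assert ev.polarity == -1
        prec, rec_ = match_rates(ev.event_samples, truth.qrs_event_samples)
        assert prec >= 0.95 and rec_ >= 0.95

    def test_artifact_presence_gate(self):
        clean_spec = L.SimulationSpec(duration=60.0, seed=1, qrs=None)
        clean, _ = L.assemble_recording(clean_spec)
        assert not qrs_artifact_present(L.bandpass_qrs(clean), 0)
        dirty, _ = strong_qrs_recording(1)
        assert qrs_artifact_present(L.bandpass_qrs(dirty), 0)


class TestTemplate:
    @staticmethod
    def _expected_window(w, apex, pre=36, post=36):
        """The QRS waveform as seen in a [event-pre, event+post] window."""
        out = np.zeros(pre + post + 1)
        lo = pre - apex
        out[lo:lo + len(w)] = w
        return out

    def test_mean_of_identical_windows_is_exact(self):
        w, apex = qrs_waveform(FS, 12.0)
        x = np.zeros(20000)
        events = np.arange(500, 19000, 300)
        for e in events:
            x[e - apex:e - apex + len(w)] += w
        ev = L.RPeakEvents(events, 1, 0.0)
        tmpl = L.build_template(L.LfpRecording(x, FS), ev)
        np.testing.assert_allclose(tmpl.waveform,
                                   self._expected_window(w, apex), atol=1e-12)

    def test_noise_shrinks_like_sqrt_n(self):
        """Template error drops ~sqrt(100) when averaging 1000 vs 10 events."""
        rng = np.random.default_rng(0)
        w, apex = qrs_waveform(FS, 10.0)
        expected = self._expected_window(w, apex)
        errs = {}
        for n in (10, 1000):
            step = 100
            x = np.zeros(n * step + 400)
            events = np.arange(200, 200 + n * step, step)
            for e in events:
                x[e - apex:e - apex + len(w)] += w
            x += rng.standard_normal(len(x)) * 2.0
            tmpl = L.build_template(L.LfpRecording(x, FS),
                                    L.RPeakEvents(events, 1, 0.0))
            errs[n] = np.max(np.abs(tmpl.waveform - expected))
        assert errs[1000] < errs[10] / 3.0  # ~1/10 expected, 1/3 is safe

    def test_tapered_endpoints_zero(self):
        tmpl = L.QrsTemplate(np.ones(73), 36, 36, 20)
        assert tmpl.tapered_waveform[0] == 0.0
        assert tmpl.tapered_waveform[-1] == 0.0

    def test_window_minimums_enforced(self):
        x = np.zeros(10000)
        ev = L.RPeakEvents(np.arange(500, 9000, 300), 1, 0.0)
        with pytest.raises(InvalidArgumentError):
            L.build_template(L.LfpRecording(x, FS), ev, pre=10)
        with pytest.raises(InvalidArgumentError):
            L.build_template(L.LfpRecording(x, FS), ev, post=20)

    def test_insufficient_events_error_names_count(self):
        x = np.zeros(2000)
        ev = L.RPeakEvents(np.array([500, 900, 1300]), 1, 0.0)
        with pytest.raises(InsufficientEventsError) as exc:
            L.build_template(L.LfpRecording(x, FS), ev)
        assert exc.value.n_usable == 3


class TestSubtraction:
    def test_zero_template_is_identity(self, default_recording):
        rec, truth = default_recording
        tmpl = L.QrsTemplate(np.zeros(73), 36, 36, 10)
        ev = L.RPeakEvents(truth.qrs_event_samples, 1, 0.0)
        out, _ = L.subtract_template(rec, tmpl, ev)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_self_cancellation(self):
        tmpl = L.QrsTemplate(np.sin(np.linspace(0, 3, 73)) * 10, 36, 36, 10)
        events = np.arange(200, 9800, 400)
        x = np.zeros(10000)
        for e in events:
            x[e - 36:e + 37] += tmpl.tapered_waveform
        out, skipped = L.subtract_template(
            L.LfpRecording(x, FS), tmpl, L.RPeakEvents(events, 1, 0.0))
        assert skipped == []
        assert np.max(np.abs(out.data)) < 1e-9

    def test_samples_outside_event_windows_untouched(self, default_recording):
        rec, truth = default_recording
        cleaned, report = L.remove_ecg(rec, channel=0)
        inside = np.zeros(rec.n_samples, dtype=bool)
        filt = L.bandpass_qrs(rec)
        ev = L.detect_r_peaks(filt, channel=0)
        for e in ev.event_samples:
            inside[max(0, e - 36):e + 37] = True
        np.testing.assert_array_equal(cleaned.data[0, ~inside],
                                      rec.data[0, ~inside])

    def test_boundary_events_skipped_not_truncated(self):
        tmpl = L.QrsTemplate(np.ones(73) * 5, 36, 36, 10)
        x = np.zeros(1000)
        ev = L.RPeakEvents(np.array([10, 500, 990]), 1, 0.0)
        out, skipped = L.subtract_template(L.LfpRecording(x, FS), tmpl, ev)
        assert skipped == [10, 990]

    def test_band_power_restored_within_10pct(self):
        rec, truth = strong_qrs_recording(5, amplitude=20.0)
        clean_bp = band_power(truth.clean_trace[0], (5, 30))
        dirty_bp = band_power(rec.data[0], (5, 30))
        assert dirty_bp >= 2.0 * clean_bp  # artifact inflates the band
        cleaned, _ = L.remove_ecg(rec, channel=0)
        assert band_power(cleaned.data[0], (5, 30)) == pytest.approx(
            clean_bp, rel=0.10)

    def test_band_powers_non_increasing_after_cleaning(self):
        """Theta/alpha/beta power only ever goes down when QRS is removed."""
        rec, truth = strong_qrs_recording(8, amplitude=20.0)
        cleaned, _ = L.remove_ecg(rec, channel=0)
        for band in ((4, 8), (8, 12), (12, 30)):
            assert band_power(cleaned.data[0], band) <= band_power(rec.data[0], band)


class TestBilateral:
    def test_no_qrs_outputs_equal_inputs(self):
        spec = L.SimulationSpec(duration=60.0, seed=11, qrs=None)
        rec, _ = L.assemble_recording(spec)
        left = L.LfpRecording(rec.data[1], FS)
        right = L.LfpRecording(rec.data[0], FS)
        lc, rc, report = L.remove_ecg_bilateral(left, right)
        np.testing.assert_array_equal(lc.data, left.data)
        np.testing.assert_array_equal(rc.data, right.data)
        assert report["reference_channel"] is None

    def test_weak_channel_improved_via_transferred_events(self):
        rec, truth = strong_qrs_recording(4, amplitude=26.0, scales=(1.0, 0.1))
        left = L.LfpRecording(rec.data[1], FS)
        right = L.LfpRecording(rec.data[0], FS)
        lc, rc, report = L.remove_ecg_bilateral(left, right)
        assert report["reference_channel"] == "right"
        true_bp = band_power(truth.clean_trace[1], (4, 30))
        err_dirty = abs(band_power(rec.data[1], (4, 30)) - true_bp)
        err_clean = abs(band_power(lc.data[0], (4, 30)) - true_bp)
        assert err_clean < err_dirty

    def test_per_state_templates_differ_when_qrs_scales_with_stim(self):
        spec = L.SimulationSpec(
            duration=120.0, seed=6,
            qrs=L.QrsSpec(amplitude=26.0, stim_on_scale=2.0),
            stim_segments=(L.StimSegment(0.0, 60.0, 2.0),))
        rec, _ = L.assemble_recording(spec)
        left = L.LfpRecording(rec.data[1], FS, stim_state="mixed",
                              stim_segments=list(spec.stim_segments))
        right = L.LfpRecording(rec.data[0], FS, stim_state="mixed",
                               stim_segments=list(spec.stim_segments))
        _, _, report = L.remove_ecg_bilateral(left, right)
        on = report["templates"]["right/on"]
        off = report["templates"]["right/off"]
        assert on["n_events_averaged"] >= 10
        assert off["n_events_averaged"] >= 10
        assert on["peak_to_peak"] > 1.5 * off["peak_to_peak"]

    def test_idempotence_second_pass_changes_little(self):
        rec, _ = strong_qrs_recording(3, amplitude=20.0, scales=(1.0, 0.3))
        once, _ = L.remove_ecg(rec, channel=0)
        twice, _ = L.remove_ecg(once, channel=0)
        bp1 = band_power(once.data[0], (5, 30))
        bp2 = band_power(twice.data[0], (5, 30))
        assert abs(bp2 - bp1) / bp1 < 0.05
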