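import numpy as np
import pytest

import spindlekit as sk
from conftest import match_events
from spindlekit.recording import IntervalSet, Recording, TimeSeriesChannel
from spindlekit.spindles import (SpindleEvent, SpindleParams, burg_ar,
                                 common_average_reference, detect_candidates,
                                 detect_spindles, detect_spindles_on_signal,
                                 gate_events, sigma_envelope, spindle_amplitude,
                                 spindle_peak_frequency, winsorized_sd)

FS = 200.0


def ecog_recording(right, lefts, fs=FS):
    ecog = {"right_anterior": TimeSeriesChannel("ra", right, fs, "uV")}
    for slot, sig in zip(("left_anterior", "left_middle", "left_posterior"), lefts):
        ecog[slot] = TimeSeriesChannel(slot, sig, fs, "uV")
    return Recording(ecog=ecog)


class TestCommonAverageReference:
    def test_common_mode_rejected(self):
        s = np.random.default_rng(0).standard_normal(1000)
        ref, fs = common_average_reference(ecog_recording(s, [s, s, s]))
        np.testing.assert_allclose(ref, 0.0, atol=1e-12)

    def test_zero_reference_passthrough(self):
        s = np.sin(np.linspace(0, 10, 1000))
        z = np.zeros(1000)
        ref, _ = common_average_reference(ecog_recording(s, [z, z, z]))
        np.testing.assert_array_equal(ref, s)

    def test_scaled_family_cancels(self):
        s = np.random.default_rng(1).standard_normal(1000)
        ref, _ = common_average_reference(ecog_recording(2 * s, [s, 2 * s, 3 * s]))
        np.testing.assert_allclose(ref, 0.0, atol=1e-12)

    def test_missing_channels_named(self):
        s = np.zeros(100)
        rec = Recording(ecog={"left_anterior": TimeSeriesChannel("la", s, FS)})
        with pytest.raises(ValueError, match="right_anterior"):
            common_average_reference(rec)
        rec = Recording(ecog={"right_anterior": TimeSeriesChannel("ra", s, FS)})
        with pytest.raises(ValueError, match="left"):
            common_average_reference(rec)


class TestSigmaEnvelope:
    def test_zero_input(self):
        assert np.allclose(sigma_envelope(np.zeros(2000), FS), 0.0)

    def test_inband_tone_plateau(self):
        # cycle-averaged rectified amplitude of an in-band tone is 2A/pi
        A = 5.0
        t = np.arange(int(FS * 20)) / FS
        env = sigma_envelope(A * np.sin(2 * np.pi * 12 * t), FS)
        plateau = env[int(5 * FS):int(15 * FS)]
        assert np.mean(plateau) == pytest.approx(2 * A / np.pi, rel=0.10)

    def test_out_of_band_attenuated(self):
        t = np.arange(int(FS * 20)) / FS
        e12 = sigma_envelope(np.sin(2 * np.pi * 12 * t), FS)
        e4 = sigma_envelope(np.sin(2 * np.pi * 4 * t), FS)
        mid = slice(int(5 * FS), int(15 * FS))
        assert np.mean(e4[mid]) < 0.05 * np.mean(e12[mid])


class TestWinsorizedSd:
    def test_matches_brute_force_clip(self):
        values = np.arange(1.0, 101.0)
        center, sd = winsorized_sd(values, (10, 90))
        lo, hi = np.percentile(values, [10, 90])
        clipped = np.clip(values, lo, hi)
        assert center == pytest.approx(clipped.mean())
        assert sd == pytest.approx(clipped.std(ddof=1))

    def test_constant_values_degenerate(self):
        with pytest.raises(ValueError, match="SD"):
            winsorized_sd(np.full(200, 3.0))

    def test_outlier_robustness(self):
        rng = np.random.default_rng(0)
        clean = rng.normal(0, 1, 1000)
        _, sd_clean = winsorized_sd(clean)
        dirty = clean.copy()
        dirty[0] = 1e6
        _, sd_dirty = winsorized_sd(dirty)
        assert sd_dirty == pytest.approx(sd_clean, rel=0.10)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="100"):
            winsorized_sd(np.arange(50.0))


class TestDetectCandidates:
    @staticmethod
    def excursion(width_s, peak, fs=FS, n_s=20.0):
        """Envelope with one triangular excursion of given width and peak z."""
        n = int(n_s * fs)
        env = np.zeros(n)
        m = int(width_s * fs)
        i0 = n // 2 - m // 2
        tri = peak * (1 - np.abs(np.linspace(-1, 1, m)))
        env[i0:i0 + m] = tri
        return env

    def test_subthreshold_envelope(self):
        env = np.full(2000, 0.5)
        assert detect_candidates(env, 0.0, 1.0, SpindleParams(), FS) == []

    def test_single_excursion_width_at_edge_crossings(self):
        # triangle peaking at z=3: above 1.7 over the middle fraction
        env = self.excursion(2.0, 3.0)
        cands = detect_candidates(env, 0.0, 1.0, SpindleParams(), FS)
        assert len(cands) == 1
        start, end, peak = cands[0]
        assert peak == pytest.approx(3.0, abs=0.01)
        # triangle crosses 1.7/3 of half-width each side: width = 2*(1-1.7/3)
        assert end - start == pytest.approx(2.0 * (1 - 1.7 / 3.0), abs=0.02)

    def test_peak_threshold_strict(self):
        env = self.excursion(1.0, 2.0)  # above edge but never above 2.5
        assert detect_candidates(env, 0.0, 1.0, SpindleParams(), FS) == []
        env = self.excursion(1.0, 2.5)  # touches 2.5 exactly: still rejected
        assert detect_candidates(env, 0.0, 1.0, SpindleParams(), FS) == []


class TestGateEvents:
    def test_duration_bounds_inclusive(self):
        sleep = IntervalSet([(0.0, 100.0)])
        durs = [0.45, 0.50, 1.0, 2.0, 2.05]
        cands = [(10.0 * (i + 1), 10.0 * (i + 1) + d, 5.0) for i, d in enumerate(durs)]
        kept = gate_events(cands, sleep, SpindleParams())
        assert [pytest.approx(e.duration_s) for e in kept] == [0.50, 1.0, 2.0]

    def test_sleep_containment_required(self):
        sleep = IntervalSet([(0.0, 10.0)])
        cands = [(9.5, 10.5, 5.0)]  # valid duration, straddles the boundary
        assert gate_events(cands, sleep, SpindleParams()) == []

    def test_empty_hypnogram(self):
        assert gate_events([(1.0, 2.0, 5.0)], IntervalSet(), SpindleParams()) == []


class TestSpindleAmplitude:
    def test_power_ratios(self):
        env = np.ones(1000)
        e = SpindleEvent(1.0, 2.0, 5.0)
        assert spindle_amplitude(e, env, baseline=1.0, fs=FS) == pytest.approx(0.0)
        assert spindle_amplitude(e, env, baseline=1 / 3, fs=FS) == pytest.approx(200.0)

    def test_burst_over_baseline(self):
        fs = FS
        env = np.ones(int(20 * fs))
        env[int(8 * fs):int(9 * fs)] = np.sqrt(5.0)  # envelope^2 = 5x baseline
        e = SpindleEvent(8.0, 9.0, 5.0)
        amp = spindle_amplitude(e, env, baseline=1.0, fs=fs)
        assert amp == pytest.approx(400.0, abs=40.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            spindle_amplitude(SpindleEvent(0, 1, 5.0), np.ones(100), 0.0, FS)


class TestPeakFrequency:
    @pytest.mark.parametrize("freq", [12.0, 14.5])
    def test_known_tone_recovered(self, freq):
        rng = np.random.default_rng(int(freq * 10))
        t = np.arange(int(FS * 1.0)) / FS
        x = np.sin(2 * np.pi * freq * t) + 0.1 * rng.standard_normal(t.size)
        assert spindle_peak_frequency(x, FS) == pytest.approx(freq, abs=0.2)

    def test_in_band_restriction(self):
        t = np.arange(int(FS * 1.0)) / FS
        x = 5.0 * np.sin(2 * np.pi * 6 * t) + 1.0 * np.sin(2 * np.pi * 12 * t)
        assert spindle_peak_frequency(x, FS) == pytest.approx(12.0, abs=0.3)

    def test_short_segment_order_reduced(self):
        t = np.arange(30) / FS  # fewer samples than the default AR order
        x = np.sin(2 * np.pi * 12 * t)
        with pytest.warns(UserWarning, match="reduced"):
            f = spindle_peak_frequency(x, FS)
        assert f == pytest.approx(12.0, abs=1.0)  # coarse: only 30 samples

    def test_burg_matches_statsmodels(self):
        # independent oracle for the AR fit itself
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(5)
        x = np.sin(2 * np.pi * 11 * np.arange(300) / FS) + 0.3 * rng.standard_normal(300)
        a, _ = burg_ar(x - x.mean(), 20)
        rho, _ = sm_burg(x, order=20, demean=True)
        np.testing.assert_allclose(-a[1:], rho, rtol=1e-8)


class TestFullDetector:
    def test_injected_bursts_recovered(self):
        p = sk.preset_params("wt", seed=11, spindle_duration_range=(0.7, 1.5),
                             sleep_bout_mean_s=400.0, wake_bout_mean_s=60.0)
        rec, truth = sk.simulate_session(p)
        events = detect_spindles(rec, truth.sleep, SpindleParams())
        tp, fp, fn, _ = match_events(events, truth.spindles)
        assert tp / max(tp + fn, 1) > 0.8
        assert fp <= max(1, 0.1 * len(events))

    def test_bursts_outside_sleep_excluded(self, desk_session):
        rec, truth = desk_session
        # score only times with no bursts as "sleep": nothing is detectable
        tr = truth.spindles
        wake_only = IntervalSet([(0.0, float(tr["start_s"].min() - 1.0))])
        events = detect_spindles(rec, wake_only, SpindleParams())
        for e in events:
            assert not any(min(e.end_s, r.end_s) > max(e.start_s, r.start_s)
                           for r in tr.itertuples())

    @pytest.mark.parametrize("seed", range(5))
    def test_noise_only_false_positive_rate(self, seed):
        p = sk.preset_params("wt", seed=seed, spindle_density_per_min=0.0)
        rec, truth = sk.simulate_session(p)
        events = detect_spindles(rec, truth.sleep, SpindleParams())
        sleep_min = truth.sleep.total_duration() / 60.0
        assert len(events) / sleep_min < 0.5

    def test_event_invariants_post_hoc(self, desk_session):
        rec, truth = desk_session
        p = SpindleParams()
        events = detect_spindles(rec, truth.sleep, p)
        assert events, "expected at least one detection"
        for e in events:
            assert p.min_dur_s <= e.duration_s <= p.max_dur_s
            assert e.peak_z > p.peak_z
            assert truth.sleep.contains_interval(e.start_s, e.end_s, tol=1e-6)
            assert p.sigma_band[0] <= e.peak_freq_hz <= p.sigma_band[1]

    def test_determinism(self, desk_session):
        rec, truth = desk_session
        e1 = detect_spindles(rec, truth.sleep, SpindleParams())
        e2 = detect_spindles(rec, truth.sleep, SpindleParams())
        assert [(a.start_s, a.end_s, a.peak_z, a.amplitude_pct, a.peak_freq_hz)
                for a in e1] == \
               [(a.start_s, a.end_s, a.peak_z, a.amplitude_pct, a.peak_freq_hz)
                for a in e2]

    def test_threshold_monotonicity(self, desk_session):
        rec, truth = desk_session
        sig, fs = common_average_reference(rec)
        n_base = len(detect_spindles_on_signal(sig, fs, truth.sleep, SpindleParams()))
        n_strict = len(detect_spindles_on_signal(sig, fs, truth.sleep,
                                                 SpindleParams(peak_z=3.5)))
        n_wide = len(detect_spindles_on_signal(sig, fs, truth.sleep,
                                               SpindleParams(min_dur_s=0.3,
                                                             max_dur_s=2.5)))
        assert n_strict <= n_base <= n_wide


def test_params_validation():
    with pytest.raises(ValueError):
        SpindleParams(peak_z=1.0, edge_z=1.7)
    with pytest.raises(ValueError):
        SpindleParams(min_dur_s=2.0, max_dur_s=0.5)
    with pytest.raises(ValueError):
        SpindleParams(burg_input="wavelet")
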