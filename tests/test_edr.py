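"""ECG-derived respiration pipeline."""

from dataclasses import replace

import numpy as np
import pytest

from cardioresp.edr import (
    CompositeEdr,
    EdrConfig,
    ModulationSeries,
    align_and_score_breaths,
    build_composite,
    clean_and_normalize,
    extract_q_trough,
    extract_r_features,
    preprocess_reference_respiration,
    run_edr,
)
from cardioresp.errors import EstimationFailureError, InvalidParameterError
from cardioresp.evaluation import EventSeries
from cardioresp.signal_core import SampledSignal
from cardioresp.synth import SynthConfig, generate_record

FS = 250.0


def sine_signal(freq=0.25, duration=60.0):
    t = np.arange(int(duration * FS)) / FS
    return SampledSignal(np.sin(2 * np.pi * freq * t), FS)


class TestPreprocessReferenceRespiration:
    def test_sinusoid_peak_count_and_spacing(self):
        _, peaks = preprocess_reference_respiration(sine_signal(0.25, 60.0))
        assert len(peaks) == 15
        # boundary peaks shift slightly with the filter edge transient
        assert np.allclose(np.diff(peaks.times)[1:-1], 4.0, atol=0.05)

    def test_spike_outlier_removed(self):
        clean = sine_signal(0.25, 60.0)
        spiked_v = clean.values.copy()
        spiked_v[7000] = 10.0 * np.max(np.abs(clean.values))
        _, p_clean = preprocess_reference_respiration(clean)
        _, p_spiked = preprocess_reference_respiration(
            SampledSignal(spiked_v, FS)
        )
        np.testing.assert_allclose(p_spiked.times, p_clean.times, atol=1 / FS)

    def test_min_distance_one_second(self, default_record):
        _, record, _, _ = default_record
        _, peaks = preprocess_reference_respiration(record["RESP"])
        assert np.all(np.diff(peaks.times) >= 250 / FS)


class TestExtractRFeatures:
    def test_constant_rate_constant_amplitude(self):
        cfg = SynthConfig(duration=120.0, hr_base=60, rsa_depth=0.0,
                          r_amp_mod=0.0, q_depth_mod=0.0, noise_sd=0.0,
                          powerline_hz=None, seed=0)
        record, _, _ = generate_record(cfg)
        r_amp, rr = extract_r_features(record["ECG"])
        assert np.allclose(rr.values, 1.0, atol=1 / FS)
        cv = np.std(r_amp.values) / np.mean(r_amp.values)
        assert cv < 0.05

    def test_amplitude_modulation_frequency_recovered(self, default_record):
        cfg, record, _, _ = default_record
        r_amp, _ = extract_r_features(record["ECG"])
        # dominant frequency of the beat-wise series via FFT of a spline
        # resampling onto a uniform grid
        from scipy.interpolate import CubicSpline

        grid = np.arange(r_amp.times[0], r_amp.times[-1], 0.25)
        v = CubicSpline(r_amp.times, r_amp.values)(grid)
        v = v - v.mean()
        freqs = np.fft.rfftfreq(v.size, 0.25)
        peak_f = freqs[np.argmax(np.abs(np.fft.rfft(v)))]
        assert peak_f == pytest.approx(cfg.rr_base / 60.0, abs=0.02)

    def test_r_anchor_min_spacing(self, default_record):
        _, record, _, _ = default_record
        r_amp, _ = extract_r_features(record["ECG"])
        assert np.all(np.diff(r_amp.times) >= 160 / FS)

    def test_too_short_raises(self):
        with pytest.raises((EstimationFailureError, Exception)):
            extract_r_features(SampledSignal(np.zeros(2000), FS))


class TestExtractQTrough:
    def test_no_negative_excursions_raises(self):
        # the band-pass removes any DC offset, so the only input without
        # negative excursions afterwards is the all-zero signal
        with pytest.raises(EstimationFailureError):
            extract_q_trough(SampledSignal(np.zeros(int(60 * FS)), FS))

    def test_depth_modulation_recovered(self):
        cfg = SynthConfig(duration=180.0, q_depth_mod=0.3, rr_base=12.0, seed=5)
        record, _, _ = generate_record(cfg)
        q = extract_q_trough(record["ECG"])
        from scipy.interpolate import CubicSpline

        grid = np.arange(q.times[0], q.times[-1], 0.25)
        v = CubicSpline(q.times, q.values)(grid)
        v = v - v.mean()
        freqs = np.fft.rfftfreq(v.size, 0.25)
        peak_f = freqs[np.argmax(np.abs(np.fft.rfft(v)))]
        assert peak_f == pytest.approx(0.2, abs=0.03)

    def test_negation_swaps_roles(self, default_record):
        # on a negated ECG the rectified-negative branch sees the (former)
        # R peaks, so trough anchors land near the R times
        _, record, _, _ = default_record
        ecg = record["ECG"]
        neg = ecg.replace_values(-ecg.values)
        q_of_neg = extract_q_trough(neg)
        r_amp, _ = extract_r_features(ecg)
        # median nearest-anchor distance small compared with a beat
        d = np.abs(q_of_neg.times[:, None] - r_amp.times[None, :]).min(axis=1)
        assert np.median(d) < 0.3


class TestCleanAndNormalize:
    def test_hand_computed_outlier_case(self):
        s = ModulationSeries(np.arange(4.0), np.array([1.0, 1, 1, 10]), "r_amplitude")
        out = clean_and_normalize(s)
        # mean |.| = 13/4 = 3.25, threshold 9.75 < 10: the outlier goes
        assert len(out) == 3
        assert np.allclose(out.values, 1.0)

    def test_constant_series_normalizes_to_one(self):
        s = ModulationSeries(np.arange(5.0), np.full(5, 7.3), "q_trough")
        out = clean_and_normalize(s)
        assert len(out) == 5
        np.testing.assert_allclose(out.values, 1.0)

    def test_in_bounds_series_mean_abs_one(self, rng):
        v = 2.0 + 0.3 * rng.standard_normal(50)
        s = ModulationSeries(np.arange(50.0), v, "rr_interval")
        out = clean_and_normalize(s)
        assert len(out) == 50
        assert np.mean(np.abs(out.values)) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points(self):
        s = ModulationSeries(np.arange(2.0), np.ones(2), "r_amplitude")
        with pytest.raises(InvalidParameterError):
            clean_and_normalize(s)


def sinusoid_series(kind, noise=0.0, seed=0, duration=120.0, step=1.0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, step)
    v = 1.0 + 0.2 * np.sin(2 * np.pi * 0.25 * t) + noise * rng.standard_normal(t.size)
    return ModulationSeries(t, v, kind)


class TestBuildComposite:
    def test_identical_series_give_bandpassed_average(self):
        a = sinusoid_series("r_amplitude")
        b = sinusoid_series("rr_interval")
        c = sinusoid_series("q_trough")
        comp = build_composite(a, b, c, FS)
        # composite ≈ band-passed 0.25 Hz sinusoid: breath peaks 4 s apart
        # (boundary peaks excluded: filter edge transients)
        d = np.diff(comp.breath_peaks.times)[1:-1]
        assert np.allclose(d, 4.0, atol=0.1)

    def test_averaging_gain_over_single_component(self):
        comps = [sinusoid_series(k, noise=0.15, seed=i)
                 for i, k in enumerate(["r_amplitude", "rr_interval", "q_trough"])]
        comp = build_composite(*comps, FS)
        t = comp.composite.times
        truth = 0.2 * np.sin(2 * np.pi * 0.25 * t)
        mid = slice(2000, -2000)

        def nrmse(sig):
            return np.sqrt(np.mean((sig[mid] - truth[mid]) ** 2))

        err_comp = nrmse(comp.composite.values)
        errs_single = []
        for k in comp.components.values():
            from cardioresp.signal_core import bandpass, moving_mean

            single = bandpass(moving_mean(k, 300), 0.15, 0.5)
            errs_single.append(nrmse(single.values))
        assert err_comp < min(errs_single) + 1e-9

    def test_non_overlapping_spans_raise(self):
        a = sinusoid_series("r_amplitude", duration=20.0)
        b = ModulationSeries(np.arange(100.0, 120.0), np.ones(20), "rr_interval")
        c = sinusoid_series("q_trough", duration=20.0)
        with pytest.raises(EstimationFailureError):
            build_composite(a, b, c, FS)

    def test_spline_reconstructs_band_limited_modulation(self):
        # beat-wise samples at ~1 Hz of a 0.25 Hz wave: 4x oversampled
        t = np.cumsum(np.full(120, 1.0))
        v = 1.0 + 0.2 * np.sin(2 * np.pi * 0.25 * t)
        s = ModulationSeries(t, v, "r_amplitude")
        from scipy.interpolate import CubicSpline

        grid = np.arange(t[0], t[-1], 1 / FS)
        rec = CubicSpline(s.times, s.values)(grid)
        truth = 1.0 + 0.2 * np.sin(2 * np.pi * 0.25 * grid)
        rel_rmse = np.sqrt(np.mean((rec - truth) ** 2)) / np.sqrt(np.mean(truth**2))
        assert rel_rmse < 0.05

    def test_scale_invariance_of_composite(self):
        a = sinusoid_series("r_amplitude")
        b = sinusoid_series("rr_interval")
        c = sinusoid_series("q_trough")
        comp1 = build_composite(a, b, c, FS)
        scaled = [
            ModulationSeries(s.times, s.values, s.kind) for s in (a, b, c)
        ]
        comp2 = build_composite(*scaled, FS)
        np.testing.assert_allclose(
            comp1.breath_peaks.times, comp2.breath_peaks.times
        )


class TestAlignAndScore:
    @staticmethod
    def comp_with_peaks(times):
        sig = sine_signal(0.25, 120.0)
        return CompositeEdr(
            composite=sig,
            components={},
            breath_peaks=EventSeries(np.asarray(times, float), label="breath"),
        )

    def test_exact_match_shift_zero(self):
        ref = EventSeries(np.arange(4.0, 100.0, 4.0), label="breath",
                          source="reference")
        comp = self.comp_with_peaks(ref.times)
        aligned, rep = align_and_score_breaths(comp, ref, beat_interval=1.0)
        assert aligned.phase_shift == 0.0
        assert rep.fp == 0 and rep.fn == 0
        assert rep.sensitivity == 1.0

    def test_global_offset_recovered(self):
        ref = EventSeries(np.arange(4.0, 100.0, 4.0), label="breath",
                          source="reference")
        comp = self.comp_with_peaks(ref.times + 0.4)
        aligned, rep = align_and_score_breaths(comp, ref, beat_interval=1.0)
        assert aligned.phase_shift == pytest.approx(0.4)
        assert rep.sensitivity == 1.0

    def test_inaccurate_label_between_half_and_one_beat(self):
        ref = EventSeries(np.array([10.0, 20.0, 30.0]), label="breath",
                          source="reference")
        comp = self.comp_with_peaks([10.0, 20.7, 30.0])
        _, rep = align_and_score_breaths(comp, ref, beat_interval=1.0)
        assert rep.labels == ["TP", "inaccurate", "TP"]
        assert rep.inaccurate == 1 and rep.fn == 1


class TestRunEdr:
    def test_end_to_end_scores(self, default_record):
        _, record, _, breaths = default_record
        comp, rep = run_edr(record["ECG"], record["RESP"])
        assert rep.sensitivity >= 0.90
        assert 0.0 <= comp.phase_shift <= 1.4
        # composite band limitation: spectral mass outside 0.1-0.6 Hz small
        v = comp.composite.values - comp.composite.values.mean()
        freqs = np.fft.rfftfreq(v.size, 1 / FS)
        power = np.abs(np.fft.rfft(v)) ** 2
        in_band = power[(freqs >= 0.1) & (freqs <= 0.6)].sum()
        assert in_band / power.sum() > 0.9

    def test_scale_invariance_of_breath_times(self, default_record):
        _, record, _, _ = default_record
        base, _ = run_edr(record["ECG"], record["RESP"])
        for c in (0.1, 10.0):
            ecg_s = record["ECG"].replace_values(record["ECG"].values * c)
            got, _ = run_edr(ecg_s, record["RESP"])
            assert got.breath_peaks.times.size == base.breath_peaks.times.size
            assert np.max(
                np.abs(got.breath_peaks.times - base.breath_peaks.times)
            ) <= 1.0 / FS
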