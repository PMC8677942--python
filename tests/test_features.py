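"""Feature-extraction pipeline: detrend, landmarks, PhNR, ratios, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phnrlab.features import (ERGFeatureSet, ExtractionConfig, FeatureError,
                              compute_baseline, compute_ratios, detrend_linear,
                              extract_features, extract_features_table,
                              find_a_trough, find_b_peak, logmar_from_acuity,
                              phnr_fixed_latency, phnr_trough)
from phnrlab.simulate import noiseless_feature_truth
from phnrlab.waveform import sample_at_time

from conftest import make_recording, synthetic_recording

DT = 220 / 430


def grid(duration=220.0, n=430):
    return np.arange(n) * (duration / n)


class TestDetrend:
    def test_annihilates_constants_and_lines(self):
        assert detrend_linear([5.0, 5, 5, 5]) == pytest.approx([0, 0, 0, 0])
        assert detrend_linear([0.0, 1, 2, 3]) == pytest.approx([0, 0, 0, 0])

    def test_residual_has_zero_slope_and_mean(self):
        t = grid()
        y = np.sin(t / 9.0) + 0.03 * t + 2.0
        resid = detrend_linear(y, times_ms=t)
        slope, intercept = np.polyfit(t, resid, 1)
        assert abs(slope) < 1e-10 and abs(resid.mean()) < 1e-10

    def test_requires_two_samples(self):
        with pytest.raises(FeatureError):
            detrend_linear([1.0])

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=60))
    @settings(max_examples=50, derandomize=True)
    def test_idempotent(self, values):
        once = detrend_linear(values)
        twice = detrend_linear(once)
        assert np.allclose(once, twice, atol=1e-9)


class TestBaseline:
    def test_constant_record(self):
        assert compute_baseline([5.0] * 430, 100.0, 220.0) == pytest.approx(5.0)

    def test_direct_mean_of_prestimulus_samples(self):
        y = np.arange(430, dtype=float)
        n_pre = int(np.sum(grid() < 100.0))
        assert compute_baseline(y, 100.0, 220.0) == pytest.approx(y[:n_pre].mean())

    def test_step_at_stimulus_excluded(self):
        t = grid()
        y = np.where(t < 100.0, 1.0, 99.0)
        # a sample exactly at t == 100 would be the first *post*-stimulus one
        assert compute_baseline(y, 100.0, 220.0) == pytest.approx(1.0)

    def test_stimulus_at_zero_errors(self):
        with pytest.raises(FeatureError):
            compute_baseline([1.0] * 430, 0.0, 220.0)


def triangular_bump(center_ms, height, halfwidth_ms=6.0):
    t = grid()
    return height * np.clip(1 - np.abs(t - center_ms) / halfwidth_ms, 0, None)


class TestLandmarks:
    def test_b_peak_of_triangular_bump(self):
        y = triangular_bump(135.0, 8.0)
        t_peak, v_peak = find_b_peak(y, 100.0, 220.0)
        assert t_peak == pytest.approx(135.0, abs=DT)
        assert v_peak == pytest.approx(8.0, abs=8.0 * DT / 6.0)  # grid-sampling slack

    def test_flat_record_tie_breaks_earliest(self):
        t_peak, _ = find_b_peak(np.zeros(430), 100.0, 220.0)
        assert t_peak == pytest.approx(100.0, abs=DT)  # first on-grid window sample

    def test_prestimulus_artifact_ignored(self):
        y = triangular_bump(135.0, 8.0) + triangular_bump(50.0, 100.0)
        t_peak, _ = find_b_peak(y, 100.0, 220.0)
        assert t_peak == pytest.approx(135.0, abs=DT)

    def test_a_trough_between_stimulus_and_peak(self):
        y = triangular_bump(135.0, 8.0) - triangular_bump(117.0, 5.0)
        t_a, v_a = find_a_trough(y, 135.0, 100.0, 220.0)
        assert t_a == pytest.approx(117.0, abs=DT)
        assert v_a == pytest.approx(-5.0, abs=5.0 * DT / 6.0)  # grid-sampling slack

    def test_monotone_rise_puts_trough_at_stimulus(self):
        y = grid().copy()  # strictly increasing
        t_a, _ = find_a_trough(y, 135.0, 100.0, 220.0)
        assert t_a == pytest.approx(100.0, abs=DT)

    def test_equal_minima_earlier_wins(self):
        y = np.zeros(430)
        i1, i2 = sample_at_time(110.0), sample_at_time(120.0)
        y[i1] = y[i2] = -3.0
        t_a, _ = find_a_trough(y, 135.0, 100.0, 220.0)
        assert t_a == pytest.approx(110.0, abs=DT / 2)

    def test_peak_before_stimulus_errors(self):
        with pytest.raises(FeatureError):
            find_a_trough(np.zeros(430), 90.0, 100.0, 220.0)


class TestPhnr:
    def test_flat_record_is_zero(self):
        assert phnr_fixed_latency(np.zeros(430), 0.0, 100.0, 220.0) == 0.0

    def test_constructed_value_at_172ms(self):
        y = np.zeros(430)
        y[sample_at_time(172.0)] = -4.0
        assert phnr_fixed_latency(y, 0.0, 100.0, 220.0) == pytest.approx(-4.0)

    def test_matches_direct_indexing(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=430)
        expected = y[336] - 0.25  # sample_at_time(172) == 336 for the defaults
        assert phnr_fixed_latency(y, 0.25, 100.0, 220.0) == pytest.approx(expected)

    def test_latency_beyond_record_errors(self):
        with pytest.raises(FeatureError):
            phnr_fixed_latency(np.zeros(430), 0.0, 100.0, 220.0, latency_ms=125.0)

    def test_flat_window(self):
        t = grid()
        y = np.where((t >= 155) & (t <= 190), -4.0, 0.0)
        res = phnr_trough(y, 0.0, 100.0, 220.0)
        assert res.value_uv == pytest.approx(-4.0)
        assert 162.0 <= res.time_ms <= 182.0
        assert not res.window_clipped

    def test_v_trough_minimum_dominates_72ms_point(self):
        y = -triangular_bump(168.0, 5.0, halfwidth_ms=8.0)
        res = phnr_trough(y, 0.0, 100.0, 220.0)
        at_72 = y[sample_at_time(172.0)]
        trough_sample = y[sample_at_time(res.time_ms)]
        assert trough_sample <= at_72
        assert res.time_ms == pytest.approx(168.0, abs=DT)

    def test_eleven_point_average_differs_from_point_minimum(self):
        y = np.zeros(430)
        i = sample_at_time(172.0)
        y[i - 5:i + 6] = -1.0
        y[i] = -4.0  # sharp spike inside a -1 shelf
        res = phnr_trough(y, 0.0, 100.0, 220.0)
        assert res.value_uv == pytest.approx((10 * -1.0 + -4.0) / 11)

    def test_window_outside_record_errors(self):
        with pytest.raises(FeatureError):
            phnr_trough(np.zeros(430), 0.0, 150.0, 220.0)


class TestRatios:
    def test_worked_example(self):
        p, w = compute_ratios(-3.0, 10.0, -2.0)
        assert p == pytest.approx(0.2)
        assert w == pytest.approx(12 / 13)

    def test_null_phnr(self):
        p, w = compute_ratios(0.0, 10.0, 0.0)
        assert (p, w) == (0.0, 1.0)

    @given(st.floats(-10, -0.01), st.floats(0.5, 30), st.floats(-10, -0.01))
    @settings(max_examples=100, derandomize=True)
    def test_p_positive_for_negative_phnr(self, a_amp, b_amp, phnr):
        p, _ = compute_ratios(a_amp, b_amp, phnr)
        assert p > 0

    def test_degenerate_inputs(self):
        with pytest.raises(FeatureError):
            compute_ratios(-1.0, 0.0, -1.0)
        with pytest.raises(FeatureError):
            compute_ratios(5.0, 5.0, -1.0)


class TestLogmar:
    @pytest.mark.parametrize("acuity,expected", [
        ("CF", 2.0), ("HM", 3.0), ("NLP", 6.0),
        ("20/20", 0.0), ("20/200", 1.0), ("6/60", 1.0), ("20/40", np.log10(2)),
    ])
    def test_conversions(self, acuity, expected):
        assert logmar_from_acuity(acuity) == pytest.approx(expected)

    def test_unparseable(self):
        with pytest.raises(FeatureError):
            logmar_from_acuity("20-40")


class TestQcAndPipeline:
    def test_flat_noise_fails_qc(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(0, 1, 430))
        fs = extract_features(rec)
        assert not fs.qc_pass and "no defined b-wave peak" in fs.qc_reasons

    def test_pure_drift_fails_qc(self):
        rec = make_recording(0.5 * grid())
        fs = extract_features(rec)
        assert not fs.qc_pass

    def test_amplitude_spike_fails_qc(self):
        rec, _ = synthetic_recording()
        y = np.array(rec.samples)
        y[250] = 500.0
        fs = extract_features(rec.with_samples(y))
        assert any("amplitude bound" in r for r in fs.qc_reasons)

    def test_clean_waveform_passes(self):
        rec, _ = synthetic_recording(noise_sd=0.3, seed=5)
        fs = extract_features(rec)
        assert fs.qc_pass and fs.qc_reasons == ()

    def test_manual_exclusion_honored(self):
        rec, _ = synthetic_recording()
        cfg = ExtractionConfig(qc_exclude_ids=(rec.record_id,))
        fs = extract_features(rec, cfg)
        assert not fs.qc_pass and "manually excluded" in fs.qc_reasons

    def test_error_carries_record_identity(self):
        rec = make_recording([1.0] * 430, subject_id="SX", stimulus_time_ms=180.0)
        with pytest.raises(FeatureError, match="SX"):
            extract_features(rec)

    def test_batch_order_preserved(self, small_cohort):
        records, _ = small_cohort
        table = extract_features_table(records[:10])
        assert len(table) == 10
        assert list(table["recording_index"]) == [r.recording_index for r in records[:10]]

    def test_shift_invariance(self):
        rec, _ = synthetic_recording(noise_sd=0.2, seed=2)
        fs0 = extract_features(rec)
        fs1 = extract_features(rec.with_samples(np.array(rec.samples) + 37.0))
        for name in ("baseline_uv", "a_amp_uv", "b_amp_uv", "phnr_min_uv",
                     "phnr72_uv", "p_ratio", "w_ratio"):
            assert getattr(fs0, name) == pytest.approx(getattr(fs1, name), abs=1e-9)

    def test_scale_equivariance(self):
        rec, _ = synthetic_recording(noise_sd=0.2, seed=3)
        k = 2.5
        fs0 = extract_features(rec)
        fs1 = extract_features(rec.with_samples(k * np.array(rec.samples)))
        for name in ("a_amp_uv", "b_amp_uv", "phnr_min_uv", "phnr72_uv"):
            assert getattr(fs1, name) == pytest.approx(k * getattr(fs0, name), rel=1e-9)
        assert fs1.p_ratio == pytest.approx(fs0.p_ratio, rel=1e-9)
        assert fs1.w_ratio == pytest.approx(fs0.w_ratio, rel=1e-9)

    @pytest.mark.parametrize("phnr", [-3.7, -2.8])
    def test_zero_noise_recovery_against_continuous_truth(self, phnr):
        rec, params = synthetic_recording(phnr=phnr)
        truth = noiseless_feature_truth(params)
        fs = extract_features(rec)
        assert fs.b_amp_uv == pytest.approx(truth["b_amp_true_feat"], rel=0.05)
        assert fs.phnr_trough_time_ms == pytest.approx(
            truth["phnr_trough_time_true"], abs=2.0)
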