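import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from mvapred import (FeatureConfig, FiducialSet, MinuteSegment, SynthSpec,
                     compute_hr, compute_mrr, compute_rmssd, compute_sdnn,
                     extract_feature_vector, rr_intervals, synth_ecg_record)
from mvapred.errors import DataError
from mvapred.feature_extraction import compute_qrs_amplitude_features

rr_seqs = st.lists(st.floats(0.3, 2.0), min_size=2, max_size=60)


# independent brute-force oracles, kept deliberately naive
def _brute_mrr(rr):
    return sum(rr) / len(rr)


def _brute_sdnn(rr):
    m = _brute_mrr(rr)
    return math.sqrt(sum((x - m) ** 2 for x in rr) / len(rr))


def _brute_rmssd(rr):
    d = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
    return math.sqrt(sum(x * x for x in d) / len(d))


def _brute_hr(rr):
    return 60.0 / _brute_mrr(rr)


class TestRRIntervals:
    def test_unit_intervals(self):
        np.testing.assert_allclose(
            rr_intervals(np.array([0, 128, 256]), fs=128.0), [1.0, 1.0])

    def test_half_second(self):
        np.testing.assert_allclose(rr_intervals([0, 64], fs=128.0), [0.5])

    def test_matches_direct_difference(self, rng):
        peaks = np.cumsum(rng.integers(80, 200, size=30))
        np.testing.assert_array_equal(
            rr_intervals(peaks, fs=250.0), np.diff(peaks) / 250.0)

    def test_single_peak_warns_empty(self):
        with pytest.warns(UserWarning):
            assert len(rr_intervals([5], fs=128.0)) == 0


class TestRRStatistics:
    @pytest.mark.parametrize("rr, expected", [
        ([0.5, 0.5], 120.0), ([1.0], 60.0), ([0.4, 0.6], 120.0)])
    def test_hr_examples(self, rr, expected):
        assert compute_hr(np.array(rr)) == pytest.approx(expected)

    def test_hr_rejects_nonpositive_rr(self):
        with pytest.raises(DataError):
            compute_hr(np.array([0.5, -0.1]))

    @pytest.mark.parametrize("rr, expected", [
        ([0.5, 0.5], 0.5), ([0.4, 0.6], 0.5)])
    def test_mrr_examples(self, rr, expected):
        assert compute_mrr(np.array(rr)) == pytest.approx(expected)

    @pytest.mark.parametrize("rr, expected", [
        ([0.8, 0.8, 0.8], 0.0), ([0.4, 0.6], 0.2),
        ([0.4, 0.6, 0.4], math.sqrt(0.08 / 2))])
    def test_rmssd_examples(self, rr, expected):
        assert compute_rmssd(np.array(rr)) == pytest.approx(expected)

    @pytest.mark.parametrize("rr, expected", [
        ([0.7, 0.7, 0.7, 0.7], 0.0), ([0.4, 0.6], 0.1), ([1.0], 0.0)])
    def test_sdnn_examples(self, rr, expected):
        assert compute_sdnn(np.array(rr)) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(rr_seqs)
    def test_statistics_match_brute_force(self, rr):
        arr = np.array(rr)
        assert compute_mrr(arr) == pytest.approx(_brute_mrr(rr), abs=1e-12)
        assert compute_sdnn(arr) == pytest.approx(_brute_sdnn(rr), abs=1e-12)
        assert compute_rmssd(arr) == pytest.approx(_brute_rmssd(rr), abs=1e-12)
        assert compute_hr(arr) == pytest.approx(_brute_hr(rr), rel=1e-12)

    def test_beats_denominator_reproduces_literal_form(self):
        rr = np.array([0.4, 0.6, 0.5])
        n_beats = len(rr) + 1
        assert compute_mrr(rr, "beats") == pytest.approx(np.sum(rr) / n_beats)
        assert compute_rmssd(rr, "beats") == pytest.approx(
            math.sqrt(np.sum(np.diff(rr) ** 2) / n_beats))
        assert compute_sdnn(rr, "beats") == pytest.approx(
            math.sqrt(np.sum((rr - rr.mean()) ** 2) / n_beats))

    def test_instantaneous_hr_option(self):
        rr = np.array([0.5, 1.0])
        assert compute_hr(rr, "inst") == pytest.approx((120 + 60) / 2)


class TestAmplitudeFeatures:
    def test_two_beats_hand_computed(self):
        x = np.zeros(100)
        x[20], x[60] = 1.0, 1.2
        fset = FiducialSet(
            r=np.array([20, 60]), q=np.array([17, 57]),
            s=np.array([23, 63]), qon=np.array([14, 54]),
            soff=np.array([26, 66]))
        out = compute_qrs_amplitude_features(x, 250.0, fset)
        assert out["mRamp"] == pytest.approx(1.1)
        assert out["sdRamp"] == pytest.approx(0.1)
        assert out["mQRSd"] == pytest.approx(12 / 250.0)
        assert out["sdQRSd"] == pytest.approx(0.0)

    def test_identical_beats_have_zero_sds(self, clean_minute):
        seg, _ = clean_minute
        vec = extract_feature_vector(seg)
        assert vec.sdQRSd < 0.02
        assert vec.sdRamp < 0.05

    def test_baseline_correction_removes_offset(self, clean_minute):
        seg, _ = clean_minute
        shifted = MinuteSegment(seg.record_id, 0, seg.samples + 5.0, seg.fs)
        a = extract_feature_vector(seg)
        b = extract_feature_vector(shifted)
        assert b.mRamp == pytest.approx(a.mRamp, abs=1e-6)
        assert b.mQamp == pytest.approx(a.mQamp, abs=1e-6)


class TestExtractFeatureVector:
    def test_jitter_free_minute(self, clean_minute):
        seg, _ = clean_minute
        vec = extract_feature_vector(seg)
        assert vec.mHR == pytest.approx(60.0, abs=1.0)
        assert vec.SDNN < 0.01

    def test_deterministic(self, clean_minute):
        seg, _ = clean_minute
        a = extract_feature_vector(seg)
        b = extract_feature_vector(seg)
        assert a == b

    def test_mrr_times_mhr_is_60(self, jittered_minute):
        seg, _ = jittered_minute
        vec = extract_feature_vector(seg)
        assert vec.mRR * vec.mHR == pytest.approx(60.0, abs=1e-9)

    def test_rate_invariance_128_vs_250(self):
        feats = {}
        for fs in (128.0, 250.0):
            rec, _ = synth_ecg_record(SynthSpec(
                fs=fs, duration_s=62.0, mean_rr=0.85, rr_jitter_sd=0.03,
                noise_sd=0.0, seed=21, drift=None))
            seg = MinuteSegment("r", 0, rec.samples[: int(60 * fs)], fs)
            feats[fs] = extract_feature_vector(seg)
        for name in ("mRR", "mHR", "SDNN", "mRamp"):
            a, b = getattr(feats[128.0], name), getattr(feats[250.0], name)
            assert b == pytest.approx(a, rel=0.05), name
        # durations carry +-1-sample quantisation per edge at 128 Hz
        assert feats[250.0].mQRSd == pytest.approx(
            feats[128.0].mQRSd, abs=2 / 128.0)

    def test_time_shift_invariance_of_dispersion(self, jittered_minute):
        seg, _ = jittered_minute
        rolled = MinuteSegment(seg.record_id, 0,
                               np.roll(seg.samples, 250), seg.fs)
        a = extract_feature_vector(seg)
        b = extract_feature_vector(rolled, FeatureConfig())
        assert b.SDNN == pytest.approx(a.SDNN, abs=0.01)
        assert b.RMSSD == pytest.approx(a.RMSSD, abs=0.01)

    def test_flat_segment_dropped(self):
        seg = MinuteSegment("flat", 0, np.zeros(7680), 128.0)
        assert extract_feature_vector(seg) is None
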