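import numpy as np
import pandas as pd
import pytest

from mvapred import (ECGRecord, FeatureTable, curate_records, load_record,
                     read_feature_table, replace_outliers, segment_record,
                     study_record_ids, synth_dataset, synth_ecg_record,
                     truncate_record, write_feature_table, write_record)
from mvapred.errors import AnnotationError, FormatError, SchemaError
from mvapred.record_io import FEATURE_NAMES
from mvapred.synthetic_ecg import SynthSpec


def _record(n, fs=128.0, **kw):
    return ECGRecord("r", np.zeros(n), fs, **kw)


class TestLoadRecord:
    def test_csv_round_trip_identity(self, tmp_path):
        rec = ECGRecord("s001", np.sin(np.arange(7680) / 17), 128.0)
        path = write_record(rec, tmp_path / "s001", format="csv")
        back = load_record(path, format="csv")
        assert back.fs == 128.0
        assert back.record_id == "s001"
        assert len(back.samples) == 7680
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)

    def test_csv_missing_fs_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# record_id=x\n0.1\n0.2\n")
        with pytest.raises(FormatError):
            load_record(path, format="csv")

    def test_wfdb_round_trip_within_one_quantization_step(self, tmp_path):
        rec, _ = synth_ecg_record(SynthSpec(fs=250, duration_s=10, seed=2))
        gain = 400.0
        write_record(rec, tmp_path / "w1", format="wfdb", gain=gain)
        back = load_record(tmp_path / "w1.hea", format="wfdb")
        assert back.fs == 250.0
        assert np.max(np.abs(back.samples - rec.samples)) <= 1.0 / gain

    def test_wfdb_onset_annotation_round_trip(self, tmp_path):
        # onset index > 1023 exercises the long-interval encoding
        rec = ECGRecord("v9", np.zeros(200_000), 250.0,
                        source_class="pre_vtvf", onset_sample=150_000)
        write_record(rec, tmp_path / "v9", format="wfdb")
        back = load_record(tmp_path / "v9", format="wfdb")
        assert back.onset_sample == 150_000
        assert back.source_class == "pre_vtvf"

    def test_onset_beyond_signal_is_annotation_error(self):
        with pytest.raises(AnnotationError):
            ECGRecord("x", np.zeros(10), 128.0, source_class="pre_vtvf",
                      onset_sample=10)


class TestCuration:
    def test_inclusion_rule_yields_18_records(self):
        ids = study_record_ids()
        assert len(ids["vfdb"]) == 9
        assert len(ids["nsrdb"]) == 9

    def test_pre_vtvf_without_onset_is_excluded(self):
        good = _record(10_000, source_class="pre_vtvf", onset_sample=5000)
        bad = ECGRecord("nolabel", np.zeros(10_000), 128.0,
                        source_class="pre_vtvf")
        normal = _record(10_000)
        kept = curate_records([good, bad, normal])
        assert [r.record_id for r in kept] == ["r", "r"]
        assert len(kept) == 2


class TestTruncate:
    def test_long_record_truncated_to_35_minutes(self):
        # a 25.5 h record at 128 Hz collapses to 35*60*128 samples
        rec = _record(11_730_944)
        assert len(truncate_record(rec).samples) == 268_800

    def test_short_record_unchanged(self):
        rec = _record(1000)
        assert truncate_record(rec) is rec

    def test_one_minute_at_128hz_is_7680_samples(self):
        rec = _record(100_000)
        assert len(truncate_record(rec, max_minutes=1).samples) == 7680

    def test_onset_beyond_truncation_dropped(self):
        rec = _record(600_000, source_class="pre_vtvf", onset_sample=500_000)
        out = truncate_record(rec, max_minutes=35)
        assert out.onset_sample is None
        assert out.source_class == "normal"


class TestReplaceOutliers:
    def test_spike_replaced_by_predecessor(self):
        t = np.arange(1280) / 128.0
        x = np.sin(2 * np.pi * 1.0 * t)
        x[600] = 50.0
        rec = ECGRecord("s", x, 128.0)
        out = replace_outliers(rec)
        assert out.samples[600] == pytest.approx(x[599])
        np.testing.assert_array_equal(np.delete(out.samples, 600),
                                      np.delete(x, 600))

    def test_clean_sinusoid_unchanged(self):
        t = np.arange(1280) / 128.0
        rec = ECGRecord("s", np.sin(2 * np.pi * t), 128.0)
        np.testing.assert_array_equal(replace_outliers(rec).samples,
                                      rec.samples)

    def test_constant_signal_unchanged(self):
        rec = ECGRecord("s", np.full(1000, 3.3), 128.0)
        np.testing.assert_array_equal(replace_outliers(rec).samples,
                                      rec.samples)

    def test_idempotent(self, rng):
        x = rng.normal(size=2000)
        x[[100, 700, 1500]] += 40.0
        once = replace_outliers(ECGRecord("s", x, 128.0))
        twice = replace_outliers(once)
        np.testing.assert_array_equal(once.samples, twice.samples)


class TestSegmentRecord:
    def test_35_minute_normal_record_at_250hz(self):
        rec = _record(35 * 60 * 250, fs=250.0)
        segs = segment_record(rec)
        assert len(segs) == 35
        assert all(len(s.samples) == 15_000 for s in segs)
        assert all(s.label == 0 and s.minutes_before_onset is None
                   for s in segs)

    def test_onset_at_start_of_segment_30_keeps_30_segments(self):
        n = 35 * 60 * 128
        rec = ECGRecord("v", np.zeros(n), 128.0, source_class="pre_vtvf",
                        onset_sample=30 * 60 * 128)
        segs = segment_record(rec)
        assert len(segs) == 30
        assert segs[-1].index_in_record == 29
        assert segs[-1].minutes_before_onset == pytest.approx(0.0)
        assert segs[0].minutes_before_onset == pytest.approx(29.0)

    def test_sub_minute_record_gives_empty_output(self):
        rec = _record(59 * 128)
        with pytest.warns(UserWarning):
            assert segment_record(rec) == []

    def test_concatenation_reproduces_signal(self, rng):
        x = rng.normal(size=5 * 60 * 128)
        rec = ECGRecord("n", x, 128.0)
        segs = segment_record(rec)
        np.testing.assert_array_equal(
            np.concatenate([s.samples for s in segs]), x)

    @pytest.mark.parametrize("onset", [0, 1, 7680, 20_000, 30_000,
                                       5 * 7680 - 1])
    def test_no_retained_segment_overlaps_onset(self, onset):
        n = 5 * 60 * 128
        rec = ECGRecord("v", np.zeros(n), 128.0, source_class="pre_vtvf",
                        onset_sample=onset)
        for seg in segment_record(rec):
            assert (seg.index_in_record + 1) * 7680 <= onset


class TestFeatureTable:
    def _toy(self):
        frame = pd.DataFrame(
            np.arange(4 * 12, dtype=float).reshape(4, 12) / 7.0,
            columns=list(FEATURE_NAMES))
        frame["label"] = [0, 0, 1, 1]
        frame["minutes_before_onset"] = [np.nan, np.nan, 3.0, 12.0]
        return FeatureTable(frame)

    def test_round_trip(self, tmp_path):
        table = self._toy()
        path = write_feature_table(table, tmp_path / "t.csv")
        back = read_feature_table(path)
        pd.testing.assert_frame_equal(
            back.frame[list(FEATURE_NAMES)], table.frame[list(FEATURE_NAMES)],
            rtol=1e-6)
        assert list(back.y) == [0, 0, 1, 1]

    def test_missing_column_is_schema_error(self, tmp_path):
        table = self._toy()
        path = write_feature_table(table, tmp_path / "t.csv")
        frame = pd.read_csv(path).drop(columns=["sdRamp"])
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="sdRamp"):
            read_feature_table(tmp_path / "bad.csv")

    def test_unknown_column_is_schema_error(self, tmp_path):
        table = self._toy()
        table.frame["mystery"] = 1.0
        path = write_feature_table(FeatureTable(
            table.frame.drop(columns=["mystery"])), tmp_path / "t.csv")
        frame = pd.read_csv(path)
        frame["mystery"] = 1.0
        frame.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="mystery"):
            read_feature_table(tmp_path / "bad.csv")

    def test_column_map_absorbs_foreign_headers(self, tmp_path):
        table = self._toy()
        path = write_feature_table(table, tmp_path / "t.csv")
        frame = pd.read_csv(path).rename(columns={"mRR": "meanRR"})
        frame.to_csv(tmp_path / "alien.csv", index=False)
        back = read_feature_table(tmp_path / "alien.csv",
                                  column_map={"meanRR": "mRR"})
        assert len(back) == 4

    def test_synthetic_table_round_trip_count(self, tmp_path):
        table = synth_dataset(45, effect=1.0, seed=3)
        assert len(table) == 90
        path = write_feature_table(table, tmp_path / "s.csv")
        assert len(read_feature_table(path)) == 90
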