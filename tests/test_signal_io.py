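import numpy as np
import pytest

from fhrcluster.signal_io import (
    AnnotationSet,
    EcgRecord,
    read_annotations,
    read_signal_csv,
    read_wfdb_record,
    write_detections,
    write_detections_csv,
    write_wfdb_record,
)


class TestEcgRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EcgRecord("x", "", 0.0, np.ones(10))
        with pytest.raises(ValueError):
            EcgRecord("x", "", 1000.0, np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            EcgRecord("x", "", 1000.0, np.array([]))

    def test_basic_properties(self):
        rec = EcgRecord("r", "ch", 500.0, np.arange(5, dtype=float))
        assert rec.n == 5
        assert rec.duration_s == pytest.approx(0.01)


class TestSignalCsv:
    def test_reads_in_file_order(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("0.0\n1.5\n-0.5\n")
        rec = read_signal_csv(p, fs=1000.0)
        assert rec.n == 3
        np.testing.assert_array_equal(rec.samples, [0.0, 1.5, -0.5])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty signal"):
            read_signal_csv(p, fs=1000.0)

    def test_non_numeric_names_line(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("1.0\nabc\n")
        with pytest.raises(ValueError, match=":2"):
            read_signal_csv(p, fs=1000.0)

    def test_missing_file_and_bad_fs(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_signal_csv(tmp_path / "absent.csv", fs=1000.0)
        p = tmp_path / "sig.csv"
        p.write_text("1.0\n")
        with pytest.raises(ValueError):
            read_signal_csv(p, fs=-1.0)

    def test_column_selection(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("0.0,5.0\n1.0,6.0\n")
        rec = read_signal_csv(p, fs=1000.0, column=1)
        np.testing.assert_array_equal(rec.samples, [5.0, 6.0])


class TestAnnotations:
    def test_parse_and_sort(self, tmp_path):
        p = tmp_path / "ann.txt"
        p.write_text("350\n100\n600\n")
        ann = read_annotations(p)
        np.testing.assert_array_equal(ann.indices, [100, 350, 600])

    def test_negative_index_rejected(self, tmp_path):
        p = tmp_path / "ann.txt"
        p.write_text("-5\n")
        with pytest.raises(ValueError, match="negative"):
            read_annotations(p)

    def test_duplicates_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "ann.txt"
        p.write_text("100\n100\n200\n")
        with caplog.at_level("WARNING"):
            ann = read_annotations(p)
        np.testing.assert_array_equal(ann.indices, [100, 200])
        assert "duplicate" in caplog.text

    def test_round_trip_random_indices(self, tmp_path, rng):
        idx = np.unique(rng.integers(0, 10**6, size=1000))
        ann = AnnotationSet("r", "fetal_detected", idx)
        path = tmp_path / "det.txt"
        write_detections(ann, path)
        back = read_annotations(path, kind="fetal_detected")
        np.testing.assert_array_equal(back.indices, idx)

    def test_empty_set_writes_empty_file(self, tmp_path):
        path = tmp_path / "det.txt"
        write_detections(AnnotationSet("r", "fetal_detected", np.array([], dtype=int)), path)
        assert path.read_text() == ""
        assert len(read_annotations(path)) == 0

    def test_csv_dump(self, tmp_path):
        path = tmp_path / "det.csv"
        write_detections_csv(AnnotationSet("r", "fetal_detected", np.array([10, 20])), 1000.0, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "index,time_s,label"
        assert lines[1].startswith("10,0.010000")


class TestWfdb:
    def test_round_trip_two_channels(self, tmp_path, rng):
        x0 = rng.normal(scale=0.5, size=2000)
        x1 = rng.normal(scale=0.5, size=2000)
        stem = tmp_path / "rec01"
        write_wfdb_record(stem, 1000.0, [("Ab-1", x0), ("Ab-2", x1)], gain=1000.0)
        rec = read_wfdb_record(stem, "Ab-2")
        assert rec.fs == 1000.0
        assert rec.channel == "Ab-2"
        # quantization at gain 1000 is +-0.5e-3
        assert np.max(np.abs(rec.samples - x1)) <= 0.5e-3 + 1e-12
        rec0 = read_wfdb_record(stem, 0)
        assert np.max(np.abs(rec0.samples - x0)) <= 0.5e-3 + 1e-12

    def test_unknown_channel_lists_available(self, tmp_path):
        stem = tmp_path / "rec02"
        write_wfdb_record(stem, 1000.0, [("Ab-1", np.zeros(100))])
        with pytest.raises(ValueError, match="Ab-1"):
            read_wfdb_record(stem, "Ab-9")

    def test_missing_header(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wfdb_record(tmp_path / "nope")
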