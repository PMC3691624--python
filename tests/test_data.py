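"""File-boundary contracts: logratio table, SEG mapping, BED parsing,
output round trips."""

import numpy as np
import pandas as pd
import pytest

from rarecnv.data import (
    ProbeIndex,
    Segmentation,
    read_interval_db,
    read_logratio_table,
    read_scored_table,
    read_segmentation,
    write_logratio_table,
    write_markers_bed,
    write_outputs,
    write_scored_table,
    write_segmentation,
)
from rarecnv.outlier import MarkerSet
from rarecnv.synth import make_probe_index


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLogratioTable:
    def test_shuffled_rows_are_sorted_to_genome_order(self, tmp_path):
        path = _write(
            tmp_path,
            "l.tsv",
            "chrom\tstart\tend\tprobe_id\tA\tB\n"
            "chr2\t100\t160\tp4\t0.4\t-0.4\n"
            "chr1\t300\t360\tp2\t0.2\t-0.2\n"
            "chr1\t100\t160\tp1\t0.1\t-0.1\n"
            "chr10\t100\t160\tp3\t0.3\t-0.3\n",
        )
        pi, L = read_logratio_table(path)
        assert list(pi.probe_id) == ["p1", "p2", "p4", "p3"]  # chr2 before chr10
        assert L.sample_ids == ["A", "B"]
        np.testing.assert_allclose(L.values[0], [0.1, 0.2, 0.4, 0.3])
        np.testing.assert_allclose(L.values[1], [-0.1, -0.2, -0.4, -0.3])

    def test_missing_required_column_is_named(self, tmp_path):
        path = _write(tmp_path, "l.tsv", "start\tend\tprobe_id\tA\n1\t2\tp1\t0.0\n")
        with pytest.raises(ValueError, match="chrom"):
            read_logratio_table(path)

    def test_empty_cell_becomes_missing_flag(self, tmp_path):
        path = _write(
            tmp_path,
            "l.tsv",
            "chrom\tstart\tend\tprobe_id\tA\tB\n"
            "chr1\t100\t160\tp1\t\t-0.1\n"
            "chr1\t200\t260\tp2\t0.2\t-0.2\n",
        )
        _, L = read_logratio_table(path)
        assert np.isnan(L.values[0, 0])
        assert L.values[1, 0] == -0.1

    def test_non_numeric_cell_rejected_with_location(self, tmp_path):
        path = _write(
            tmp_path,
            "l.tsv",
            "chrom\tstart\tend\tprobe_id\tA\nchr1\t100\t160\tp1\toops\n",
        )
        with pytest.raises(ValueError, match="'A'"):
            read_logratio_table(path)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            "l.tsv",
            "chrom\tstart\tend\tprobe_id\tA\n"
            "chr1\t100\t160\tp1\t0.1\nchr1\t200\t260\tp1\t0.2\n",
        )
        with pytest.raises(ValueError, match="duplicate probe_id"):
            read_logratio_table(path)

    def test_round_trip(self, tmp_path, rng, small_index, matrix_factory):
        L = matrix_factory(rng.normal(size=(3, 12)), small_index)
        path = tmp_path / "rt.tsv"
        write_logratio_table(path, L)
        pi2, L2 = read_logratio_table(path)
        assert list(pi2.probe_id) == list(small_index.probe_id)
        np.testing.assert_allclose(L2.values, L.values, atol=1e-6)


class TestSegmentation:
    def test_bp_range_maps_to_probe_positions(self, tmp_path, small_index):
        # probes start at 0,1000,...,11000; segment covering probes 3..7
        path = _write(
            tmp_path,
            "s.seg",
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "S0\tchr1\t3001\t7500\t5\t-0.3\n",
        )
        seg = read_segmentation(path, small_index)
        rec = seg.records.iloc[0]
        assert (rec.start_pos, rec.end_pos, rec.n_probes) == (3, 8, 5)
        assert rec.seg_mean == -0.3

    def test_segment_in_unknown_chromosome_dropped_with_warning(
        self, tmp_path, small_index
    ):
        path = _write(
            tmp_path,
            "s.seg",
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "S0\tchrX\t1\t5000\t5\t-0.3\n",
        )
        with pytest.warns(UserWarning, match="dropped"):
            seg = read_segmentation(path, small_index)
        assert len(seg) == 0

    def test_overlapping_segments_same_sample_rejected(self, tmp_path, small_index):
        path = _write(
            tmp_path,
            "s.seg",
            "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
            "S0\tchr1\t1\t5000\t5\t0.1\n"
            "S0\tchr1\t4001\t9000\t5\t-0.1\n",
        )
        with pytest.raises(ValueError, match="overlap"):
            read_segmentation(path, small_index)

    def test_seg_round_trip_is_bijective(self, tmp_path, small_index, segmentation_factory):
        seg = segmentation_factory(
            [
                ("S0", "chr1", 0, 4, 4, 0.25),
                ("S0", "chr1", 4, 12, 8, -0.125),
                ("S1", "chr1", 2, 9, 7, 0.5),
            ]
        )
        path = tmp_path / "rt.seg"
        write_segmentation(path, seg, small_index)
        seg2 = read_segmentation(path, small_index)
        pd.testing.assert_frame_equal(
            seg2.records, seg.records, check_dtype=False, atol=1e-6
        )


class TestIntervalDB:
    def test_bed_line_parsed_half_open(self, tmp_path):
        path = _write(tmp_path, "d.bed", "chr1\t100\t200\tvarA\n")
        db = read_interval_db(path, "isca")
        assert len(db) == 1
        row = db.intervals.iloc[0]
        assert (row.chrom, row.start, row.end, row.record_id) == ("chr1", 100, 200, "varA")

    def test_empty_file_gives_empty_db(self, tmp_path):
        db = read_interval_db(_write(tmp_path, "e.bed", ""), "dgv")
        assert len(db) == 0

    def test_zero_length_interval_skipped_and_counted(self, tmp_path):
        path = _write(tmp_path, "d.bed", "chr1\t100\t100\tx\nchr1\t5\t6\ty\n")
        with pytest.warns(UserWarning, match="1 malformed"):
            db = read_interval_db(path, "gad")
        assert len(db) == 1

    def test_record_id_synthesized_for_bed3(self, tmp_path):
        db = read_interval_db(_write(tmp_path, "d.bed", "chr1\t1\t10\n"), "dgv")
        assert db.intervals.iloc[0].record_id.startswith("dgv")


class TestOutputs:
    def test_empty_marker_set_writes_header_only(self, tmp_path, small_index):
        path = tmp_path / "m.bed"
        write_markers_bed(path, MarkerSet(k=7), small_index)
        assert path.read_text().strip() == "#chrom\tstart\tend\tsample\tpvalue"

    def test_marker_line_spans_window_bp(self, tmp_path, small_index):
        ms = MarkerSet(
            pd.DataFrame({"sample": ["S0"], "window": [0], "pvalue": [0.001]}), k=7
        )
        path = tmp_path / "m.bed"
        write_markers_bed(path, ms, small_index)
        line = path.read_text().splitlines()[1].split("\t")
        # window of probes 0..6: starts at probe 0 start, ends at probe 6 end
        assert line[:3] == ["chr1", "0", str(int(small_index.end[6]))]

    def test_scored_table_round_trip(self, tmp_path):
        scored = pd.DataFrame(
            {
                "sample": ["S0"],
                "chrom": ["chr1"],
                "start_pos": [3],
                "end_pos": [10],
                "n_probes": [7],
                "seg_mean": [-0.312345],
                "marker_probes": [7],
                "density_score": [100.0],
            }
        )
        path = tmp_path / "sc.tsv"
        write_scored_table(path, scored)
        back = read_scored_table(path)
        pd.testing.assert_frame_equal(back, scored, check_dtype=False, atol=1e-6)

    def test_write_outputs_creates_both_files(self, tmp_path, small_index):
        out = tmp_path / "out"
        write_outputs(MarkerSet(k=7), pd.DataFrame(), small_index, out)
        assert (out / "markers.bed").exists() and (out / "scored.tsv").exists()
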