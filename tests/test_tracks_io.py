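"""Genome-track I/O: binning, BedGraph round trips, bismark dialects, BED/GTF."""

import numpy as np
import pytest

from l0seg import l0_segment
from l0seg.tracks_io import (
    BinGrid,
    read_bed,
    read_bedgraph,
    read_bigwig_binned,
    read_bismark,
    read_gene_models,
    segmentation_to_intervals,
    write_bedgraph,
    write_bismark,
)


def make_bedgraph(path, chrom, starts, ends, values):
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


class TestBinnedReading:
    def test_sum_aggregation(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        make_bedgraph(p, "chr1", [0], [4], [1.0])  # per-base 1 over 4 bp
        series, grid = read_bigwig_binned(str(p), bin_bp=2)
        assert list(series.values) == [2.0, 2.0]
        assert list(series.weights) == [1.0, 1.0]

    def test_partial_last_bin_weight(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        make_bedgraph(p, "chr1", [0], [50], [1.0])
        series, grid = read_bigwig_binned(str(p), bin_bp=20)
        assert grid.n_bins == 3
        assert series.values[-1] == pytest.approx(10.0)
        assert series.weights[-1] == pytest.approx(0.5)

    def test_conservation_of_mass(self, tmp_path, rng):
        # binned sums equal the per-base total
        p = tmp_path / "t.bedgraph"
        vals = rng.poisson(5, 30).astype(float)
        make_bedgraph(p, "chr1", np.arange(30), np.arange(1, 31), vals)
        series, _ = read_bigwig_binned(str(p), bin_bp=7)
        assert series.values.sum() == pytest.approx(vals.sum(), abs=1e-6)

    def test_bigwig_round_trip_matches_direct_binning(self, tmp_path, rng):
        pyBigWig = pytest.importorskip("pyBigWig")
        vals = rng.poisson(3, 200).astype(float)
        bw_path = str(tmp_path / "t.bw")
        bw = pyBigWig.open(bw_path, "w")
        bw.addHeader([("chr1", 200)])
        bw.addEntries("chr1", 0, values=vals, span=1, step=1)
        bw.close()
        series, grid = read_bigwig_binned(bw_path, "chr1", 0, 200, bin_bp=20)
        want = vals.reshape(10, 20).sum(axis=1)
        assert np.allclose(series.values, want)

    def test_mean_option(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        make_bedgraph(p, "chr1", [0], [40], [3.0])
        series, _ = read_bigwig_binned(str(p), bin_bp=20, stat="mean")
        assert np.allclose(series.values, [3.0, 3.0])


class TestBedGraphWriting:
    def test_adjacent_equal_values_merged(self, tmp_path):
        out = tmp_path / "o.bedgraph"
        write_bedgraph(str(out), "chr1", [0, 20, 40], [20, 40, 60], [0.0, 0.0, 10.0])
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t") == ["chr1", "0", "40", "0"]

    def test_round_trip(self, tmp_path):
        out = tmp_path / "o.bedgraph"
        write_bedgraph(str(out), "chr1", [0, 40], [40, 100], [1.5, 2.5])
        track = read_bedgraph(str(out))
        assert list(track.starts) == [0, 40]
        assert list(track.ends) == [40, 100]
        assert list(track.values) == [1.5, 2.5]

    def test_segment_spanning_partial_bin_clipped_to_region_end(self):
        seg = l0_segment(np.array([1.0, 1.0, 5.0]), "gaussian", 0.1)
        grid = BinGrid("chr1", 0, 50, 20)  # last bin covers 10 bp
        starts, ends, values = segmentation_to_intervals(seg, grid)
        assert ends[-1] == 50  # region end, not bin end 60


class TestBismark:
    def test_cov_dialect_one_based(self, tmp_path):
        p = tmp_path / "m.cov"
        p.write_text("chr1\t101\t101\t75.0\t3\t1\nchr1\t151\t151\t50.0\t2\t2\n")
        series, pos, chrom = read_bismark(str(p))
        assert chrom == "chr1"
        assert list(pos) == [100, 150]  # converted to 0-based
        assert list(series.meth) == [3.0, 2.0]
        assert list(series.total) == [4.0, 4.0]

    def test_bedgraph_dialect_zero_based(self, tmp_path):
        p = tmp_path / "m.cov"
        p.write_text("chr1\t100\t101\t75.0\t3\t1\n")
        series, pos, _ = read_bismark(str(p))
        assert list(pos) == [100]
        assert series.total[0] == 4.0

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "m.cov"
        p.write_text("chr1\t101\t101\t75.0\t3\t1\nchr1\t151\t151\tbad\tx\t2\n")
        with pytest.raises(ValueError, match=":2"):
            read_bismark(str(p))

    def test_unsorted_positions_rejected(self, tmp_path):
        p = tmp_path / "m.cov"
        p.write_text("chr1\t151\t151\t50.0\t2\t2\nchr1\t101\t101\t75.0\t3\t1\n")
        with pytest.raises(ValueError, match="increasing"):
            read_bismark(str(p))

    def test_empty_region_gives_empty_series(self, tmp_path):
        p = tmp_path / "m.cov"
        p.write_text("chr1\t101\t101\t75.0\t3\t1\n")
        series, pos, _ = read_bismark(str(p), start=5000, end=6000)
        assert pos.size == 0

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "m.cov"
        write_bismark(str(p), "chr2", [10, 20], [3, 0], [4, 5])
        series, pos, chrom = read_bismark(str(p))
        assert chrom == "chr2"
        assert list(pos) == [10, 20]
        assert list(series.meth) == [3.0, 0.0]
        assert list(series.total) == [4.0, 5.0]


class TestBedAndGenes:
    def test_bed6_strand_aware_tss_tes(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t500\ttx1\t0\t+\nchr1\t700\t900\ttx2\t0\t-\n")
        df = read_gene_models(str(p))
        plus = df[df["name"] == "tx1"].iloc[0]
        minus = df[df["name"] == "tx2"].iloc[0]
        assert (plus["tss"], plus["tes"]) == (100, 500)
        assert (minus["tss"], minus["tes"]) == (900, 700)

    def test_bed12_outer_bounds(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t500\ttx1\t0\t+\t120\t480\t0\t2\t50,50\t0,350\n")
        df = read_gene_models(str(p))
        assert df.iloc[0]["tes"] == 500

    def test_gtf_transcripts(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\ttranscript\t101\t500\t.\t+\t.\ttranscript_id "t1";\n'
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\ttranscript_id "t1";\n'
        )
        df = read_gene_models(str(p))
        assert len(df) == 1
        assert df.iloc[0]["start"] == 100  # GTF is 1-based
        assert df.iloc[0]["tes"] == 500

    def test_read_bed_scores_and_names(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t10\t50\tpeak1\t100\t.\nchr1\t70\t90\tpeak2\t200\t.\n")
        bed = read_bed(p.as_posix())
        assert len(bed) == 2
        assert list(bed.name) == ["peak1", "peak2"]
        assert bed.score[1] == 200
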