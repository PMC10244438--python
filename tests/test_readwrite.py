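"""BED/bedGraph/DEG/gene-model parsing: examples, error contracts, round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seconsensus as sc
from seconsensus.readwrite import ParseError

from oracles import region_mass_oracle


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadIntervals:
    def test_bed6_field_mapping(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr1\t100\t600\tpeak1\t25\t+\n")
        ps = sc.read_intervals(p)
        (iv,) = list(ps)
        assert (iv.chrom, iv.start, iv.end, iv.strand, iv.name) == (
            "chr1", 100, 600, "+", "peak1",
        )

    def test_output_sorted(self, tmp_path):
        p = write(tmp_path, "a.bed", "chr2\t50\t80\nchr1\t0\t10\n")
        ps = sc.read_intervals(p)
        assert [(iv.chrom, iv.start, iv.end) for iv in ps] == [
            ("chr1", 0, 10), ("chr2", 50, 80),
        ]

    @pytest.mark.parametrize(
        "line",
        ["chr1\t600\t100", "chr1\t100\t100", "chr1\tx\t200", "chr1\t-5\t200"],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = write(tmp_path, "a.bed", "chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            sc.read_intervals(p)

    def test_skips_track_browser_comment_lines(self, tmp_path):
        p = write(
            tmp_path, "a.bed",
            'track name="x"\nbrowser position chr1\n# c\nchr1\t1\t2\n',
        )
        assert len(sc.read_intervals(p)) == 1

    def test_empty_file_is_empty_peakset(self, tmp_path):
        assert len(sc.read_intervals(write(tmp_path, "e.bed", ""))) == 0

    def test_round_trip(self, tmp_path):
        ivs = [
            sc.GenomicInterval("chr1", 0, 10, "+", "a"),
            sc.GenomicInterval("chr1", 50, 900, "-", "b"),
            sc.GenomicInterval("chr2", 5, 6),
        ]
        out = tmp_path / "rt.bed"
        sc.write_intervals(ivs, out)
        back = sc.read_intervals(out)
        assert [(i.chrom, i.start, i.end, i.strand) for i in back] == [
            (i.chrom, i.start, i.end, i.strand) for i in ivs
        ]

    @given(
        rows=st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(0, 10_000),
                st.integers(1, 5_000),
            ),
            max_size=50,
        )
    )
    def test_random_valid_bed_parses_to_valid_intervals(self, tmp_path_factory, rows):
        tmp = tmp_path_factory.mktemp("bed")
        text = "".join(f"{c}\t{s}\t{s + l}\n" for c, s, l in rows)
        ps = sc.read_intervals(write(tmp, "r.bed", text))
        assert len(ps) == len(rows)
        keys = [iv.sort_key() for iv in ps]
        assert keys == sorted(keys)
        for iv in ps:
            assert iv.end > iv.start >= 0 and iv.chrom


class TestReadSignalTrack:
    def test_uniform_record_fills_bins(self, tmp_path):
        p = write(tmp_path, "a.bedGraph", "chr1\t0\t100\t5.0\n")
        t = sc.read_signal_track(p, bin_width=50)
        assert t.bins["chr1"].tolist() == [5.0, 5.0]

    def test_partial_bin_gets_length_weighted_average(self, tmp_path):
        p = write(tmp_path, "a.bedGraph", "chr1\t0\t75\t4.0\n")
        t = sc.read_signal_track(p, bin_width=50)
        assert t.bins["chr1"].tolist() == [4.0, 2.0]

    def test_absent_chromosome_reads_zero(self, tmp_path):
        p = write(tmp_path, "a.bedGraph", "chr1\t0\t100\t5.0\n")
        t = sc.read_signal_track(p, bin_width=50)
        assert sc.region_signal(t, sc.GenomicInterval("chr2", 0, 100)) == 0.0

    def test_overlapping_records_error(self, tmp_path):
        p = write(tmp_path, "a.bedGraph", "chr1\t0\t100\t5.0\nchr1\t50\t150\t1.0\n")
        with pytest.raises(ParseError, match="overlap"):
            sc.read_signal_track(p, bin_width=50)

    def test_unknown_format_error(self, tmp_path):
        p = write(tmp_path, "a.bedGraph", "chr1\t0\t100\t5.0\n")
        with pytest.raises(ValueError, match="format"):
            sc.read_signal_track(p, bin_width=50, format="wiggle")

    @given(
        raw=st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 97), st.floats(0, 100)),
            max_size=20,
        ),
        bin_width=st.sampled_from([1, 7, 50, 64]),
    )
    def test_mass_conservation(self, tmp_path_factory, raw, bin_width):
        # lay records end to end so they never overlap
        pos, records = 0, []
        for gap, length, value in raw:
            start = pos + gap
            records.append((start, start + length, value))
            pos = start + length
        tmp = tmp_path_factory.mktemp("bg")
        text = "".join(f"chr1\t{s}\t{e}\t{v!r}\n" for s, e, v in records)
        t = sc.read_signal_track(write(tmp, "m.bedGraph", text), bin_width)
        binned = t.total_mass()
        direct = sum(v * (e - s) for s, e, v in records)
        assert binned == pytest.approx(direct, rel=1e-9, abs=1e-9)


class TestGeneModelAndDEG:
    def test_gene_model_tsv_and_strand_aware_tss(self, tmp_path):
        p = write(
            tmp_path, "g.tsv",
            "gene_id\tchrom\tstart\tend\tstrand\nA\tchr1\t100\t200\t+\nB\tchr1\t300\t400\t-\n",
        )
        a, b = sc.read_gene_models(p)
        assert a.tss == 100 and b.tss == 399

    def test_gtf_lite_converts_coordinates(self, tmp_path):
        p = write(
            tmp_path, "g.gtf",
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "A";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "A";\n',
        )
        (g,) = sc.read_gene_models(p)
        assert (g.interval.start, g.interval.end) == (100, 200)

    def test_duplicate_gene_id_error(self, tmp_path):
        p = write(
            tmp_path, "g.tsv",
            "gene_id\tchrom\tstart\tend\tstrand\nA\tchr1\t1\t2\t+\nA\tchr1\t5\t9\t+\n",
        )
        with pytest.raises(ParseError, match="duplicate"):
            sc.read_gene_models(p)

    def test_deg_row_mapping(self, tmp_path):
        p = write(
            tmp_path, "d.tsv",
            "gene\tlog2fc\tpvalue\tqvalue\nZBTB16\t2.1\t1e-6\t1e-4\n",
        )
        (r,) = sc.read_deg_table(p)
        assert (r.gene_id, r.log2fc, r.pvalue, r.qvalue) == ("ZBTB16", 2.1, 1e-6, 1e-4)

    def test_pvalue_only_leaves_q_missing(self, tmp_path):
        p = write(tmp_path, "d.tsv", "gene\tlog2fc\tpvalue\nA\t1.0\t0.5\nB\t-2\t0.1\n")
        recs = sc.read_deg_table(p)
        assert [r.qvalue for r in recs] == [None, None]
        assert [r.gene_id for r in recs] == ["A", "B"]  # input order kept

    def test_duplicate_gene_error(self, tmp_path):
        p = write(tmp_path, "d.tsv", "gene\tlog2fc\tpvalue\nSP7\t1\t0.1\nSP7\t2\t0.2\n")
        with pytest.raises(ParseError, match="SP7"):
            sc.read_deg_table(p)

    def test_no_significance_column_error(self, tmp_path):
        p = write(tmp_path, "d.tsv", "gene\tlog2fc\nA\t1\n")
        with pytest.raises(ParseError, match="p-value"):
            sc.read_deg_table(p)

    def test_deseq2_style_aliases(self, tmp_path):
        p = write(
            tmp_path, "d.tsv",
            "gene_name\tlog2FoldChange\tpval\tpadj\nA\t1.5\t0.001\t0.01\n",
        )
        (r,) = sc.read_deg_table(p)
        assert r.qvalue == 0.01

    def test_gene_list_skips_comments(self, tmp_path):
        p = write(tmp_path, "l.txt", "# header\nZBTB16\n\nSP7\n")
        assert sc.read_gene_list(p) == ["ZBTB16", "SP7"]


class TestIntervalInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=-1, end=10),
            dict(chrom="chr1", start=10, end=10),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sc.GenomicInterval(**kwargs)

    def test_binned_track_matches_per_base_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 5, 40)
        t = sc.SignalTrack(bins={"chr1": arr}, bin_width=7)
        for _ in range(20):
            s = int(rng.integers(0, 250))
            e = s + int(rng.integers(1, 60))
            got = sc.region_signal(t, sc.GenomicInterval("chr1", s, e))
            assert got == pytest.approx(region_mass_oracle(arr, 7, s, e), rel=1e-9)
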