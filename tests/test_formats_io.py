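"""Format readers/writers: coordinate conventions, naming, round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from novoseqkit import formats_io as fio


# ---------------------------------------------------------------------------
# FASTA and contig naming
# ---------------------------------------------------------------------------


class TestFasta:
    def test_name_parsed_at_last_underscore(self, tmp_path):
        p = tmp_path / "in.fa"
        p.write_text(">Donor0010_1572\nacgt\n>A_B_7\nACGTACGT\n")
        contigs = fio.read_fasta(p)
        assert contigs[0].individual_id == "Donor0010"
        assert contigs[0].local_id == "1572"
        assert contigs[0].length == 4
        assert contigs[0].sequence == "ACGT"  # uppercased
        assert (contigs[1].individual_id, contigs[1].local_id) == ("A_B", "7")

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert fio.read_fasta(p) == []

    def test_header_without_underscore_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">noUnderscore\nACGT\n")
        with pytest.raises(fio.FormatError, match="noUnderscore"):
            fio.read_fasta(p)

    def test_empty_sequence_rejected(self):
        with pytest.raises(fio.FormatError):
            fio.Contig("Ind1", "1", "")

    def test_roundtrip(self, tmp_path):
        contigs = [fio.Contig("Ind_x", str(i), "ACGTA" * (i + 1)) for i in range(5)]
        p = tmp_path / "out.fa"
        fio.write_fasta(contigs, p)
        assert fio.read_fasta(p) == contigs


# ---------------------------------------------------------------------------
# show-coords tab dialect
# ---------------------------------------------------------------------------


def _coords_row(qs, qe, ts, te, idy=96.0, covr=80.0, covq=91.0, tagr="chr1", tagq="q"):
    l1, l2 = abs(qe - qs) + 1, abs(te - ts) + 1
    return "\t".join(
        [str(qs), str(qe), str(ts), str(te), str(l1), str(l2),
         f"{idy:.2f}", f"{covr:.2f}", f"{covq:.2f}", tagr, tagq]
    )


class TestCoordsTable:
    def test_one_based_inclusive_to_half_open(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(_coords_row(1, 100, 201, 300) + "\n")
        (hit,) = fio.read_coords_table(p)
        assert (hit.query_start, hit.query_end) == (0, 100)
        assert (hit.target_start, hit.target_end) == (200, 300)
        assert hit.strand == "+"
        assert hit.identity_pct == 96.0
        assert hit.query_cov_pct == 91.0

    def test_reversed_target_is_minus_strand(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(_coords_row(1, 100, 500, 301) + "\n")
        (hit,) = fio.read_coords_table(p)
        assert hit.strand == "-"
        assert (hit.target_start, hit.target_end) == (300, 500)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text("")
        assert fio.read_coords_table(p) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "a.coords"
        p.write_text(_coords_row(1, 10, 1, 10) + "\n1\t2\t3\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_coords_table(p)

    def test_write_read_involution(self, tmp_path):
        p1, p2 = tmp_path / "a.coords", tmp_path / "b.coords"
        p1.write_text(
            _coords_row(1, 100, 201, 300, 96.55, 80.10, 91.00) + "\n"
            + _coords_row(5, 250, 900, 601, 99.00, 50.00, 75.25) + "\n"
        )
        hits = fio.read_coords_table(p1)
        fio.write_coords_table(hits, p2)
        assert p1.read_text() == p2.read_text()


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------


def _rm_out(rows):
    header = "header\nheader\n\n"
    lines = []
    for score, seq_id, begin, end, cls in rows:
        lines.append(
            f"  {score}  1.0  0.0  0.0  {seq_id}  {begin}  {end}  (0)  +  rep  {cls}  1  10  (0)  1"
        )
    return header + "\n".join(lines) + "\n"


class TestRepeatMasker:
    def test_single_line_annotation(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(_rm_out([(500, "c1", 101, 200, "LINE/L1")]))
        (ann,) = fio.parse_repeatmasker_out(p, {"c1": 400})
        counts = ann.class_base_counts()
        assert counts["LINE"] == 100
        assert counts["Unmasked"] == 300

    def test_unannotated_sequence_fully_unmasked(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(_rm_out([]))
        (ann,) = fio.parse_repeatmasker_out(p, {"c1": 250})
        assert ann.class_base_counts()["Unmasked"] == 250

    def test_overlap_resolved_by_higher_score(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            _rm_out(
                [
                    (300, "c1", 1, 100, "SINE/Alu"),
                    (500, "c1", 51, 150, "LINE/L1"),
                ]
            )
        )
        (ann,) = fio.parse_repeatmasker_out(p, {"c1": 200})
        counts = ann.class_base_counts()
        assert counts["LINE"] == 100  # wins the 50 bp overlap
        assert counts["SINE"] == 50
        assert counts["Unmasked"] == 50

    def test_unknown_sequence_id_rejected(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(_rm_out([(500, "ghost", 1, 10, "LINE/L1")]))
        with pytest.raises(fio.FormatError, match="ghost"):
            fio.parse_repeatmasker_out(p, {"c1": 100})

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("LINE/L1", "LINE"),
            ("SINE/Alu", "SINE"),
            ("LTR/ERVL", "LTR"),
            ("DNA/hAT", "DNA"),
            ("Simple_repeat", "Simple_repeat"),
            ("Satellite/centr", "Satellite"),
            ("snRNA", "RNA"),
            ("Low_complexity", "Low_complexity"),
            ("Unknown", "Other"),
        ],
    )
    def test_class_mapping(self, raw, expected):
        assert fio.map_repeat_class(raw) == expected

    def test_writer_roundtrip(self, tmp_path):
        ann = fio.RepeatAnnotation("c1", 500, [(10, 110, "LINE"), (200, 260, "SINE")])
        p = tmp_path / "rm.out"
        fio.write_repeatmasker_out([ann], p)
        (back,) = fio.parse_repeatmasker_out(p, {"c1": 500})
        assert back.intervals == ann.intervals

    def test_annotation_tsv_roundtrip(self, tmp_path):
        anns = [
            fio.RepeatAnnotation("a", 500, [(10, 110, "LINE"), (200, 260, "SINE")]),
            fio.RepeatAnnotation("b", 300, []),
        ]
        p = tmp_path / "ann.tsv"
        fio.write_repeat_annotation_tsv(anns, p)
        assert fio.read_repeat_annotation_tsv(p) == anns


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


class TestBed:
    def test_read(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tgene\n")
        (iv,) = fio.read_bed(p)
        assert iv == fio.GenomicInterval("chr1", 10, 20, "gene")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
                st.sampled_from(["a", "b", "x_1"]),
            ),
            max_size=20,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip(self, tmp_path_factory, raw):
        intervals = [
            fio.GenomicInterval(c, s, s + ln, lab) for c, s, ln, lab in raw
        ]
        p = tmp_path_factory.mktemp("bed") / "r.bed"
        fio.write_bed(intervals, p)
        assert fio.read_bed(p) == intervals

    def test_invalid_interval_rejected_with_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\tx\nchr1\t30\t30\ty\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_bed(p)

    def test_negative_start_rejected(self):
        with pytest.raises(fio.FormatError):
            fio.GenomicInterval("chr1", -1, 10)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _write_vcf(path, rows):
    head = (
        "##fileformat=VCFv4.2\n"
        '##FILTER=<ID=LowQual,Description="l">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
        '##ALT=<ID=DEL,Description="d">\n'
        '##ALT=<ID=DUP,Description="d">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "##contig=<ID=chr1,length=100000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    path.write_text(head + "".join(r + "\n" for r in rows))


class TestDeletionVcf:
    def test_pos_end_gt_conversion(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_vcf(p, ["chr1\t101\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\tGT\t0/1"])
        (rec,) = fio.read_deletion_vcf(p, "ind1")
        assert (rec.start, rec.end) == (100, 200)
        assert rec.genotype == "het"
        assert rec.svtype == "DEL"
        assert rec.filter_status == "PASS"

    def test_svlen_fallback(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_vcf(p, ["chr1\t101\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-50\tGT\t1/1"])
        (rec,) = fio.read_deletion_vcf(p)
        assert (rec.start, rec.end) == (100, 150)
        assert rec.genotype == "hom_alt"

    def test_lowqual_retained_at_read_time(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_vcf(p, ["chr1\t11\t.\tN\t<DEL>\t.\tLowQual\tSVTYPE=DEL;END=60\tGT\t0/0"])
        (rec,) = fio.read_deletion_vcf(p)
        assert rec.filter_status == "LowQual"
        assert rec.genotype == "hom_ref"

    def test_missing_genotype(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_vcf(p, ["chr1\t11\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=60\tGT\t./."])
        (rec,) = fio.read_deletion_vcf(p)
        assert rec.genotype == "missing"

    def test_writer_roundtrip(self, tmp_path):
        recs = [
            fio.DeletionRecord("i1", "chr1", 100, 250, "PASS", "DEL", "het"),
            fio.DeletionRecord("i1", "chr1", 400, 900, "LowQual", "DEL", "hom_alt"),
            fio.DeletionRecord("i1", "chr1", 950, 1000, "PASS", "other", "missing"),
        ]
        p = tmp_path / "a.vcf"
        fio.write_deletion_vcf(recs, p, "i1", {"chr1": 100_000})
        assert fio.read_deletion_vcf(p, "i1") == recs


# ---------------------------------------------------------------------------
# SAM flag stream
# ---------------------------------------------------------------------------


class TestSamFlagStream:
    def _sam(self, tmp_path, body):
        p = tmp_path / "a.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:ns1\tLN:500\n" + body)
        return p

    def test_flags_and_targets(self, tmp_path):
        p = self._sam(
            tmp_path,
            "r1\t0\tns1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"
            "r3\t2048\tns1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n",
        )
        recs = list(fio.read_sam_flag_stream(p))
        assert recs[0] == fio.SamFlagRecord("r1", 0, "ns1")
        assert recs[1].target_id is None and recs[1].is_unmapped
        assert recs[2].is_supplementary and recs[2].target_id == "ns1"

    def test_non_integer_flag_rejected(self, tmp_path):
        p = self._sam(tmp_path, "r1\tzero\tns1\t1\t60\t10M\t*\t0\t0\tA\t*\n")
        with pytest.raises(fio.FormatError, match="non-integer flag"):
            list(fio.read_sam_flag_stream(p))

    def test_writer_roundtrip(self, tmp_path):
        recs = [
            (fio.SamFlagRecord("r1", 0, "ns1"), "ACGT"),
            (fio.SamFlagRecord("r2", 4, None), "TTTT"),
            (fio.SamFlagRecord("r1", 0x100, "ns1"), "ACGT"),
        ]
        p = tmp_path / "a.sam"
        fio.write_sam_flag_stream(recs, p, {"ns1": 500})
        assert list(fio.read_sam_flag_stream(p)) == [r for r, _ in recs]
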