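"""Format readers/writers and the cytosine context classifier."""

import itertools

import pytest

from methsuite.formats import (Alignment, FormatError, classify_context,
                               read_cgmap, read_fasta, read_gene_annotation,
                               read_tfbs_bed, revcomp, write_cgmap,
                               write_tfbs_bed)
from methsuite.formats import CytosineRecord, H_BASES

from conftest import make_genome


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        g = read_fasta(p)
        assert list(g) == ["chr1"]
        assert g["chr1"].seq == "ACGT"
        assert g["chr1"].length == 4

    def test_case_folding_and_multiline(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgt\nACGT\n")
        assert read_fasta(p)["a"].seq == "ACGTACGT"

    def test_duplicate_header_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError, match="empty"):
            read_fasta(p)

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>a\nAC\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def oracle_context(seq: str, pos: int, strand_base: str) -> str | None:
    """Independent string-based classifier: extract the 3-mer starting at
    the cytosine on its own strand, then pattern-match."""
    i = pos - 1
    if strand_base == "C":
        trimer = seq[i:i + 3]
    else:
        trimer = revcomp(seq[max(0, i - 2):i + 1])
    if len(trimer) >= 2 and trimer[1] == "G":
        return "CG"
    if len(trimer) == 3 and trimer[1] in H_BASES and trimer[2] == "G":
        return "CHG"
    if len(trimer) == 3 and trimer[1] in H_BASES and trimer[2] in H_BASES:
        return "CHH"
    return None


class TestClassifyContext:
    @pytest.mark.parametrize("seq,pos,base,expect", [
        ("ACGT", 2, "C", "CG"),
        ("CCGT", 1, "C", "CHG"),
        ("CATT", 1, "C", "CHH"),
        ("ACGT", 3, "G", "CG"),      # reverse-complement context
        ("ACNT", 2, "C", None),      # N neighbour is unassignable
        ("AAAC", 4, "C", None),      # runs off the chromosome end
    ])
    def test_examples(self, seq, pos, base, expect):
        g = make_genome(c=seq)
        assert classify_context(g, "c", pos, base) == expect

    def test_wrong_reference_base_is_contract_violation(self):
        g = make_genome(c="ACGT")
        with pytest.raises(ValueError, match="expected C"):
            classify_context(g, "c", 1, "C")

    def test_agrees_with_oracle_on_all_4mers(self):
        for bases in itertools.product("ACGT", repeat=4):
            seq = "".join(bases)
            g = make_genome(c=seq)
            for i, b in enumerate(seq, 1):
                if b in "CG":
                    assert classify_context(g, "c", i, b) == \
                        oracle_context(seq, i, b), (seq, i, b)


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

class TestCGmap:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("chr1\tC\t5\tCG\tCG\t0.75\t3\t4\n")
        (r,) = read_cgmap(p)
        assert (r.chrom, r.pos, r.strand_base, r.context) == \
            ("chr1", 5, "C", "CG")
        assert (r.level, r.mc_count, r.total_count) == (0.75, 3, 4)

    def test_uncovered_site_has_undefined_level(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("chr1\tC\t5\tCG\tCG\tna\t0\t0\n")
        (r,) = read_cgmap(p)
        assert r.total_count == 0 and r.level is None

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("chr1\tC\t5\tCG\tCG\t0.75\t3\n")
        with pytest.raises(FormatError, match="line 1"):
            list(read_cgmap(p))

    def test_non_numeric_count_is_error(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("chr1\tC\t5\tCG\tCG\t0.75\tx\t4\n")
        with pytest.raises(FormatError, match="non-numeric"):
            list(read_cgmap(p))

    def test_non_cytosine_context_lines_are_skipped(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("chr1\tC\t1\t--\t--\t0\t0\t1\n"
                     "chr1\tC\t5\tCG\tCG\t0.75\t3\t4\n")
        assert len(list(read_cgmap(p))) == 1

    def test_roundtrip_is_byte_identical(self, tmp_path):
        records = [
            CytosineRecord("chr1", 5, "C", "CG", 0.75, 3, 4, "CG"),
            CytosineRecord("chr1", 9, "G", "CHH", None, 0, 0, "CA"),
            CytosineRecord("chr2", 2, "C", "CHG", 1 / 3, 1, 3, "CT"),
        ]
        p1, p2 = tmp_path / "a.cgmap", tmp_path / "b.cgmap"
        write_cgmap(records, p1)
        write_cgmap(read_cgmap(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3\n"


class TestGeneAnnotation:
    def test_gene_with_two_exons(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER +
                     "chr1\t.\tgene\t1001\t3000\t.\t+\t.\tID=g1\n"
                     "chr1\t.\texon\t1001\t1500\t.\t+\t.\tParent=g1\n"
                     "chr1\t.\texon\t2001\t3000\t.\t+\t.\tParent=g1\n")
        (g,) = read_gene_annotation(p)
        assert (g.gene_id, g.chrom, g.strand) == ("g1", "chr1", "+")
        assert g.exons == ((1001, 1500), (2001, 3000))
        assert g.introns == ((1501, 2000),)

    def test_exonless_gene_gets_spanning_exon(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER +
                     "chr1\t.\tgene\t100\t200\t.\t-\t.\tID=g1\n")
        (g,) = read_gene_annotation(p)
        assert g.exons == ((100, 200),)

    def test_exon_outside_span_is_clamped(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER +
                     "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n"
                     "chr1\t.\texon\t150\t250\t.\t+\t.\tParent=g1\n")
        (g,) = read_gene_annotation(p)
        assert g.exons == ((150, 200),)

    def test_unknown_strand_gene_is_dropped(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER +
                     "chr1\t.\tgene\t100\t200\t.\t.\t.\tID=g1\n"
                     "chr1\t.\tgene\t300\t400\t.\t+\t.\tID=g2\n")
        genes = read_gene_annotation(p)
        assert [g.gene_id for g in genes] == ["g2"]

    def test_exons_linked_through_mrna(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER +
                     "chr1\t.\tgene\t100\t400\t.\t+\t.\tID=g1\n"
                     "chr1\t.\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1\n"
                     "chr1\t.\texon\t100\t180\t.\t+\t.\tParent=t1\n"
                     "chr1\t.\texon\t300\t400\t.\t+\t.\tParent=t1\n")
        (g,) = read_gene_annotation(p)
        assert g.exons == ((100, 180), (300, 400))


# ---------------------------------------------------------------------------
# BED and SAM geometry
# ---------------------------------------------------------------------------

class TestBed:
    def test_coordinates_converted_to_1based_inclusive(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t110\tSOX2\n")
        (t,) = read_tfbs_bed(p)
        assert (t.chrom, t.start, t.end, t.name) == ("chr1", 101, 110, "SOX2")
        assert t.end - t.start + 1 == 10  # interval width preserved

    def test_three_column_bed_gets_default_name(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t5\n")
        (t,) = read_tfbs_bed(p)
        assert t.name == "TFBS" and t.start == 1 and t.end == 5

    def test_roundtrip_preserves_half_open_coordinates(self, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        p1.write_text("chr1\t100\t110\tSOX2\t0\t-\nchr2\t0\t3\tX\t0\t+\n")
        write_tfbs_bed(read_tfbs_bed(p1), p2)
        assert p1.read_text() == p2.read_text()


class TestAlignmentGeometry:
    def test_softclip_reference_footprint(self):
        aln = Alignment("r", "c", 10, "ACGTACGTAC", [("S", 2), ("M", 8)],
                        "watson")
        assert aln.reference_length() == 8
        pairs = list(aln.aligned_pairs())
        assert pairs[0] == (2, 10) and pairs[-1] == (9, 17)

    def test_deletion_splits_blocks(self):
        aln = Alignment("r", "c", 5, "ACGT", [("M", 2), ("D", 1), ("M", 2)],
                        "watson")
        assert aln.reference_length() == 5
        assert aln.reference_blocks() == [(5, 6), (8, 9)]
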