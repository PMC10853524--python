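import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xrprofile import (
    Genome,
    GenomicInterval,
    InputError,
    deduplicate_reads,
    fetch_sequence,
    read_bed6,
    read_chromatin_states,
    read_fasta,
    read_gene_annotation,
    reverse_complement,
    write_bed6,
    write_bedgraph_rpm,
)
from xrprofile.genome_io import check_chromosomes

from conftest import make_reads


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_case_normalized(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n")
        g = read_fasta(p)
        assert dict(g) == {"chr1": "ACGT"}

    def test_two_records_lengths(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a desc ignored\n" + "A" * 10 + "\n>b\n" + "C" * 20 + "\n")
        g = read_fasta(p)
        assert g.chrom_sizes() == {"a": 10, "b": 20}

    def test_illegal_character_named(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chrX\nACGUT\n")
        with pytest.raises(InputError, match="chrX"):
            read_fasta(p)
        with pytest.raises(InputError, match="position 4"):
            read_fasta(p)

    def test_duplicate_chromosome(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c\nAA\n>c\nCC\n")
        with pytest.raises(InputError, match="duplicate"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(InputError):
            read_fasta(p)


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

class TestBed6:
    def test_single_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t10\t37\tr1\t0\t+\n")
        rs = read_bed6(p)
        assert len(rs) == 1
        rec = rs[0]
        assert (rec.interval.chrom, rec.interval.start, rec.interval.end) == ("chr1", 10, 37)
        assert rec.interval.strand == "+" and rec.length == 27

    def test_empty_file(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("")
        assert len(read_bed6(p)) == 0

    def test_dot_strand_rejected_with_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t5\ta\t0\t+\nchr1\t5\t9\tb\t0\t.\n")
        with pytest.raises(InputError, match="line 2"):
            read_bed6(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t9\t5\ta\t0\t+\n")
        with pytest.raises(InputError, match="start >= end"):
            read_bed6(p)

    def test_round_trip(self, tmp_path):
        rs = make_reads(
            [("chr2", 5, 31, "-", "x"), ("chr1", 0, 27, "+", "y"), ("chr1", 3, 30, "-", "z")]
        )
        p = tmp_path / "rt.bed"
        write_bed6(rs, p)
        back = read_bed6(p)
        assert back.equals(rs)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

GFF = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=g1;biotype=protein_coding
chr1\tsrc\tgene\t301\t400\t.\t+\t.\tID=g2;biotype=protein_coding
chr1\tsrc\tgene\t501\t600\t.\t+\t.\tID=g3;biotype=lncRNA
"""


class TestGeneAnnotation:
    def test_gff3_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        genes = read_gene_annotation(p, "gff3")
        g1 = next(g for g in genes if g.id == "g1")
        assert (g1.interval.start, g1.interval.end, g1.interval.strand) == (100, 200, "-")

    def test_biotype_filter(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        assert {g.id for g in read_gene_annotation(p, "gff3")} == {"g1", "g2"}
        assert len(read_gene_annotation(p, "gff3", biotype_filter=None)) == 3

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=AT2G23430\n"
            "chr1\ts\tgene\t20\t30\t.\t+\t.\tID=AT2G23430\n"
        )
        with pytest.raises(InputError):
            read_gene_annotation(p, "gff3", biotype_filter=None)

    def test_bed6_genes(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tga\t0\t+\nchr1\t200\t300\tgb\t0\t-\nchr2\t0\t50\tgc\t0\t+\n")
        genes = read_gene_annotation(p, "bed6")
        assert [g.id for g in genes] == ["ga", "gb", "gc"]


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------

class TestFetchSequence:
    genome = Genome({"chr1": "AACCGGTT"})

    def test_forward(self):
        assert fetch_sequence(self.genome, GenomicInterval("chr1", 0, 4, "+")) == "AACC"

    def test_reverse_complement(self):
        assert fetch_sequence(self.genome, GenomicInterval("chr1", 0, 4, "-")) == "GGTT"
        assert fetch_sequence(self.genome, GenomicInterval("chr1", 4, 8, "-")) == "AACC"

    def test_out_of_bounds(self):
        with pytest.raises(InputError):
            fetch_sequence(self.genome, GenomicInterval("chr1", 4, 9, "+"))

    def test_unknown_chromosome(self):
        with pytest.raises(InputError):
            fetch_sequence(self.genome, GenomicInterval("chrZ", 0, 2, "+"))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=4, max_size=60),
        data=st.data(),
    )
    def test_strands_are_reverse_complements(self, seq, data):
        g = Genome({"c": seq})
        start = data.draw(st.integers(0, len(seq) - 2))
        end = data.draw(st.integers(start + 1, len(seq)))
        fwd = fetch_sequence(g, GenomicInterval("c", start, end, "+"))
        rev = fetch_sequence(g, GenomicInterval("c", start, end, "-"))
        assert rev == reverse_complement(fwd)
        assert len(fwd) == len(rev) == end - start


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------

class TestDeduplicate:
    def test_identical_collapse(self):
        rs = make_reads([("chr1", 0, 27, "+")] * 3)
        out, removed = deduplicate_reads(rs)
        assert len(out) == 1 and removed == 2

    def test_strand_in_key(self):
        rs = make_reads([("chr1", 0, 27, "+"), ("chr1", 0, 27, "-")])
        out, removed = deduplicate_reads(rs)
        assert len(out) == 2 and removed == 0

    def test_idempotent_and_order_independent(self):
        rows = [
            ("chr2", 5, 31, "-"),
            ("chr1", 0, 27, "+"),
            ("chr1", 0, 27, "+"),
            ("chr1", 3, 30, "-"),
        ]
        once, _ = deduplicate_reads(make_reads(rows))
        twice, removed = deduplicate_reads(once)
        assert removed == 0 and twice.equals(once)
        shuffled, _ = deduplicate_reads(make_reads(rows[::-1]))
        assert shuffled.equals(once, check_names=False)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

class TestBedgraph:
    def test_single_read_forced_scale(self, tmp_path):
        rs = make_reads([("chr1", 0, 10, "+")])
        p = tmp_path / "o.bedGraph"
        write_bedgraph_rpm(rs, {"chr1": 50}, p)
        assert p.read_text() == "chr1\t0\t10\t1e+06\n"

    def test_two_identical_reads(self, tmp_path):
        rs = make_reads([("chr1", 3, 8, "+"), ("chr1", 3, 8, "-")])
        p = tmp_path / "o.bedGraph"
        write_bedgraph_rpm(rs, {"chr1": 20}, p)
        assert p.read_text() == "chr1\t3\t8\t1e+06\n"

    def test_value_mass_equals_rpm_times_mean_length(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(200):
            s = int(rng.integers(0, 960))
            rows.append(("chr1", s, s + int(rng.integers(10, 40)), "+" if i % 2 else "-"))
        rs = make_reads(rows)
        p = tmp_path / "o.bedGraph"
        write_bedgraph_rpm(rs, {"chr1": 1000}, p)
        mass = sum(
            (int(e) - int(s)) * float(v)
            for _, s, e, v in (line.split("\t") for line in p.read_text().splitlines())
        )
        assert mass == pytest.approx(1e6 * rs.lengths.mean(), rel=1e-9)

    def test_empty_library_rejected(self, tmp_path):
        from xrprofile.intervals import ReadSet

        with pytest.raises(InputError):
            write_bedgraph_rpm(ReadSet.empty(), {"chr1": 10}, tmp_path / "x")

    def test_chromosome_mismatch_rejected(self, tmp_path):
        rs = make_reads([("chrZ", 0, 5, "+")])
        with pytest.raises(InputError, match="chrZ"):
            write_bedgraph_rpm(rs, {"chr1": 10}, tmp_path / "x")


def test_check_chromosomes_reports_missing():
    g = Genome({"chr1": "ACGT"})
    with pytest.raises(InputError, match="chr9"):
        check_chromosomes(make_reads([("chr9", 0, 2, "+")]), g)


def test_chromatin_state_overlap_rejected(tmp_path):
    p = tmp_path / "s.bed"
    p.write_text("chr1\t0\t100\topen\nchr1\t50\t150\thetAT\n")
    with pytest.raises(InputError, match="overlap"):
        read_chromatin_states(p)


def test_chromatin_state_load(tmp_path):
    p = tmp_path / "s.bed"
    p.write_text("chr1\t0\t100\topen\nchr1\t100\t150\thetAT\nchr2\t0\t80\tgenic\n")
    segs = read_chromatin_states(p)
    assert [s.state for s in segs] == ["open", "hetAT", "genic"]
    assert segs[0].interval.strand == "."
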