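import pytest

from mycogene.errors import ConsistencyError, FormatError
from mycogene.formats_io import (FORWARD, REVERSE, UNKNOWN, GeneModel,
                                 read_genes, read_genome, read_transcripts,
                                 write_gff3)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenome:
    def test_case_folding_and_simple_record(self, tmp_path):
        g = read_genome(_write(tmp_path, "a.fa", ">c1\nacgt\n"))
        assert g.contigs == {"c1": "ACGT"}

    def test_header_truncated_at_whitespace(self, tmp_path):
        g = read_genome(_write(tmp_path, "a.fa", ">c1 some description\nACGTN\n"))
        assert g.contigs == {"c1": "ACGTN"}

    def test_duplicate_contig_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="duplicate"):
            read_genome(_write(tmp_path, "a.fa", ">c1\nACGT\n>c1\nTTTT\n"))

    def test_invalid_character_names_line(self, tmp_path):
        with pytest.raises(FormatError, match=":2:"):
            read_genome(_write(tmp_path, "a.fa", ">c1\nACXT\n"))

    def test_sequence_before_header_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_genome(_write(tmp_path, "a.fa", "ACGT\n"))

    def test_multiline_sequence_joined(self, tmp_path):
        g = read_genome(_write(tmp_path, "a.fa", ">c1\nAC\nGT\n"))
        assert g.contigs["c1"] == "ACGT"


GTF_TWO_EXONS = (
    'c1\tcuff\texon\t1\t5\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'c1\tcuff\texon\t11\t15\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
)


class TestReadTranscripts:
    def test_gtf_two_exons(self, tmp_path):
        (t,) = read_transcripts(_write(tmp_path, "a.gtf", GTF_TWO_EXONS))
        assert t.transcript_id == "t1"
        assert t.exons == [(1, 5), (11, 15)]
        assert t.strand == FORWARD

    def test_dot_strand_is_unknown(self, tmp_path):
        (t,) = read_transcripts(
            _write(tmp_path, "a.gtf", GTF_TWO_EXONS.replace("\t+\t", "\t.\t"))
        )
        assert t.strand == UNKNOWN

    def test_gff3_parent_attribute(self, tmp_path):
        text = ("c1\tsrc\texon\t1\t5\t.\t-\t.\tID=e1;Parent=t9\n"
                "c1\tsrc\texon\t11\t15\t.\t-\t.\tID=e2;Parent=t9\n")
        (t,) = read_transcripts(_write(tmp_path, "a.gff3", text))
        assert t.transcript_id == "t9"
        assert t.strand == REVERSE

    def test_exon_order_insensitive(self, tmp_path):
        lines = GTF_TWO_EXONS.splitlines(keepends=True)
        shuffled = "".join(lines[::-1])
        (t,) = read_transcripts(_write(tmp_path, "a.gtf", shuffled))
        assert t.exons == [(1, 5), (11, 15)]

    def test_multi_contig_transcript_rejected(self, tmp_path):
        text = GTF_TWO_EXONS + \
            'c2\tcuff\texon\t1\t5\t.\t+\t.\ttranscript_id "t1";\n'
        with pytest.raises(ConsistencyError, match="t1"):
            read_transcripts(_write(tmp_path, "a.gtf", text))

    def test_conflicting_strands_rejected(self, tmp_path):
        text = GTF_TWO_EXONS + \
            'c1\tcuff\texon\t21\t25\t.\t-\t.\ttranscript_id "t1";\n'
        with pytest.raises(ConsistencyError, match="strand"):
            read_transcripts(_write(tmp_path, "a.gtf", text))

    def test_start_greater_than_end_rejected(self, tmp_path):
        text = 'c1\tcuff\texon\t9\t5\t.\t+\t.\ttranscript_id "t1";\n'
        with pytest.raises(FormatError):
            read_transcripts(_write(tmp_path, "a.gtf", text))

    def test_non_exon_lines_ignored(self, tmp_path):
        text = ('c1\tcuff\ttranscript\t1\t15\t.\t+\t.\ttranscript_id "t1";\n'
                + GTF_TWO_EXONS)
        (t,) = read_transcripts(_write(tmp_path, "a.gtf", text))
        assert t.exons == [(1, 5), (11, 15)]


class TestWriteGff3:
    def test_single_segment_forward_cds_line(self, tmp_path):
        g = GeneModel("g1", "c1", FORWARD, [(10, 18, 0)])
        path = tmp_path / "out.gff3"
        write_gff3([g], path)
        cds = [l for l in path.read_text().splitlines() if "\tCDS\t" in l]
        cols = cds[0].split("\t")
        assert cols[0] == "c1" and cols[3] == "10" and cols[4] == "18"
        assert cols[6] == "+" and cols[7] == "0"

    def test_reverse_two_segment_phases(self, tmp_path):
        # reverse gene: translation starts at the genomic right; walking
        # the spliced CDS 5'->3', segment (30,37) is first (8 nt, phase 0)
        # and (10, 20) second with phase (3 - 8 % 3) % 3 = 1
        g = GeneModel("g1", "c1", REVERSE, [(10, 20, 0), (30, 37, 0)])
        path = tmp_path / "out.gff3"
        write_gff3([g], path)
        cds = [l.split("\t") for l in path.read_text().splitlines()
               if "\tCDS\t" in l]
        assert [(c[3], c[4], c[7]) for c in cds] == [
            ("10", "20", "1"), ("30", "37", "0")
        ]

    def test_empty_gene_list(self, tmp_path):
        path = tmp_path / "out.gff3"
        write_gff3([], path)
        assert path.read_text() == "##gff-version 3\n"

    def test_round_trip_identity(self, tmp_path, small_truth):
        path = tmp_path / "rt.gff3"
        write_gff3(small_truth.genes, path)
        back = read_genes(path)
        orig = sorted(small_truth.genes, key=lambda g: g.start)
        back = sorted(back, key=lambda g: g.start)
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            a = a.with_phases()
            assert (a.contig, a.strand, a.cds_segments, a.provenance) == (
                b.contig, b.strand, b.cds_segments, b.provenance)
            assert (a.complete5prime, a.complete3prime) == (
                b.complete5prime, b.complete3prime)
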