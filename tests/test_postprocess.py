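import pytest

from mycogene.formats_io import FORWARD, REVERSE, GeneModel, TranscriptAlignment
from mycogene.postprocess import (apply_filters, combine, filter_nested,
                                  filter_short, filter_variants,
                                  report_fusions)


def gene(gid, segs, strand=FORWARD, score=None, provenance="stage1",
         contig="c1"):
    return GeneModel(gid, contig, strand, [(s, e, 0) for s, e in segs],
                     provenance=provenance, score=score)


class TestFilterShort:
    def test_29_aa_gene_removed(self):
        # 29 aa + stop = 90 nt
        assert filter_short([gene("a", [(1, 90)])]) == []

    def test_30_aa_gene_kept(self):
        # 30 aa + stop = 93 nt: "less than 30 amino acids" is removed,
        # exactly 30 survives
        out = filter_short([gene("a", [(1, 93)])])
        assert len(out) == 1

    def test_empty_input(self):
        assert filter_short([]) == []


class TestFilterVariants:
    def test_duplicate_variant_without_unique_material_removed(self):
        a = gene("a", [(1, 600)], score=10.0)
        b = gene("b", [(16, 600)], score=5.0)   # wholly inside a, same introns
        out = filter_variants([a, b])
        assert [g.gene_id for g in out] == ["a"]

    def test_variant_with_unique_intron_kept(self):
        a = gene("a", [(1, 600)], score=10.0)
        b = gene("b", [(1, 300), (351, 650)], score=5.0)
        out = filter_variants([a, b])
        assert {g.gene_id for g in out} == {"a", "b"}

    def test_ten_unique_amino_acids_boundary(self):
        a = gene("a", [(1, 600)], score=10.0)
        kept = gene("b", [(1, 630)], score=5.0)      # 30 nt = 10 aa outside
        out = filter_variants([a, kept])
        assert {g.gene_id for g in out} == {"a", "b"}
        dropped = gene("c", [(1, 627)], score=5.0)   # 27 nt = 9 aa outside
        out = filter_variants([a, dropped])
        assert {g.gene_id for g in out} == {"a"}

    def test_single_variant_locus_kept_unconditionally(self):
        a = gene("a", [(1, 120)], score=-50.0)
        assert filter_variants([a]) == [a]

    def test_idempotent(self):
        genes = [
            gene("a", [(1, 600)], score=10.0),
            gene("b", [(16, 600)], score=5.0),
            gene("c", [(1000, 1500)], score=3.0),
        ]
        once = filter_variants(genes)
        assert filter_variants(once) == once


class TestFilterNested:
    def test_fully_nested_antisense_gene_removed(self):
        big = gene("big", [(1, 1000)], strand=FORWARD)
        small = gene("small", [(200, 500)], strand=REVERSE)
        out = filter_nested([big, small])
        assert [g.gene_id for g in out] == ["big"]

    def test_quarter_outside_kept(self):
        big = gene("big", [(1, 1000)], strand=FORWARD)
        # 400 nt CDS, 100 nt beyond the big gene's end: 25% outside
        small = gene("small", [(701, 1100)], strand=REVERSE)
        out = filter_nested([big, small])
        assert {g.gene_id for g in out} == {"big", "small"}

    def test_exactly_twenty_percent_outside_kept(self):
        big = gene("big", [(1, 1000)], strand=FORWARD)
        small = gene("small", [(681, 1080)], strand=REVERSE)  # 80/400 = 20%
        assert {g.gene_id for g in filter_nested([big, small])} == {
            "big", "small"}

    def test_just_under_twenty_percent_removed(self):
        big = gene("big", [(1, 1000)], strand=FORWARD)
        small = gene("small", [(680, 1079)], strand=REVERSE)  # 79/400
        assert [g.gene_id for g in filter_nested([big, small])] == ["big"]

    def test_equal_length_pair_both_kept(self):
        a = gene("a", [(1, 300)], strand=FORWARD)
        b = gene("b", [(100, 399)], strand=REVERSE)
        assert len(filter_nested([a, b])) == 2

    def test_same_strand_overlap_untouched(self):
        a = gene("a", [(1, 900)], strand=FORWARD)
        b = gene("b", [(200, 500)], strand=FORWARD)
        assert len(filter_nested([a, b])) == 2

    def test_idempotent(self):
        genes = [gene("big", [(1, 1000)], strand=FORWARD),
                 gene("small", [(200, 500)], strand=REVERSE),
                 gene("far", [(2000, 2400)], strand=REVERSE)]
        once = filter_nested(genes)
        assert filter_nested(once) == once


class TestCombine:
    def test_disjoint_sets_concatenated_in_order(self):
        s1 = [gene("x", [(1000, 1600)], provenance="stage1")]
        s2 = [gene("y", [(1, 600)], provenance="stage2")]
        out = combine(s1, s2)
        assert [g.provenance for g in out] == ["stage2", "stage1"]
        assert [g.gene_id for g in out] == ["gene_0001", "gene_0002"]

    def test_same_strand_overlap_prefers_stage1(self):
        s1 = [gene("x", [(1, 600)], provenance="stage1")]
        s2 = [gene("y", [(100, 700)], provenance="stage2")]
        out = combine(s1, s2)
        assert len(out) == 1 and out[0].provenance == "stage1"

    def test_opposite_strand_overlap_both_retained(self):
        s1 = [gene("x", [(1, 600)], strand=FORWARD, provenance="stage1")]
        s2 = [gene("y", [(100, 700)], strand=REVERSE, provenance="stage2")]
        assert len(combine(s1, s2)) == 2


class TestFilterChainProperties:
    def test_chain_is_non_increasing_and_ordered(self):
        genes = [
            gene("a", [(1, 600)], score=10.0),
            gene("b", [(16, 600)], score=5.0),
            gene("tiny", [(700, 760)]),                      # < 30 aa
            gene("nested", [(100, 400)], strand=REVERSE),
        ]
        out = apply_filters(genes)
        assert len(out) <= len(genes)
        assert [g.gene_id for g in out] == ["a"]


class TestFusions:
    def test_two_same_strand_genes_in_one_transcript(self):
        genes = [gene("a", [(10, 100)]), gene("b", [(200, 300)])]
        t = TranscriptAlignment("t1", "c1", FORWARD, [(1, 350)])
        rep = report_fusions(genes, [t])
        assert len(rep.rows) == 1
        row = rep.rows[0]
        assert (row.transcript_id, row.n_constituents, row.strand_pattern) == (
            "t1", 2, "++")

    def test_antisense_pair_pattern(self):
        genes = [gene("a", [(10, 100)], strand=FORWARD),
                 gene("b", [(200, 300)], strand=REVERSE)]
        t = TranscriptAlignment("t1", "c1", ".", [(1, 350)])
        rep = report_fusions(genes, [t])
        assert rep.rows[0].strand_pattern == "+-"

    def test_single_gene_transcript_absent(self):
        genes = [gene("a", [(10, 100)])]
        t = TranscriptAlignment("t1", "c1", FORWARD, [(1, 350)])
        assert report_fusions(genes, [t]).rows == []

    def test_transcript_overlapping_utr_only_not_counted(self):
        # gene CDS outside the transcript span: no constituent
        genes = [gene("a", [(400, 500)]), gene("b", [(600, 700)])]
        t = TranscriptAlignment("t1", "c1", FORWARD, [(1, 350)])
        assert report_fusions(genes, [t]).rows == []


class TestDubious:
    def test_dubious_genes_never_in_main_annotation(self, mixed_run):
        main = {g.segments_key() for g in mixed_run.final_genes}
        for g in mixed_run.dubious.genes:
            assert g.provenance == "dubious"
            assert g.segments_key() not in main

    def test_dubious_only_from_uncovered_transcripts(self, mixed_run,
                                                     mixed_truth):
        spans = [(g.contig, g.start, g.end) for g in mixed_run.final_genes]
        by_tid = {t.transcript_id: t for t in mixed_truth.transcripts}
        for g in mixed_run.dubious.genes:
            t = by_tid[g.transcript_id]
            assert not any(
                c == t.contig and s <= t.end and e >= t.start
                for c, s, e in spans
            )

    def test_forced_prediction_in_uncovered_transcript(self, cfg):
        """A transcript with only a weak short ORF still gets a forced
        gene once the noncoding transition is zeroed."""
        import numpy as np
        from mycogene.stage1 import (predict_stage1, seed_training_set,
                                     spec_without_noncoding, train_stage1)
        from mycogene.synthetic import SENSE_CODONS
        from mycogene.transcript_space import SplicedTranscript

        rng = np.random.default_rng(5)

        def mk(seq, tid):
            return SplicedTranscript(tid, "c", seq, FORWARD,
                                     [(1, len(seq))])

        def orf(n):
            body = "".join(SENSE_CODONS[i]
                           for i in rng.integers(0, 61, (n - 6) // 3))
            return "ATG" + body + "TAA"

        junk = ("CT" * 300)[:400]
        training = [mk(("CT" * 20)[:30] + orf(660 + 3 * i)
                       + ("CT" * 25)[:40], f"t{i}") for i in range(8)]
        model = train_stage1(seed_training_set(training, cfg), cfg)
        weak = mk(junk[:150] + orf(123) + junk[:150], "weak")
        free = predict_stage1(model, [weak], cfg)
        forced = predict_stage1(model, [weak], cfg, provenance="dubious",
                                spec=spec_without_noncoding(model))
        # without forcing the noncoding parse may win; with forcing a
        # kozak->cds->stop run must be emitted
        assert len(forced.genes) >= 1
        assert all(g.provenance == "dubious" for g in forced.genes)
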