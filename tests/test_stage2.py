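import math

import numpy as np
import pytest
from scipy import stats

from mycogene.config import RunConfig
from mycogene.dna import revcomp
from mycogene.formats_io import FORWARD, REVERSE, Genome, TranscriptAlignment
from mycogene.stage2 import (ConstraintTrack, EvidencedIntron,
                             build_constraints, collect_evidenced_introns,
                             fit_boundary_lengths, max_intron_length,
                             select_regions)
from mycogene.synthetic import SynthParams, generate

RNG = np.random.default_rng(77)


def synth_introns(n, length_range=(60, 140), donor_sig=4, acceptor_sig=4,
                  rng=None):
    """Introns with GT + ``donor_sig`` consensus positions, an i.i.d.
    AT-rich interior, and ``acceptor_sig`` consensus positions + AG."""
    rng = rng or np.random.default_rng(77)
    probs = np.array([0.35, 0.15, 0.15, 0.35])
    out = []
    donor_cons = "AAGTGG"[:donor_sig]
    acc_cons = "TTTACC"[:acceptor_sig]
    for i in range(n):
        total = int(rng.integers(*length_range))
        interior = "".join(
            "ACGT"[j] for j in rng.choice(4, size=total - 4 - donor_sig
                                          - acceptor_sig, p=probs))
        seq = "GT" + donor_cons + interior + acc_cons + "AG"
        out.append(EvidencedIntron("c", 1, len(seq), FORWARD, seq, "CA", "GG"))
    return out


class TestBoundaryFit:
    def test_planted_donor_signal_recovered(self, cfg):
        introns = synth_introns(300, donor_sig=4, acceptor_sig=4)
        donor, acceptor = fit_boundary_lengths(introns, cfg)
        # GT + 4 consensus positions + 2 exon nt = 8
        assert donor == 8
        assert acceptor == 8

    def test_null_composition_gives_minimal_length(self, cfg):
        introns = synth_introns(300, donor_sig=0, acceptor_sig=0)
        donor, acceptor = fit_boundary_lengths(introns, cfg)
        # only the invariant GT/AG differ from the interior: 2 + 2 exon nt
        assert donor == 4
        assert acceptor == 4

    def test_signal_beyond_cap_clamped_to_22(self, cfg):
        rng = np.random.default_rng(5)
        introns = []
        for _ in range(200):
            # 30 fixed consensus positions from the donor end
            seq = ("GT" + "A" * 28
                   + "".join("ACGT"[j] for j in rng.choice(
                       4, size=60, p=[0.25] * 4))
                   + "AG")
            introns.append(EvidencedIntron("c", 1, len(seq), FORWARD, seq,
                                           "CA", "GG"))
        donor, _ = fit_boundary_lengths(introns, cfg)
        assert donor == cfg.donor_max == 22

    def test_too_few_introns_falls_back_to_defaults(self, cfg):
        introns = synth_introns(cfg.min_introns_for_fit - 1)
        assert fit_boundary_lengths(introns, cfg) == (
            cfg.default_donor_len, cfg.default_acceptor_len)
        assert fit_boundary_lengths(synth_introns(cfg.min_introns_for_fit),
                                    cfg) != (0, 0)

    def test_chi_square_critical_value(self, cfg):
        # df=3 at p=0.01, the threshold the boundary fit applies
        assert stats.chi2.isf(cfg.chi2_p, df=3) == pytest.approx(
            11.345, abs=1e-3)


class TestMaxIntron:
    def test_ten_percent_longer_than_longest(self, cfg):
        assert max_intron_length([400, 1000], cfg) == 1100

    def test_capped_at_5000(self, cfg):
        assert max_intron_length([4800], cfg) == 5000

    def test_cap_disabled_by_flag(self, cfg):
        free = cfg.replace(disable_intron_cap=True)
        assert max_intron_length([4800], free) == 5280

    def test_no_introns_uses_default(self, cfg):
        assert max_intron_length([], cfg) == cfg.default_max_intron


class TestConstraints:
    @pytest.fixture()
    def track(self, cfg):
        genome = Genome({"c": "A" * 600})
        t = TranscriptAlignment("t1", "c", FORWARD, [(100, 400)])
        return build_constraints([t], genome, stranded=True, cfg=cfg)

    def test_mid_transcript_forbidden(self, track):
        assert not track.boundary_allowed("c", FORWARD, 250)

    def test_relaxed_within_50_of_transcript_end(self, track):
        # 100 + 50 = 150 is the first forbidden position
        assert track.boundary_allowed("c", FORWARD, 149)
        assert not track.boundary_allowed("c", FORWARD, 150)
        assert not track.boundary_allowed("c", FORWARD, 350)
        assert track.boundary_allowed("c", FORWARD, 351)

    def test_position_30_nt_from_end_allowed(self, track):
        assert track.boundary_allowed("c", FORWARD, 380)

    def test_position_51_nt_from_end_forbidden(self, track):
        assert not track.boundary_allowed("c", FORWARD, 349)

    def test_opposite_strand_unconstrained_when_stranded(self, track):
        assert track.boundary_allowed("c", REVERSE, 250)

    def test_unstranded_coverage_constrains_both_strands(self, cfg):
        genome = Genome({"c": "A" * 600})
        t = TranscriptAlignment("t1", "c", ".", [(100, 400)])
        track = build_constraints([t], genome, stranded=False, cfg=cfg)
        assert not track.boundary_allowed("c", FORWARD, 250)
        assert not track.boundary_allowed("c", REVERSE, 250)

    def test_alignment_gaps_are_not_coverage(self, cfg):
        genome = Genome({"c": "A" * 900})
        t = TranscriptAlignment("t1", "c", FORWARD, [(100, 400), (500, 800)])
        track = build_constraints([t], genome, stranded=True, cfg=cfg)
        # inside the evidenced intron boundaries may be placed
        assert track.boundary_allowed("c", FORWARD, 450)
        assert not track.boundary_allowed("c", FORWARD, 300)


class TestRegionSelection:
    def test_all_single_exon_stage1_genes_discarded(self, clean_run):
        reasons = {id(g): r for g, r in clean_run.selection.discarded}
        for g in clean_run.stage1_genes:
            if len(g.cds_segments) == 1:
                assert reasons.get(id(g)) is not None
        for g in clean_run.selection.kept:
            assert len(g.cds_segments) > 1

    def test_discarded_loci_covered_by_windows(self, clean_run):
        for g, _reason in clean_run.selection.discarded:
            assert any(
                c == g.contig and ws <= g.start and we >= g.end
                for c, ws, we in clean_run.selection.windows
            ), f"discarded locus {g.gene_id} not re-predicted"

    def test_truncated_transcripts_flagged_suspected_incomplete(self):
        p = SynthParams(seed=4, n_genes=50, frac_expressed=1.0,
                        frac_truncated5=0.3, frac_merged_same=0,
                        frac_merged_sas=0)
        truth = generate(p)
        from mycogene.stage1 import self_train
        cfg = RunConfig(seed=4, verbosity=0)
        _model, res, _ = self_train(truth.genome, truth.transcripts, cfg)
        sel = select_regions(res, truth.genome, cfg)
        trunc_tids = {t.transcript_id for t in truth.transcripts
                      if truth.labels[t.transcript_id] == "truncated5"}
        flagged = {g.transcript_id for g, r in sel.discarded
                   if r == "suspected_incomplete"}
        assert flagged & trunc_tids

    def test_false_positive_intron_yields_alt_splice_window(self):
        p = SynthParams(seed=4, n_genes=40, frac_expressed=1.0,
                        frac_truncated5=0, frac_merged_same=0,
                        frac_merged_sas=0, frac_fp_intron=0.4)
        truth = generate(p)
        from mycogene.stage1 import self_train
        cfg = RunConfig(seed=4, verbosity=0)
        _model, res, _ = self_train(truth.genome, truth.transcripts, cfg)
        sel = select_regions(res, truth.genome, cfg)
        assert sel.alt_windows


class TestStage2Predictions:
    def test_predicted_introns_canonical_and_bounded(
            self, clean_run, clean_truth, cfg):
        spliced = [st for st, _ in clean_run.stage1_result.parses.values()]
        evid = collect_evidenced_introns(clean_truth.genome, spliced)
        cap = max_intron_length([i.length for i in evid], cfg)
        checked = 0
        for g in clean_run.stage2_genes:
            for s, e in g.introns:
                seq = clean_truth.genome.fetch(g.contig, s, e)
                if g.strand == REVERSE:
                    seq = revcomp(seq)
                assert seq.startswith("GT") and seq.endswith("AG")
                assert cfg.min_intron <= e - s + 1 <= cap
                checked += 1
        assert checked > 0

    def test_no_boundary_violates_constraint_track(
            self, clean_run, clean_truth, cfg):
        track = build_constraints(clean_truth.transcripts,
                                  clean_truth.genome, True, cfg)
        for g in clean_run.stage2_genes:
            for s, e in g.introns:
                assert track.boundary_allowed(g.contig, g.strand, s)
                assert track.boundary_allowed(g.contig, g.strand, e)

    def test_unexpressed_genes_recovered_ab_initio(self, mixed_run,
                                                   mixed_truth):
        unexpr = [g for g in mixed_truth.genes
                  if mixed_truth.labels[g.gene_id] == "unexpressed"]
        pred = {g.segments_key(): g for g in mixed_run.final_genes}
        recovered = [pred[g.segments_key()] for g in unexpr
                     if g.segments_key() in pred]
        assert recovered, "no unexpressed gene recovered ab initio"
        assert all(g.provenance == "stage2" for g in recovered)

    def test_stage2_genes_translate_cleanly(self, clean_run, clean_truth):
        from mycogene.dna import STOP_CODONS, translate_has_internal_stop
        for g in clean_run.stage2_genes:
            cds = g.spliced_cds(clean_truth.genome)
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            assert not translate_has_internal_stop(cds)
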