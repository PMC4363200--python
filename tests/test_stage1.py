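import numpy as np
import pytest

from mycogene.config import RunConfig
from mycogene.dna import STOP_CODONS
from mycogene.errors import TrainingError
from mycogene.formats_io import FORWARD
from mycogene.ghmm import score_wam
from mycogene.stage1 import (STATE_CDS, STATE_KOZAK, STATE_MID,
                             STATE_NONCODING, Stage1Model,
                             seed_training_set, spec_without_noncoding,
                             train_stage1)
from mycogene.synthetic import SENSE_CODONS
from mycogene.transcript_space import SplicedTranscript

RNG = np.random.default_rng(123)


def junk(n):
    """ATG-free filler (no ORFs can start inside it)."""
    return ("CT" * (n // 2 + 1))[:n]


def codons(n, rng=RNG):
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))


def orf(n_nt, rng=RNG):
    assert n_nt % 3 == 0
    return "ATG" + codons((n_nt - 6) // 3, rng) + "TAA"


def make_st(seq, tid="t1", start=1):
    return SplicedTranscript(tid, "c", seq, FORWARD,
                             [(start, start + len(seq) - 1)])


class TestSeedTrainingSet:
    def test_long_orf_becomes_cds_example_with_utr_flanks(self, cfg):
        st = make_st(junk(30) + orf(702) + junk(30))
        ts = seed_training_set([st], cfg)
        assert len(ts.cds_bodies) == 1
        assert len(ts.cds_bodies[0]) == 702 - 6
        assert ts.utr5_lengths == [30] and ts.utr3_lengths == [30]
        assert len(ts.kozak_windows) == 1
        assert ts.kozak_windows[0].endswith("ATG")
        assert len(ts.kozak_windows[0]) == cfg.kozak_window

    def test_600_nt_floor_inclusive(self, cfg):
        keep = make_st(junk(30) + orf(600) + junk(30), "keep")
        drop = make_st(junk(30) + orf(597) + junk(30), "drop")
        ts = seed_training_set([keep, drop], cfg)
        assert len(ts.cds_bodies) == 1
        assert len(ts.cds_bodies[0]) == 600 - 6

    def test_450_nt_orf_excluded_from_training(self, cfg):
        big = make_st(junk(30) + orf(702) + junk(30), "big")
        small = make_st(junk(30) + orf(450) + junk(30), "small")
        ts = seed_training_set([big, small], cfg)
        assert len(ts.cds_bodies) == 1

    def test_utr_orf_300_excised_297_kept(self, cfg):
        for utr_orf_len, expect_excised in [(300, True), (297, False)]:
            utr_orf = "ATG" + "GGC" * ((utr_orf_len - 6) // 3) + "TAA"
            utr5 = junk(40) + utr_orf + junk(40)
            st = make_st(utr5 + orf(702) + junk(30))
            ts = seed_training_set([st], cfg)
            total_utr5 = sum(len(x) for x in ts.utr5_examples)
            if expect_excised:
                assert total_utr5 == len(utr5) - utr_orf_len
            else:
                assert total_utr5 == len(utr5)

    def test_overlapping_genes_keep_longer(self, cfg):
        # two transcripts whose ORFs lift to overlapping genomic spans
        long_t = make_st(junk(30) + orf(900) + junk(30), "long", start=1)
        short_t = make_st(junk(12) + orf(600) + junk(12), "short", start=500)
        ts = seed_training_set([long_t, short_t], cfg)
        assert len(ts.cds_bodies) == 1
        assert len(ts.cds_bodies[0]) == 900 - 6

    def test_orfless_transcript_is_noncoding_example(self, cfg):
        coding = make_st(junk(30) + orf(702) + junk(30), "c1")
        nc = make_st(junk(400), "nc")
        ts = seed_training_set([coding, nc], cfg)
        assert ts.n_noncoding == 1
        assert len(ts.noncoding_examples) == 1

    def test_no_candidates_raises_training_error(self, cfg):
        with pytest.raises(TrainingError):
            seed_training_set([make_st(junk(300))], cfg)


class TestTrainStage1:
    def _model(self, cfg, n=12):
        rng = np.random.default_rng(0)
        sts = [
            make_st(junk(30) + orf(630 + 3 * int(rng.integers(0, 80)), rng)
                    + junk(40), f"t{i}")
            for i in range(n)
        ]
        ts = seed_training_set(sts, cfg)
        return ts, train_stage1(ts, cfg)

    def test_consensus_kozak_window_scores_highest(self, cfg):
        sts = [make_st("A" * 30 + orf(702) + junk(30), f"t{i}")
               for i in range(5)]
        ts = seed_training_set(sts, cfg)
        model = train_stage1(ts, cfg)
        good = score_wam(model.kozak, "AAAAAAAAATG")
        bad = score_wam(model.kozak, "CCCCCCCCATG")
        assert good > bad

    def test_cds_duration_support_spans_observed_lengths(self, cfg):
        ts, model = self._model(cfg)
        dur = model.durations[STATE_CDS]
        assert dur.support_min <= min(ts.cds_lengths)
        assert dur.support_max >= max(ts.cds_lengths)
        assert dur.modulus == 3

    def test_shared_utr_table_by_default(self, cfg):
        _, model = self._model(cfg)
        assert model.utr3_chain is model.utr_chain

    def test_state_set_and_fixed_lengths(self, cfg):
        _, model = self._model(cfg)
        names = {st.name for st in model.spec.states}
        assert names == {"utr5", "kozak", "cds", "stop", "utr3",
                         "mid_utr", "noncoding"}
        kozak = next(s for s in model.spec.states if s.name == STATE_KOZAK)
        assert kozak.duration.fixed_length == 11
        stop = next(s for s in model.spec.states if s.name == "stop")
        assert stop.duration.fixed_length == 3

    def test_noncoding_removal_renormalises_begin(self, cfg):
        _, model = self._model(cfg)
        spec = spec_without_noncoding(model)
        assert STATE_NONCODING not in spec.begin
        assert sum(spec.begin.values()) == pytest.approx(1.0)


class TestPredictStage1:
    def test_stage1_genes_are_valid_cds(self, clean_run, clean_truth):
        for g in clean_run.stage1_genes:
            cds = g.spliced_cds(clean_truth.genome)
            assert cds.startswith("ATG")
            assert cds[-3:] in STOP_CODONS
            assert len(cds) % 3 == 0

    def test_gene_count_equals_one_plus_middle_utr_segments(self, clean_run):
        for tid, (st, path) in clean_run.stage1_result.parses.items():
            states = [s for s, _, _ in path.segments]
            n_genes = states.count(STATE_KOZAK)
            n_mid = states.count(STATE_MID)
            if n_genes:
                assert n_genes == 1 + n_mid

    def test_multi_exon_genes_use_evidenced_introns_exactly(
            self, clean_run, clean_truth):
        """Stage-1 intron boundaries must agree exactly with the
        transcript-to-genome alignment."""
        checked = 0
        for g in clean_run.stage1_genes:
            if len(g.cds_segments) < 2 or not g.transcript_id:
                continue
            st, _ = clean_run.stage1_result.parses[g.transcript_id]
            evid = set(st.evidenced_introns)
            for intron in g.introns:
                assert intron in evid
                checked += 1
        assert checked > 10

    def test_self_training_runs_exactly_two_retrain_iterations(
            self, clean_run, cfg):
        labels = [h.split(":")[0] for h in clean_run.history
                  if h.startswith(("seed", "iteration"))]
        assert labels == ["seed", "iteration 1", "iteration 2"]

    def test_training_set_sizes_logged_per_iteration(self, clean_run):
        for line in clean_run.history:
            if line.startswith(("seed", "iteration")):
                assert "CDS" in line and "Kozak" in line


class TestNoncodingCompetition:
    def test_orf_free_transcript_parses_as_noncoding(self, cfg):
        rng = np.random.default_rng(3)
        training = [
            make_st(junk(30) + orf(630 + 3 * int(rng.integers(0, 60)), rng)
                    + junk(40), f"t{i}")
            for i in range(10)
        ]
        model = train_stage1(seed_training_set(training, cfg), cfg)
        from mycogene.stage1 import predict_stage1
        nc = make_st(junk(500), "nc")
        res = predict_stage1(model, [nc], cfg)
        assert res.genes == []
        assert res.parses["nc"][1].states() == [STATE_NONCODING]
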