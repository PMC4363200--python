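import math

import numpy as np
import pytest

from mycogene.dna import encode
from mycogene.errors import ConfigError
from mycogene.ghmm import (DurationModel, GhmmSpec, LiteralMotifSet,
                           MarkovChainModel, OracleSizeError, State,
                           ViterbiConstraints, WeightedArrayMatrix,
                           enumerate_all_parses, fixed_duration,
                           score_markov, score_wam, smooth_durations,
                           train_markov, train_wam, viterbi)

from _toyghmm import random_instance


class TestMarkovTraining:
    def test_order0_plain_frequencies(self):
        m = train_markov([("AAAC", 0)], order=0, pseudocount=0.0)
        p = np.exp(m._logp[0][0, 0])
        assert p[0] == pytest.approx(0.75)
        assert p[1] == pytest.approx(0.25)

    def test_order0_pseudocount_closed_form(self):
        m = train_markov([("AAAC", 0)], order=0, pseudocount=1.0)
        p = np.exp(m._logp[0][0, 0])
        assert p[0] == pytest.approx((3 + 1) / (4 + 4))

    def test_order1_periodic_counts_land_in_phase_tables(self):
        # hand-tally "ACGTACGTA" with phase offset 0: the base at index i
        # goes to table i % 3 conditioned on the preceding base
        seq = "ACGTACGTA"
        m = train_markov([(seq, 0)], order=1, periodicity=3, pseudocount=0.0)
        enc = encode(seq)
        counts = np.zeros((3, 4, 4))
        for i in range(1, len(seq)):
            counts[i % 3, enc[i - 1], enc[i]] += 1
        assert np.allclose(m.counts, counts)

    def test_order_reduction_quota(self):
        # 12 events cannot support an order-2 table at quota 50
        m = train_markov([("ACGTACGTACGTA", 0)], order=2, pseudocount=0.01,
                         order_quota=50)
        assert m.order == 0

    def test_n_contexts_excluded_from_counting(self):
        m = train_markov([("ANAC", 0)], order=1, pseudocount=0.0)
        assert m.counts.sum() == 1  # only the A->C event has a valid context


class TestMarkovScoring:
    def test_order0_score(self):
        m = train_markov([("AAAC", 0)], order=0, pseudocount=0.0)
        assert score_markov(m, "AA") == pytest.approx(2 * math.log(0.75))

    def test_empty_sequence_scores_zero(self):
        m = train_markov([("AAAC", 0)], order=0, pseudocount=0.0)
        assert score_markov(m, "") == 0.0

    def test_concatenation_additive_with_carried_context(self):
        m = train_markov([("ACGTTGCAACGT", 0)], order=2, pseudocount=0.5)
        s = "ACGTGCA"
        whole = score_markov(m, s)
        left, right = s[:3], s[3:]
        assert score_markov(m, left) + score_markov(
            m, right, prior_context=left) == pytest.approx(whole)

    def test_position_logprobs_match_scalar(self):
        rng = np.random.default_rng(0)
        m = MarkovChainModel(2, 3, rng.random((3, 16, 4)) * 9, 0.3)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        enc = encode(seq)
        total = sum(
            m.position_logprobs(enc, 2, c)[i]
            for i, c in ((i, i % 3) for i in range(2, 30))
        )
        scalar = m.score_segment(enc, 0, 29, 0)
        # the first two positions use backoff orders 0 and 1
        total += m.position_logprobs(enc, 0, 0)[0]
        total += m.position_logprobs(enc, 1, 1)[1]
        assert total == pytest.approx(scalar)


class TestWam:
    def test_own_window_is_argmax(self):
        wam = train_wam(["ATG"], order=0, pseudocount=0.01)
        scores = {
            w: score_wam(wam, w)
            for w in ("ATG", "TTG", "AAG", "ATA", "CCC")
        }
        assert max(scores, key=scores.get) == "ATG"

    def test_order1_tables_match_hand_tally(self):
        windows = ["AAT", "AAT", "ACT", "GCT"]
        wam = train_wam(windows, order=1, pseudocount=0.0)
        # position 1 conditioned on position 0: after A, C appears 1/3
        p = np.exp(wam._logp[1])
        assert p[0, 1] == pytest.approx(1 / 3)      # A -> C
        assert p[0, 0] == pytest.approx(2 / 3)      # A -> A
        assert p[2, 1] == pytest.approx(1.0)        # G -> C

    def test_ragged_windows_rejected(self):
        with pytest.raises(ConfigError):
            train_wam(["ATG", "AT"], order=0)

    def test_vectorised_window_scores_match_scalar(self):
        rng = np.random.default_rng(1)
        windows = ["".join(rng.choice(list("ACGT"), size=5)) for _ in range(8)]
        wam = train_wam(windows, order=1, pseudocount=0.1)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        arr = wam.windows_ending_logprobs(encode(seq))
        for t in range(5, 41):
            assert arr[t] == pytest.approx(wam.score(seq[t - 5 : t]))


class TestDurations:
    def test_point_mass_without_smoothing(self):
        dm = smooth_durations([300] * 10, bandwidth=0)
        assert math.exp(dm.log_prob(300)) > 0.99
        assert dm.log_prob(299) < dm.log_prob(300) - 5

    def test_triangular_spread_sums_to_one(self):
        dm = smooth_durations([300] * 10, bandwidth=2)
        mass = sum(math.exp(dm.log_prob(d)) for d in range(296, 305))
        assert mass == pytest.approx(1.0, abs=5e-3)
        # outside the smoothed support only the small geometric tail remains
        assert math.exp(dm.log_prob(303)) < 1e-3

    def test_unobserved_length_inside_support_positive(self):
        dm = smooth_durations([100, 104], bandwidth=2)
        assert np.isfinite(dm.log_prob(102))

    def test_modulus_restriction(self):
        dm = smooth_durations([300, 303, 306], bandwidth=2, modulus=3,
                              residue=0)
        assert dm.log_prob(301) == -np.inf
        assert np.isfinite(dm.log_prob(303))

    def test_geometric_tails_monotone(self):
        dm = smooth_durations([50, 60], bandwidth=1)
        assert dm.log_prob(100) > dm.log_prob(150)
        assert dm.log_prob(10) > dm.log_prob(5)


def _uniform_state(name, length_lo, length_hi, rng):
    em = MarkovChainModel(0, 1, np.ones((1, 1, 4)), 1.0)
    lens = list(range(length_lo, length_hi + 1))
    dur = smooth_durations(lens * 5, bandwidth=0, tail_mass=0.0)
    return State(name, em, dur)


class TestViterbi:
    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            spec, seq = random_instance(rng, max_states=3)
            vp = viterbi(spec, seq, force_python=True)
            op = enumerate_all_parses(spec, seq)
            assert (vp is None) == (op is None)
            if vp is None:
                continue
            assert vp.log_prob == pytest.approx(op.log_prob, abs=1e-9)
            assert vp.segments == op.segments

    def test_fast_path_matches_reference_decoder(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            spec, _ = random_instance(rng)
            seq = "".join(rng.choice(list("ACGT"), size=200))
            pf = viterbi(spec, seq)
            pp = viterbi(spec, seq, force_python=True)
            assert (pf is None) == (pp is None)
            if pf is None:
                continue
            assert pf.log_prob == pytest.approx(pp.log_prob, abs=1e-9)
            assert pf.segments == pp.segments

    def test_constraint_never_improves_score(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            spec, seq = random_instance(rng)
            free = viterbi(spec, seq)
            if free is None:
                continue
            cons = ViterbiConstraints(len(seq))
            name = spec.states[int(rng.integers(len(spec.states)))].name
            p = int(rng.integers(1, len(seq) + 1))
            cons.forbid_occupancy(name, p, p)
            constrained = viterbi(spec, seq, cons)
            if constrained is not None:
                assert constrained.log_prob <= free.log_prob + 1e-9

    def test_all_states_forbidden_gives_no_parse(self):
        rng = np.random.default_rng(3)
        spec, seq = random_instance(rng)
        cons = ViterbiConstraints(len(seq))
        for st in spec.states:
            cons.forbid_occupancy(st.name, 2, 2)
        assert viterbi(spec, seq, cons) is None
        assert enumerate_all_parses(spec, seq, cons) is None

    def test_durations_dictate_path_under_uniform_emissions(self):
        # two states with point-mass durations 4 and 6 on a 10-nt
        # sequence: the only admissible parses alternate them
        rng = np.random.default_rng(0)
        em = MarkovChainModel(0, 1, np.ones((1, 1, 4)), 1.0)
        s4 = State("four", em, smooth_durations([4] * 5, bandwidth=0,
                                                tail_mass=0.0))
        s6 = State("six", em, smooth_durations([6] * 5, bandwidth=0,
                                               tail_mass=0.0))
        spec = GhmmSpec(
            [s4, s6],
            {("four", "six"): 0.5, ("six", "four"): 0.5},
            {"four": 0.5, "six": 0.5},
            {"four": 0.5, "six": 0.5},
        )
        path = viterbi(spec, "ACGTACGTAC")
        assert [(n, e - s + 1) for n, s, e in path.segments] in (
            [("four", 4), ("six", 6)], [("six", 6), ("four", 4)]
        )

    def test_empty_sequence_empty_path(self):
        rng = np.random.default_rng(0)
        spec, _ = random_instance(rng)
        path = viterbi(spec, "")
        assert path.segments == [] and path.log_prob == 0.0

    def test_long_sequence_scores_stay_finite(self):
        # no underflow in log space on a long decode (bounded durations
        # keep the run linear; non-uniform emissions avoid mass ties)
        rng = np.random.default_rng(9)
        # order-2 emissions: the context reset at segment starts makes
        # scores boundary-dependent, so parses do not tie en masse
        em = MarkovChainModel(2, 1, rng.random((1, 16, 4)) * 20, 0.5)
        dur = smooth_durations(list(range(50, 200)), bandwidth=2,
                               tail_mass=0.0)
        spec = GhmmSpec([State("s", em, dur)], {("s", "s"): 0.9},
                        {"s": 1.0}, {"s": 0.1})
        seq = "ACGT" * 5_000
        path = viterbi(spec, seq)
        assert path is not None and np.isfinite(path.log_prob)
        assert path.segments[-1][2] == len(seq)

    def test_oracle_refuses_oversized_instances(self):
        rng = np.random.default_rng(0)
        spec, _ = random_instance(rng)
        with pytest.raises(OracleSizeError):
            enumerate_all_parses(spec, "A" * 31)


class TestSpecValidation:
    def test_transition_sum_checked(self):
        em = MarkovChainModel(0, 1, np.ones((1, 1, 4)), 1.0)
        dur = fixed_duration(3)
        spec = GhmmSpec([State("a", em, dur)], {("a", "a"): 0.5},
                        {"a": 1.0}, {"a": 0.2})
        with pytest.raises(ConfigError):
            spec.validate()

    def test_wam_requires_matching_fixed_length(self):
        wam = train_wam(["ATG"], order=0)
        dur = fixed_duration(4)
        spec = GhmmSpec([State("w", wam, dur)], {}, {"w": 1.0}, {"w": 1.0})
        with pytest.raises(ConfigError):
            spec.validate()

    def test_model_dump_is_text(self, tmp_path):
        rng = np.random.default_rng(0)
        spec, _ = random_instance(rng)
        out = tmp_path / "model.txt"
        spec.dump(out)
        text = out.read_text()
        assert "## states" in text and "## transitions" in text


class TestTrainScoreConsistency:
    def test_order0_mle_is_locally_optimal(self):
        """The training sequence's own score under the fitted order-0
        table is at least its score under any perturbed table."""
        seq = "AAACCGTTTTAACGA"
        m = train_markov([(seq, 0)], order=0, pseudocount=0.0)
        base = score_markov(m, seq)
        p = np.exp(m._logp[0][0, 0]).copy()
        rng = np.random.default_rng(0)
        for _ in range(20):
            q = p + rng.normal(0, 0.05, size=4)
            q = np.clip(q, 1e-6, None)
            q /= q.sum()
            perturbed = float(sum(
                np.log(q["ACGT".find(b)]) for b in seq
            ))
            assert perturbed <= base + 1e-9
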