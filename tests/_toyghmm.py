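"""Random small GHMM instances shared by the decoder tests and the
decoder/oracle acceptance check."""

from __future__ import annotations

import numpy as np

from mycogene.ghmm import GhmmSpec, MarkovChainModel, State, smooth_durations


def random_instance(rng: np.random.Generator, max_states: int = 4,
                    max_len: int = 14):
    """A random spec + sequence small enough for exhaustive enumeration.

    Duration supports are kept narrow (no geometric tails) so the number
    of admissible segmentations stays enumerable."""
    S = int(rng.integers(2, max_states + 1))
    if S >= 4:
        max_len = min(max_len, 10)   # keep the enumeration tractable
    L = int(rng.integers(4, max_len + 1))
    # minimum duration scales with L so the segment count stays small
    lo_base = max(2, L // 6)
    states = []
    for i in range(S):
        order = int(rng.integers(0, 3))
        per = 3 if rng.random() < 0.3 else 1
        counts = rng.random((per, 4 ** order, 4)) * 50
        em = MarkovChainModel(order, per, counts, pseudocount=0.5)
        lo = lo_base + int(rng.integers(0, 3))
        hi = lo + int(rng.integers(0, 3))
        lens = list(rng.integers(lo, hi + 1, size=20))
        dur = smooth_durations(lens, bandwidth=int(rng.integers(0, 2)),
                               tail_mass=0.0)
        states.append(State(f"s{i}", em, dur,
                            start_phase=int(rng.integers(0, 3))))
    names = [st.name for st in states]
    A = rng.random((S, S)) * (rng.random((S, S)) < 0.6)
    endp = rng.random(S)
    trans, end = {}, {}
    for i in range(S):
        tot = A[i].sum() + endp[i]
        for j in range(S):
            if A[i, j] > 0:
                trans[(names[i], names[j])] = A[i, j] / tot
        end[names[i]] = endp[i] / tot
    b = rng.random(S)
    b /= b.sum()
    begin = {names[i]: b[i] for i in range(S)}
    spec = GhmmSpec(states, trans, begin, end)
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return spec, seq
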