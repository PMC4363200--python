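"""Generic generalised-HMM machinery.

A GHMM state emits a variable-length segment: fixed-length states carry
a weighted array matrix (WAM) or a literal motif set, variable-length
states carry a Markov-chain emission model (optionally three-periodic)
and a smoothed empirical duration distribution.  Decoding is explicit-
duration Viterbi in log space, with optional per-position constraints on
where a state may lie, start or end.

The decoder exploits the sparsity of admissible segment starts (a coding
segment can only start where the model topology allows, e.g. after an
ATG window), which keeps decoding fast enough in pure numpy for
chromosome-window-sized sequences.

``enumerate_all_parses`` is a brute-force oracle used by the test suite:
it scores every admissible segmentation with scalar arithmetic that is
independent of the decoder's prefix-sum bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dna import encode
from .errors import ConfigError, MycogeneError

NEG = -np.inf

#: score differences below this are treated as ties and broken
#: lexicographically (leftmost earliest-differing boundary)
TIE_EPS = 1e-9


class OracleSizeError(MycogeneError):
    """The enumeration oracle refuses instances beyond its size guard."""


# ---------------------------------------------------------------------------
# emission models
# ---------------------------------------------------------------------------

class MarkovChainModel:
    """k-order Markov chain over DNA, optionally three-periodic.

    Context codes are little-endian by distance: the base immediately
    preceding the emitted base is the least-significant digit, so
    marginalising a k-mer context to an m-mer context (backoff) is a
    reshape-and-sum over the most-distant bases.  Periodic models keep
    one table per codon position of the *emitted* base.

    The first ``k`` bases of a segment are scored with shortened
    contexts (orders 0..k-1), i.e. context never crosses the segment
    start.
    """

    def __init__(self, order: int, periodicity: int, counts: np.ndarray,
                 pseudocount: float, n_floor: float = math.log(0.25)):
        if periodicity not in (1, 3):
            raise ConfigError("periodicity must be 1 or 3")
        self.order = order
        self.periodicity = periodicity
        self.pseudocount = pseudocount
        self.n_floor = n_floor
        # counts shape: (periodicity, 4**order, 4)
        self.counts = counts
        self._logp: dict[int, np.ndarray] = {}
        for m in range(order + 1):
            c = counts.reshape(periodicity, 4 ** (order - m), 4 ** m, 4).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = (c + pseudocount) / (
                    c.sum(axis=-1, keepdims=True) + 4 * pseudocount
                )
                self._logp[m] = np.log(p)

    # -- training -----------------------------------------------------------

    @classmethod
    def train(
        cls,
        seqs: Sequence[tuple[str, int]],
        order: int,
        periodicity: int = 1,
        pseudocount: float = 0.01,
        order_quota: Optional[int] = None,
        n_floor: float = math.log(0.25),
    ) -> "MarkovChainModel":
        """Count (context -> base) events; optionally reduce the order
        until at least ``order_quota * 4**k`` events support the tables."""
        if not seqs:
            raise ConfigError("train_markov: empty training set")
        encoded = [(encode(s), ph % 3) for s, ph in seqs]
        k = order
        while True:
            counts = np.zeros((periodicity, 4 ** k, 4))
            events = 0
            for enc, ph in encoded:
                n = len(enc)
                for i in range(n):
                    b = enc[i]
                    if b == 4:
                        continue
                    m = min(k, i)
                    if m < k:
                        continue  # full-order table only counts full contexts
                    ctx = 0
                    ok = True
                    for d in range(1, k + 1):
                        bb = enc[i - d]
                        if bb == 4:
                            ok = False
                            break
                        ctx += int(bb) * 4 ** (d - 1)
                    if not ok:
                        continue
                    phase = (ph + i) % 3 if periodicity == 3 else 0
                    counts[phase, ctx, b] += 1
                    events += 1
            if order_quota is None or k == 0 or events >= order_quota * 4 ** k:
                break
            k -= 1
        return cls(k, periodicity, counts, pseudocount, n_floor)

    # -- scoring ------------------------------------------------------------

    def logp(self, m: int, phase: int, ctx: int, base: int) -> float:
        if base == 4:
            return self.n_floor
        return float(self._logp[m][phase if self.periodicity == 3 else 0, ctx, base])

    def score_segment(self, enc: np.ndarray, start: int, end: int,
                      start_phase: int = 0) -> float:
        """Score enc[start..end] (0-based inclusive) as one segment."""
        total = 0.0
        for i in range(start, end + 1):
            o = i - start
            m = min(self.order, o)
            b = int(enc[i])
            if b == 4:
                total += self.n_floor
                continue
            ctx = 0
            ok = True
            for d in range(1, m + 1):
                bb = int(enc[i - d])
                if bb == 4:
                    ok = False
                    break
                ctx += bb * 4 ** (d - 1)
            if not ok:
                total += self.n_floor
                continue
            phase = (start_phase + o) % 3
            total += self.logp(m, phase, ctx, b)
        return total

    def score(self, sequence: str, start_phase: int = 0,
              prior_context: str = "") -> float:
        """Score a whole sequence as one segment.

        ``prior_context`` optionally supplies bases preceding the
        sequence so scores are additive across a split when context is
        carried over.
        """
        enc = encode(prior_context + sequence)
        off = len(prior_context)
        if not sequence:
            return 0.0
        total = 0.0
        for i in range(off, len(enc)):
            o = i - off
            m = min(self.order, i)  # context may reach into prior_context
            b = int(enc[i])
            if b == 4:
                total += self.n_floor
                continue
            ctx = 0
            ok = True
            for d in range(1, m + 1):
                bb = int(enc[i - d])
                if bb == 4:
                    ok = False
                    break
                ctx += bb * 4 ** (d - 1)
            total += self.logp(m, (start_phase + o) % 3, ctx, b) if ok else self.n_floor
        return total

    def position_logprobs(self, enc: np.ndarray, m: int, phase: int) -> np.ndarray:
        """lp[i] = log P(enc[i] | m preceding bases, table ``phase``).

        Positions with i < m, or any N in context/base, score the floor.
        """
        L = len(enc)
        out = np.full(L, self.n_floor)
        if L == 0:
            return out
        ctx = np.zeros(L, dtype=np.int64)
        valid = np.ones(L, dtype=bool)
        for d in range(1, m + 1):
            prev = np.full(L, 4, dtype=np.int8)
            prev[d:] = enc[:-d] if d else enc
            valid &= prev != 4
            ctx += np.where(prev == 4, 0, prev).astype(np.int64) * 4 ** (d - 1)
        if m > 0:
            valid[:m] = False
        valid &= enc != 4
        table = self._logp[m][phase if self.periodicity == 3 else 0]
        idx = np.where(valid)[0]
        out[idx] = table[ctx[idx], enc[idx].astype(np.int64)]
        return out


class WeightedArrayMatrix:
    """Position-specific k-order model over a fixed-length window.

    Position ``j`` conditions on min(order, j) preceding bases, i.e.
    context is confined to the window (shortened-context backoff at the
    window's 5' edge).
    """

    def __init__(self, order: int, window_length: int,
                 counts: list[np.ndarray], pseudocount: float,
                 n_floor: float = math.log(0.25),
                 anchor: Optional[str] = None):
        self.order = order
        self.window_length = window_length
        self.pseudocount = pseudocount
        self.n_floor = n_floor
        #: literal motif the window must END with (e.g. "ATG" for the
        #: Kozak/start window); windows without it score -inf
        self.anchor = anchor
        self.counts = counts
        self._logp = []
        for c in counts:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = (c + pseudocount) / (c.sum(axis=-1, keepdims=True) + 4 * pseudocount)
                self._logp.append(np.log(p))

    @classmethod
    def train(cls, windows: Sequence[str], order: int,
              pseudocount: float = 0.01,
              n_floor: float = math.log(0.25)) -> "WeightedArrayMatrix":
        if not windows:
            raise ConfigError("train_wam: empty training set")
        wl = len(windows[0])
        for w in windows:
            if len(w) != wl:
                raise ConfigError("train_wam: ragged windows")
        counts = [np.zeros((4 ** min(order, j), 4)) for j in range(wl)]
        for w in windows:
            enc = encode(w)
            for j in range(wl):
                b = int(enc[j])
                if b == 4:
                    continue
                m = min(order, j)
                ctx = 0
                ok = True
                for d in range(1, m + 1):
                    bb = int(enc[j - d])
                    if bb == 4:
                        ok = False
                        break
                    ctx += bb * 4 ** (d - 1)
                if ok:
                    counts[j][ctx, b] += 1
        return cls(order, wl, counts, pseudocount, n_floor)

    def score_window(self, enc: np.ndarray, start: int) -> float:
        """Score the window enc[start : start+window_length]."""
        if self.anchor:
            tail = enc[start + self.window_length - len(self.anchor)
                       : start + self.window_length]
            if list(tail) != list(encode(self.anchor)):
                return NEG
        total = 0.0
        for j in range(self.window_length):
            i = start + j
            b = int(enc[i])
            if b == 4:
                total += self.n_floor
                continue
            m = min(self.order, j)
            ctx = 0
            ok = True
            for d in range(1, m + 1):
                bb = int(enc[i - d])
                if bb == 4:
                    ok = False
                    break
                ctx += bb * 4 ** (d - 1)
            total += float(self._logp[j][ctx, b]) if ok else self.n_floor
        return total

    def score(self, window: str) -> float:
        if len(window) != self.window_length:
            raise ConfigError("score_wam: window length mismatch")
        return self.score_window(encode(window), 0)

    def windows_ending_logprobs(self, enc: np.ndarray) -> np.ndarray:
        """E[t] (1-based t) = score of the window occupying positions
        t-window_length+1..t; -inf where the window does not fit."""
        L = len(enc)
        wl = self.window_length
        out = np.full(L + 1, NEG)
        if L < wl:
            return out
        n = L - wl + 1                      # window start offsets 0..n-1
        acc = np.zeros(n)
        for j in range(wl):
            pos = np.arange(n) + j
            b = enc[pos].astype(np.int64)
            m = min(self.order, j)
            ctx = np.zeros(n, dtype=np.int64)
            valid = b != 4
            for d in range(1, m + 1):
                bb = enc[pos - d].astype(np.int64)
                valid &= bb != 4
                ctx += np.where(bb == 4, 0, bb) * 4 ** (d - 1)
            vals = np.full(n, self.n_floor)
            idx = np.where(valid)[0]
            table = self._logp[j]
            vals[idx] = table[ctx[idx], b[idx]]
            acc += vals
        out[wl:] = acc
        if self.anchor:
            a = encode(self.anchor)
            ok = np.ones(n, dtype=bool)
            for j, base in enumerate(a):
                pos = np.arange(n) + wl - len(a) + j
                ok &= enc[pos] == base
            out[wl:][~ok] = NEG
        return out


class LiteralMotifSet:
    """Fixed-length literal motif emission (e.g. the stop-codon state)."""

    def __init__(self, logp_by_motif: dict[str, float]):
        lengths = {len(m) for m in logp_by_motif}
        if len(lengths) != 1:
            raise ConfigError("literal motifs must share one length")
        self.length = lengths.pop()
        self.logp_by_motif = dict(logp_by_motif)

    @classmethod
    def train(cls, observed: Sequence[str], motifs: Sequence[str],
              pseudocount: float = 1.0) -> "LiteralMotifSet":
        counts = {m: pseudocount for m in motifs}
        for o in observed:
            if o in counts:
                counts[o] += 1
        total = sum(counts.values())
        return cls({m: math.log(c / total) for m, c in counts.items()})

    def score_at(self, seq: str, start: int) -> float:
        """Score the motif at 0-based ``start``; -inf if not a motif."""
        return self.logp_by_motif.get(seq[start : start + self.length], NEG)

    def ends_logprobs(self, seq: str) -> np.ndarray:
        L = len(seq)
        out = np.full(L + 1, NEG)
        for t in range(self.length, L + 1):
            out[t] = self.logp_by_motif.get(seq[t - self.length : t], NEG)
        return out


# public functional wrappers matching the operation names ---------------------

def train_markov(seqs, order, periodicity=1, pseudocount=0.01, **kw):
    return MarkovChainModel.train(seqs, order, periodicity, pseudocount, **kw)


def score_markov(model: MarkovChainModel, sequence: str, start_phase: int = 0,
                 prior_context: str = "") -> float:
    return model.score(sequence, start_phase, prior_context)


def train_wam(windows, order, pseudocount=0.01):
    return WeightedArrayMatrix.train(windows, order, pseudocount)


def score_wam(wam: WeightedArrayMatrix, window: str) -> float:
    return wam.score(window)


# ---------------------------------------------------------------------------
# duration models
# ---------------------------------------------------------------------------

@dataclass
class DurationModel:
    """Fixed or smoothed-empirical segment-length distribution.

    Empirical models hold a log-pmf over [support_min, support_max] and
    geometric tails on both sides: the high-side tail is the usual
    continuation beyond the longest observed length; the low-side tail
    keeps shorter-than-observed segments admissible (heavily penalised
    rather than impossible), which the transcript predictor needs for
    genes shorter than the training-set floor.  ``modulus``/``residue``
    restrict admissible lengths (coding segments: length = 0 mod 3).
    """

    kind: str                               # 'fixed' | 'empirical'
    fixed_length: int = 0
    support_min: int = 0
    support_max: int = 0
    log_pmf: Optional[np.ndarray] = None    # over support
    tail_mass: float = 1e-3
    tail_rate: float = 0.01                 # geometric hazard for both tails
    modulus: int = 1
    residue: int = 0

    def log_prob(self, d: int) -> float:
        if d < 1:
            return NEG
        if self.kind == "fixed":
            return 0.0 if d == self.fixed_length else NEG
        if self.modulus > 1 and d % self.modulus != self.residue:
            return NEG
        if self.support_min <= d <= self.support_max:
            return float(self.log_pmf[d - self.support_min])
        if self.tail_mass <= 0.0:
            return NEG
        r = self.tail_rate
        if d > self.support_max:
            j = d - self.support_max
        else:
            j = self.support_min - d
        # geometric: tail_mass * r * (1-r)^(j-1), split over residue classes
        lp = math.log(self.tail_mass) + math.log(r) + (j - 1) * math.log1p(-r)
        return lp

    def log_prob_array(self, dmax: int) -> np.ndarray:
        out = np.full(dmax + 1, NEG)
        if self.kind == "fixed":
            if self.fixed_length <= dmax:
                out[self.fixed_length] = 0.0
            return out
        d = np.arange(1, dmax + 1)
        vals = np.full(dmax, NEG)
        lo, hi = self.support_min, self.support_max
        inside = (d >= lo) & (d <= hi)
        vals[inside] = self.log_pmf[np.clip(d[inside] - lo, 0, len(self.log_pmf) - 1)]
        if self.tail_mass > 0.0:
            r = self.tail_rate
            base = math.log(self.tail_mass) + math.log(r)
            above = d > hi
            vals[above] = base + (d[above] - hi - 1) * math.log1p(-r)
            below = d < lo
            vals[below] = base + (lo - d[below] - 1) * math.log1p(-r)
        if self.modulus > 1:
            vals[(d % self.modulus) != self.residue] = NEG
        out[1:] = vals
        return out

    @property
    def max_finite(self) -> Optional[int]:
        """Largest admissible duration, or None if unbounded (tailed)."""
        return self.fixed_length if self.kind == "fixed" else None


def smooth_durations(
    lengths: Sequence[int],
    bandwidth: Optional[int] = None,
    support: Optional[tuple[int, int]] = None,
    modulus: int = 1,
    residue: int = 0,
    tail_mass: float = 1e-3,
) -> DurationModel:
    """Triangular-kernel smoothing of observed segment lengths.

    The histogram over the support is convolved with a triangular kernel
    of half-width ``bandwidth`` (default max(2, width/50)), renormalised
    to 1 - 2*tail_mass, with geometric tails beyond both support ends
    whose rate is matched to the spread of the data.
    """
    if not lengths:
        raise ConfigError("smooth_durations: empty length sample")
    lengths = [int(x) for x in lengths]
    lo = min(lengths) if support is None else support[0]
    hi = max(lengths) if support is None else support[1]
    width = hi - lo + 1
    if bandwidth is None:
        bandwidth = max(2, width // 50)
    ext_lo = max(1, lo - bandwidth)
    ext_hi = hi + bandwidth
    hist = np.zeros(ext_hi - ext_lo + 1)
    clipped_high = [x for x in lengths if x > hi]
    for x in lengths:
        if ext_lo <= x <= ext_hi:
            hist[x - ext_lo] += 1
    if bandwidth > 0:
        kern = np.array(
            [bandwidth + 1 - abs(j) for j in range(-bandwidth, bandwidth + 1)],
            dtype=float,
        )
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
    if modulus > 1:
        d = np.arange(ext_lo, ext_hi + 1)
        hist[(d % modulus) != residue] = 0.0
    total = hist.sum()
    if total <= 0:
        raise ConfigError("smooth_durations: no mass inside support")
    pmf = hist / total * (1.0 - 2.0 * tail_mass)
    sd = float(np.std(lengths))
    if clipped_high:
        excess = float(np.mean(clipped_high)) - hi
        scale = max(1.0, excess)
    else:
        scale = max(1.0, sd)
    rate = 1.0 / (1.0 + scale)
    with np.errstate(divide="ignore"):
        log_pmf = np.log(pmf)
    return DurationModel(
        kind="empirical",
        support_min=ext_lo,
        support_max=ext_hi,
        log_pmf=log_pmf,
        tail_mass=tail_mass,
        tail_rate=rate,
        modulus=modulus,
        residue=residue,
    )


def fixed_duration(n: int) -> DurationModel:
    return DurationModel(kind="fixed", fixed_length=n)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class State:
    name: str
    emission: object                      # MarkovChainModel | WAM | LiteralMotifSet
    duration: DurationModel
    start_phase: int = 0                  # codon phase of the first emitted base

    @property
    def is_fixed(self) -> bool:
        return self.duration.kind == "fixed"


@dataclass
class GhmmSpec:
    """States, transition probabilities and begin/end distributions."""

    states: list[State]
    transitions: dict[tuple[str, str], float]
    begin: dict[str, float]
    end: dict[str, float]

    def __post_init__(self) -> None:
        self._index = {st.name: i for i, st in enumerate(self.states)}
        if len(self._index) != len(self.states):
            raise ConfigError("duplicate state names")

    def index(self, name: str) -> int:
        return self._index[name]

    def validate(self, tol: float = 1e-9) -> None:
        for st in self.states:
            out = sum(
                p for (a, b), p in self.transitions.items() if a == st.name
            ) + self.end.get(st.name, 0.0)
            if abs(out - 1.0) > 1e-6:
                raise ConfigError(
                    f"state {st.name}: outgoing probabilities sum to {out}"
                )
            if st.emission is None or st.duration is None:
                raise ConfigError(f"state {st.name}: missing emission/duration")
            if isinstance(st.emission, WeightedArrayMatrix) and (
                not st.is_fixed
                or st.duration.fixed_length != st.emission.window_length
            ):
                raise ConfigError(f"state {st.name}: WAM needs matching fixed length")
            if isinstance(st.emission, LiteralMotifSet) and (
                not st.is_fixed or st.duration.fixed_length != st.emission.length
            ):
                raise ConfigError(f"state {st.name}: literal needs matching length")
        btot = sum(self.begin.values())
        if abs(btot - 1.0) > 1e-6:
            raise ConfigError(f"begin probabilities sum to {btot}")

    def log_matrices(self):
        S = len(self.states)
        logA = np.full((S, S), NEG)
        for (a, b), p in self.transitions.items():
            if p > 0:
                logA[self._index[a], self._index[b]] = math.log(p)
        logB = np.full(S, NEG)
        for a, p in self.begin.items():
            if p > 0:
                logB[self._index[a]] = math.log(p)
        logE = np.full(S, NEG)
        for a, p in self.end.items():
            if p > 0:
                logE[self._index[a]] = math.log(p)
        return logA, logB, logE

    # -- flat-text serialisation (inspectable/diffable model dumps) ---------

    def dump(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("# mycogene GHMM dump\n")
            fh.write("## states\n")
            for st in self.states:
                em = type(st.emission).__name__
                dur = (
                    f"fixed:{st.duration.fixed_length}"
                    if st.is_fixed
                    else f"empirical:{st.duration.support_min}-{st.duration.support_max}"
                )
                fh.write(f"{st.name}\t{em}\t{dur}\tstart_phase={st.start_phase}\n")
            fh.write("## begin\n")
            for a, p in sorted(self.begin.items()):
                fh.write(f"{a}\t{p:.6g}\n")
            fh.write("## transitions\n")
            for (a, b), p in sorted(self.transitions.items()):
                fh.write(f"{a}\t{b}\t{p:.6g}\n")
            fh.write("## end\n")
            for a, p in sorted(self.end.items()):
                fh.write(f"{a}\t{p:.6g}\n")
            fh.write("## emissions\n")
            for st in self.states:
                em = st.emission
                if isinstance(em, MarkovChainModel):
                    fh.write(f"{st.name}\tmarkov order={em.order} "
                             f"periodicity={em.periodicity}\n")
                    tab = np.exp(em._logp[min(em.order, 1)])
                    fh.write(f"{st.name}\torder1-table\t"
                             + " ".join(f"{x:.4f}" for x in tab.ravel()) + "\n")
                elif isinstance(em, WeightedArrayMatrix):
                    fh.write(f"{st.name}\twam order={em.order} "
                             f"window={em.window_length}\n")
                elif isinstance(em, LiteralMotifSet):
                    fh.write(f"{st.name}\tliteral "
                             + ",".join(sorted(em.logp_by_motif)) + "\n")


@dataclass
class StatePath:
    """A segmentation of [1, L]: ordered (state, start, end) plus score."""

    segments: list[tuple[str, int, int]]
    log_prob: float
    segment_scores: list[float] = field(default_factory=list)

    def states(self) -> list[str]:
        return [s for s, _, _ in self.segments]


@dataclass
class ViterbiConstraints:
    """Per-position admissibility masks, all 1-based position indexed
    (index 0 unused).  ``occupancy[s][p]`` False forbids state s from
    covering position p; ``start``/``end`` restrict segment boundaries."""

    length: int
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)
    start: dict[str, np.ndarray] = field(default_factory=dict)
    end: dict[str, np.ndarray] = field(default_factory=dict)

    def _new(self) -> np.ndarray:
        return np.ones(self.length + 1, dtype=bool)

    def forbid_occupancy(self, state: str, pos_from: int, pos_to: int) -> None:
        arr = self.occupancy.setdefault(state, self._new())
        arr[max(1, pos_from) : min(self.length, pos_to) + 1] = False

    def forbid_start(self, state: str, pos_from: int, pos_to: int) -> None:
        arr = self.start.setdefault(state, self._new())
        arr[max(1, pos_from) : min(self.length, pos_to) + 1] = False

    def restrict_starts(self, state: str, allowed_positions) -> None:
        arr = np.zeros(self.length + 1, dtype=bool)
        pos = np.asarray(list(allowed_positions), dtype=np.int64)
        pos = pos[(pos >= 1) & (pos <= self.length)]
        arr[pos] = True
        self.start[state] = arr

    def restrict_ends(self, state: str, allowed_positions) -> None:
        arr = np.zeros(self.length + 1, dtype=bool)
        pos = np.asarray(list(allowed_positions), dtype=np.int64)
        pos = pos[(pos >= 1) & (pos <= self.length)]
        arr[pos] = True
        self.end[state] = arr


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

class _MarkovScorer:
    """Per-sequence arrays for O(1) segment scores of one Markov state."""

    def __init__(self, model: MarkovChainModel, enc: np.ndarray, start_phase: int):
        self.model = model
        self.k = model.order
        self.sp = start_phase % 3
        L = len(enc)
        periodic = model.periodicity == 3
        phases = 3 if periodic else 1
        # lp[m][c][i]: order-m logprob with table c at position i
        lp = [
            [model.position_logprobs(enc, m, c) for c in range(phases)]
            for m in range(self.k + 1)
        ]
        # full-order composites M_delta[i] = lp_k[(i+delta)%3][i]
        self.C = np.zeros((3, L + 1))
        idx = np.arange(L)
        if periodic:
            for delta in range(3):
                M = np.choose((idx + delta) % 3, lp[self.k])
                self.C[delta, 1:] = np.cumsum(M)
        else:
            self.C[0, 1:] = np.cumsum(lp[self.k][0])
            self.C[1] = self.C[0]
            self.C[2] = self.C[0]
        s_idx = np.arange(L + 1)
        self.delta_of_s = (self.sp - s_idx) % 3 if periodic else np.zeros(L + 1, dtype=np.int64)
        # Csel[s] = C[delta(s), s]
        self.Csel = self.C[self.delta_of_s, s_idx]
        # corrA[s] = sum_m lp[m][(sp+m)%3][s+m]  (first k in-segment positions)
        corrA = np.zeros(L + 1)
        for m in range(self.k):
            c = (self.sp + m) % 3 if periodic else 0
            arr = lp[m][c]
            corrA[: L - m] += arr[m:] if m else arr
            # positions s with s+m >= L contribute nothing (segment would
            # not have length >= k anyway)
        # corrB[s] = C[delta(s), s+k] - C[delta(s), s]
        s_ok = np.arange(0, max(0, L + 1 - self.k))
        corr = np.full(L + 1, 0.0)
        if len(s_ok):
            d_s = self.delta_of_s[s_ok]
            corr[s_ok] = corrA[s_ok] - (self.C[d_s, s_ok + self.k] - self.C[d_s, s_ok])
        self.corr = corr
        # exact short-segment scores ES[d][t] for d=1..k-1
        self.ES = {}
        for d in range(1, self.k):
            arr = np.full(L + 1, NEG)
            acc = np.zeros(L)  # indexed by segment start s (0-based), s+d<=L
            n = L - d + 1
            if n <= 0:
                self.ES[d] = arr
                continue
            acc = np.zeros(n)
            for m in range(d):
                c = (self.sp + m) % 3 if periodic else 0
                acc += lp[m][c][m : m + n]
            arr[d:] = acc
            self.ES[d] = arr

    def seg_score_ge_k(self, s_arr: np.ndarray, t: int) -> np.ndarray:
        """Emission scores of segments (s+1..t) with length >= k."""
        d_s = self.delta_of_s[s_arr]
        Ct = self.C[:, t]
        return Ct[d_s] - self.Csel[s_arr] + self.corr[s_arr]

    def fixed_scores(self, n: int) -> np.ndarray:
        """E[t] = score of the length-n segment ending at 1-based t."""
        L = self.C.shape[1] - 1
        out = np.full(L + 1, NEG)
        if n > L:
            return out
        if n < max(self.k, 1) and self.k > 1:
            return self.ES[n].copy() if n in self.ES else out
        s_arr = np.arange(0, L - n + 1)
        d_s = self.delta_of_s[s_arr]
        out[n:] = self.C[d_s, s_arr + n] - self.Csel[s_arr] + self.corr[s_arr]
        return out


class _NullScorer:
    """Uniform-zero emission (used by tests for duration-only toys)."""

    k = 0

    def seg_score_ge_k(self, s_arr, t):
        return np.zeros(len(s_arr))


def _prep_scorer(state: State, enc: np.ndarray):
    em = state.emission
    if isinstance(em, MarkovChainModel):
        return _MarkovScorer(em, enc, state.start_phase)
    return _NullScorer()


def viterbi(
    spec: GhmmSpec,
    sequence: str,
    constraints: Optional[ViterbiConstraints] = None,
    force_python: bool = False,
) -> Optional[StatePath]:
    """Maximum-log-probability segmentation of ``sequence``.

    Returns None (an explicit no-parse) when no admissible path exists.
    Exact score ties are broken toward the path whose earliest differing
    segment boundary is leftmost (then by state index), so output is
    deterministic and comparable with the enumeration oracle.

    Long sequences are decoded by a compiled kernel; whenever the kernel
    detects a near-tie it defers to this reference implementation so the
    tie-break stays exact.
    """
    if not force_python and len(sequence) > 60:
        result = _viterbi_fast(spec, sequence, constraints)
        if result is not _FALLBACK:
            return result
    return _viterbi_py(spec, sequence, constraints)


def _viterbi_py(
    spec: GhmmSpec,
    sequence: str,
    constraints: Optional[ViterbiConstraints] = None,
) -> Optional[StatePath]:
    L = len(sequence)
    if L == 0:
        return StatePath([], 0.0)
    enc = encode(sequence)
    S = len(spec.states)
    logA, logB, logE = spec.log_matrices()
    names = [st.name for st in spec.states]

    # constraint arrays
    ones = np.ones(L + 1, dtype=bool)
    occ_pref = []
    start_ok = []
    end_ok = []
    for st in spec.states:
        occ = constraints.occupancy.get(st.name) if constraints else None
        if occ is None:
            occ_pref.append(None)
        else:
            pref = np.zeros(L + 1, dtype=np.int64)
            pref[1:] = np.cumsum(~occ[1:])
            occ_pref.append(pref)
        start_ok.append(constraints.start.get(st.name, ones) if constraints else ones)
        end_ok.append(constraints.end.get(st.name, ones) if constraints else ones)

    # per-state preparation
    fixed_len = [0] * S
    fixedE = [None] * S
    scorers = [None] * S
    dur_arr = [None] * S
    dmin = [1] * S
    dmax = [L] * S
    var_states = []
    fix_states = []
    for j, st in enumerate(spec.states):
        if st.is_fixed:
            n = st.duration.fixed_length
            fixed_len[j] = n
            em = st.emission
            if isinstance(em, WeightedArrayMatrix):
                fixedE[j] = em.windows_ending_logprobs(enc)
            elif isinstance(em, LiteralMotifSet):
                fixedE[j] = em.ends_logprobs(sequence)
            elif isinstance(em, MarkovChainModel):
                sc = _MarkovScorer(em, enc, st.start_phase)
                fixedE[j] = sc.fixed_scores(n)
            else:
                fixedE[j] = np.zeros(L + 1)
            fix_states.append(j)
        else:
            scorers[j] = _prep_scorer(st, enc)
            da = st.duration.log_prob_array(L)
            dur_arr[j] = da
            finite = np.where(np.isfinite(da))[0]
            if len(finite):
                dmin[j] = int(finite[0])
                dmax[j] = int(finite[-1])
            else:
                dmin[j], dmax[j] = 1, 0  # nothing admissible
            var_states.append(j)

    V = np.full((S, L + 1), NEG)
    W = np.full((S, L + 1), NEG)
    bp_s = np.full((S, L + 1), -1, dtype=np.int64)
    bp_p = np.full((S, L + 1), -1, dtype=np.int64)  # predecessor state at bp_s
    W[:, 0] = logB
    Wpred = np.full((S, L + 1), -1, dtype=np.int64)  # argmax predecessor for W

    # sparse start boundaries per variable state
    starts = [np.empty(L + 1, dtype=np.int64) for _ in range(S)]
    wvals = [np.empty(L + 1) for _ in range(S)]
    n_starts = [0] * S

    def _register_starts(s: int) -> None:
        if s + 1 > L:
            return
        for j in var_states:
            w = W[j, s]
            if w == NEG or not start_ok[j][s + 1]:
                continue
            i = n_starts[j]
            starts[j][i] = s
            wvals[j][i] = w
            n_starts[j] = i + 1

    def _reconstruct(j: int, t: int) -> list[tuple[int, int, int]]:
        """Segments (start, end, state) of the stored best path to (j, t)."""
        segs = []
        while t > 0:
            s = int(bp_s[j, t])
            segs.append((s + 1, t, j))
            pj = int(bp_p[j, t])
            t, j = s, pj
            if t == 0:
                break
        return segs[::-1]

    def _path_key(segs) -> tuple:
        bounds = tuple(e for _, e, _ in segs[:-1])
        st_seq = tuple(j for _, _, j in segs)
        return (bounds, st_seq)

    def _choose(cands: list[tuple[float, int, int]], t: int, j: int):
        """cands: (score, s, pred_state). Pick max score; near-exact ties
        (within TIE_EPS) by lexicographically smallest boundary path."""
        best = max(c[0] for c in cands)
        tied = [c for c in cands if c[0] >= best - TIE_EPS]
        if len(tied) == 1:
            return tied[0]
        keyed = []
        for score, s, pj in tied:
            prefix = _reconstruct(pj, s) if s > 0 and pj >= 0 else []
            segs = prefix + [(s + 1, t, j)]
            keyed.append((_path_key(segs), (score, s, pj)))
        keyed.sort(key=lambda x: x[0])
        return keyed[0][1]

    _register_starts(0)

    for t in range(1, L + 1):
        V_col = np.full(S, NEG)
        for j in fix_states:
            if not end_ok[j][t]:
                continue
            n = fixed_len[j]
            s = t - n
            if s < 0:
                continue
            w = W[j, s]
            if w == NEG:
                continue
            if not start_ok[j][s + 1]:
                continue
            e = fixedE[j][t]
            if e == NEG:
                continue
            pref = occ_pref[j]
            if pref is not None and pref[t] - pref[s] > 0:
                continue
            V_col[j] = w + e
            bp_s[j, t] = s
            bp_p[j, t] = Wpred[j, s]
        for j in var_states:
            if not end_ok[j][t]:
                continue
            nj = n_starts[j]
            if nj == 0:
                continue
            lo_s = t - dmax[j]
            hi_s = t - max(dmin[j], 1)
            if hi_s < 0:
                continue
            sc = scorers[j]
            k = sc.k
            st_arr = starts[j]
            a = int(np.searchsorted(st_arr[:nj], lo_s, side="left"))
            b = int(np.searchsorted(st_arr[:nj], min(hi_s, t - max(k, 1)),
                                    side="right"))
            cand_pairs: list[tuple[float, int]] = []
            if b > a:
                s_slice = st_arr[a:b]
                cand = wvals[j][a:b] + sc.seg_score_ge_k(s_slice, t) \
                    + dur_arr[j][t - s_slice]
                pref = occ_pref[j]
                if pref is not None:
                    cand = np.where(pref[t] - pref[s_slice] > 0, NEG, cand)
                im = int(np.argmax(cand))
                if cand[im] > NEG:
                    vmax = float(cand[im])
                    near = np.flatnonzero(cand >= vmax - TIE_EPS)
                    if len(near) > 1:
                        cand_pairs.extend(
                            (float(cand[i]), int(s_slice[i])) for i in near
                        )
                    else:
                        cand_pairs.append((vmax, int(s_slice[im])))
            # short segments (d < k): exact scores
            if k > 1:
                d_lo = max(dmin[j], 1)
                d_hi = min(k - 1, t, dmax[j])
                for d in range(d_lo, d_hi + 1):
                    s = t - d
                    w = W[j, s]
                    if w == NEG or not start_ok[j][s + 1]:
                        continue
                    da = dur_arr[j][d]
                    if da == NEG:
                        continue
                    es = sc.ES[d][t] if isinstance(sc, _MarkovScorer) else 0.0
                    if es == NEG:
                        continue
                    pref = occ_pref[j]
                    if pref is not None and pref[t] - pref[s] > 0:
                        continue
                    cand_pairs.append((w + da + es, s))
            if not cand_pairs:
                continue
            best_val = max(v for v, _ in cand_pairs)
            tied_list = [(v, s) for v, s in cand_pairs if v >= best_val - TIE_EPS]
            if len(tied_list) == 1:
                best_s = tied_list[0][1]
            else:
                cands = [(v, s, int(Wpred[j, s])) for v, s in tied_list]
                _, best_s, _ = _choose(cands, t, j)
            V_col[j] = best_val
            bp_s[j, t] = best_s
            bp_p[j, t] = Wpred[j, best_s]
        V[:, t] = V_col
        # W column for boundary t
        if t < L:
            mat = V_col[:, None] + logA
            wcol = mat.max(axis=0)
            pred = mat.argmax(axis=0)
            # tie resolution among predecessors
            for jj in range(S):
                if wcol[jj] == NEG:
                    continue
                ties = np.flatnonzero(mat[:, jj] >= wcol[jj] - TIE_EPS)
                if len(ties) > 1:
                    keyed = sorted(
                        (_path_key(_reconstruct(int(i), t)), int(i)) for i in ties
                    )
                    pred[jj] = keyed[0][1]
            W[:, t] = wcol
            Wpred[:, t] = pred
            _register_starts(t)

    final = V[:, L] + logE
    jbest = int(np.argmax(final))
    if final[jbest] == NEG:
        return None
    ties = np.flatnonzero(final >= final[jbest] - TIE_EPS)
    if len(ties) > 1:
        keyed = sorted((_path_key(_reconstruct(int(i), L)), int(i)) for i in ties)
        jbest = keyed[0][1]
    segs_idx = _reconstruct(jbest, L)
    segments = [(names[j], s, e) for s, e, j in segs_idx]
    seg_scores = []
    for s, e, j in segs_idx:
        seg_scores.append(float(V[j, e] - W[j, s - 1]))
    return StatePath(segments, float(final[jbest]), seg_scores)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_all_parses(
    spec: GhmmSpec,
    sequence: str,
    constraints: Optional[ViterbiConstraints] = None,
    max_len: int = 30,
    max_states: int = 6,
) -> Optional[StatePath]:
    """Exhaustively enumerate every admissible segmentation (test oracle).

    Scores are accumulated with scalar per-position arithmetic, fully
    independent of the decoder's prefix-sum machinery; tie-break is the
    same declarative rule (smallest boundary list, then state indices).
    """
    L = len(sequence)
    if L > max_len or len(spec.states) > max_states:
        raise OracleSizeError(
            f"oracle refuses |seq|={L} (max {max_len}), "
            f"|states|={len(spec.states)} (max {max_states})"
        )
    if L == 0:
        return StatePath([], 0.0)
    enc = encode(sequence)
    S = len(spec.states)
    logA, logB, logE = spec.log_matrices()
    names = [st.name for st in spec.states]
    ones = np.ones(L + 1, dtype=bool)

    def occ_ok(j, s, e):
        if constraints is None:
            return True
        occ = constraints.occupancy.get(names[j])
        if occ is None:
            return True
        return bool(occ[s:e + 1].all())

    def s_ok(j, p):
        if constraints is None:
            return True
        return bool(constraints.start.get(names[j], ones)[p])

    def e_ok(j, p):
        if constraints is None:
            return True
        return bool(constraints.end.get(names[j], ones)[p])

    def emit(j, s, e):
        """Scalar emission score of state j over 1-based [s, e]."""
        st = spec.states[j]
        em = st.emission
        if isinstance(em, MarkovChainModel):
            return em.score_segment(enc, s - 1, e - 1, st.start_phase)
        if isinstance(em, WeightedArrayMatrix):
            return em.score_window(enc, s - 1)
        if isinstance(em, LiteralMotifSet):
            return em.score_at(sequence, s - 1)
        return 0.0

    best: list = [NEG, None]  # score, (key, segments)

    def consider(score, segs):
        key = (tuple(e for _, e, _ in segs[:-1]), tuple(j for _, _, j in segs))
        if best[1] is None or score > best[0] + TIE_EPS:
            best[0] = score
            best[1] = (key, list(segs))
        elif score >= best[0] - TIE_EPS and key < best[1][0]:
            best[0] = max(best[0], score)
            best[1] = (key, list(segs))

    segs: list = []

    def rec(pos, prev_j, score):
        if pos > L:
            return
        for j in range(S):
            trans = logB[j] if prev_j < 0 else logA[prev_j, j]
            if trans == NEG:
                continue
            st = spec.states[j]
            if st.is_fixed:
                d_range = [st.duration.fixed_length]
            else:
                d_range = [
                    d for d in range(1, L - pos + 2)
                    if st.duration.log_prob(d) > NEG
                ]
            for d in d_range:
                e = pos + d - 1
                if e > L:
                    continue
                if not (s_ok(j, pos) and e_ok(j, e) and occ_ok(j, pos, e)):
                    continue
                dscore = 0.0 if st.is_fixed else st.duration.log_prob(d)
                escore = emit(j, pos, e)
                if escore == NEG or dscore == NEG:
                    continue
                total = score + trans + dscore + escore
                segs.append((pos, e, j))
                if e == L:
                    if logE[j] > NEG:
                        consider(total + logE[j], segs)
                else:
                    rec(e + 1, j, total)
                segs.pop()

    rec(1, -1, 0.0)
    if best[1] is None:
        return None
    segments = [(names[j], s, e) for s, e, j in best[1][1]]
    return StatePath(segments, float(best[0]))


# ---------------------------------------------------------------------------
# compiled fast path
# ---------------------------------------------------------------------------

_FALLBACK = object()

try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _decode_kernel(S, L, logA, logB, logE, is_var, fixlen, fixedE, kord,
                       Cmat, Csel, corr, delta, ES, dur, dmin, dmax,
                       startok, endok, occ, has_occ,
                       V, W, Wpred, bp_s, bp_p, eps):
        starts = np.zeros((S, L + 1), dtype=np.int64)
        wv = np.zeros((S, L + 1))
        nstart = np.zeros(S, dtype=np.int64)
        tie = 0
        for j in range(S):
            W[j, 0] = logB[j]
            Wpred[j, 0] = -1
            if is_var[j] == 1 and logB[j] > NEG and startok[j, 1] == 1:
                starts[j, 0] = 0
                wv[j, 0] = logB[j]
                nstart[j] = 1
        for t in range(1, L + 1):
            for j in range(S):
                V[j, t] = NEG
                if endok[j, t] == 0:
                    continue
                if is_var[j] == 0:
                    n = fixlen[j]
                    s = t - n
                    if s < 0:
                        continue
                    w = W[j, s]
                    if w == NEG or startok[j, s + 1] == 0:
                        continue
                    e = fixedE[j, t]
                    if e == NEG:
                        continue
                    if has_occ[j] == 1 and occ[j, t] - occ[j, s] > 0:
                        continue
                    V[j, t] = w + e
                    bp_s[j, t] = s
                    bp_p[j, t] = Wpred[j, s]
                else:
                    best = NEG
                    bs = -1
                    k = kord[j]
                    dmn = dmin[j]
                    dmx = dmax[j]
                    for idx in range(nstart[j] - 1, -1, -1):
                        s = starts[j, idx]
                        d = t - s
                        if d < dmn:
                            continue
                        if d > dmx:
                            break
                        dl = dur[j, d]
                        if dl == NEG:
                            continue
                        if has_occ[j] == 1 and occ[j, t] - occ[j, s] > 0:
                            continue
                        if d >= k or k == 0:
                            em = Cmat[j, delta[j, s], t] - Csel[j, s] + corr[j, s]
                        else:
                            em = ES[j, d, t]
                            if em == NEG:
                                continue
                        val = wv[j, idx] + dl + em
                        if val > best:
                            if val <= best + eps and bs >= 0:
                                tie = 1
                            best = val
                            bs = s
                        elif val >= best - eps and bs >= 0:
                            tie = 1
                    if bs >= 0:
                        V[j, t] = best
                        bp_s[j, t] = bs
                        bp_p[j, t] = Wpred[j, bs]
            if t < L:
                for jj in range(S):
                    wb = NEG
                    wp = -1
                    for i in range(S):
                        a = logA[i, jj]
                        if a == NEG:
                            continue
                        v = V[i, t]
                        if v == NEG:
                            continue
                        val = v + a
                        if val > wb:
                            if val <= wb + eps and wp >= 0:
                                tie = 1
                            wb = val
                            wp = i
                        elif val >= wb - eps and wp >= 0:
                            tie = 1
                    W[jj, t] = wb
                    Wpred[jj, t] = wp
                    if (is_var[jj] == 1 and wb > NEG
                            and startok[jj, t + 1] == 1):
                        starts[jj, nstart[jj]] = t
                        wv[jj, nstart[jj]] = wb
                        nstart[jj] += 1
        # final state choice
        jbest = -1
        fbest = NEG
        for j in range(S):
            if logE[j] == NEG or V[j, L] == NEG:
                continue
            val = V[j, L] + logE[j]
            if val > fbest:
                if val <= fbest + eps and jbest >= 0:
                    tie = 1
                fbest = val
                jbest = j
            elif val >= fbest - eps and jbest >= 0:
                tie = 1
        return jbest, fbest, tie

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    _HAVE_NUMBA = False


def _viterbi_fast(spec, sequence, constraints):
    if not _HAVE_NUMBA:
        return _FALLBACK
    L = len(sequence)
    enc = encode(sequence)
    S = len(spec.states)
    logA, logB, logE = spec.log_matrices()
    names = [st.name for st in spec.states]

    is_var = np.zeros(S, dtype=np.int8)
    fixlen = np.zeros(S, dtype=np.int64)
    fixedE = np.full((S, L + 1), NEG)
    kord = np.zeros(S, dtype=np.int64)
    KMAX = 1
    scorers = [None] * S
    for j, st in enumerate(spec.states):
        if not st.is_fixed and isinstance(st.emission, MarkovChainModel):
            KMAX = max(KMAX, st.emission.order)
    Cmat = np.zeros((S, 3, L + 1))
    Csel = np.zeros((S, L + 1))
    corr = np.zeros((S, L + 1))
    delta = np.zeros((S, L + 1), dtype=np.int64)
    ES = np.full((S, KMAX + 1, L + 1), NEG)
    dur = np.full((S, L + 1), NEG)
    dmin = np.ones(S, dtype=np.int64)
    dmax = np.full(S, L, dtype=np.int64)

    for j, st in enumerate(spec.states):
        if st.is_fixed:
            n = st.duration.fixed_length
            fixlen[j] = n
            em = st.emission
            if isinstance(em, WeightedArrayMatrix):
                fixedE[j] = em.windows_ending_logprobs(enc)
            elif isinstance(em, LiteralMotifSet):
                fixedE[j] = em.ends_logprobs(sequence)
            elif isinstance(em, MarkovChainModel):
                sc = _MarkovScorer(em, enc, st.start_phase)
                fixedE[j] = sc.fixed_scores(n)
            else:
                fixedE[j] = np.zeros(L + 1)
        else:
            is_var[j] = 1
            sc = _prep_scorer(st, enc)
            scorers[j] = sc
            if isinstance(sc, _MarkovScorer):
                kord[j] = sc.k
                Cmat[j] = sc.C
                Csel[j] = sc.Csel
                corr[j] = sc.corr
                delta[j] = sc.delta_of_s
                for d, arr in sc.ES.items():
                    ES[j, d] = arr
            da = st.duration.log_prob_array(L)
            dur[j, : len(da)] = da
            finite = np.where(np.isfinite(da))[0]
            if len(finite):
                dmin[j] = int(finite[0])
                dmax[j] = int(finite[-1])
            else:
                dmin[j], dmax[j] = 1, 0

    ones = np.ones((L + 1), dtype=np.int8)
    startok = np.ones((S, L + 1), dtype=np.int8)
    endok = np.ones((S, L + 1), dtype=np.int8)
    occ = np.zeros((S, L + 1), dtype=np.int64)
    has_occ = np.zeros(S, dtype=np.int8)
    if constraints is not None:
        for j, name in enumerate(names):
            sa = constraints.start.get(name)
            if sa is not None:
                startok[j] = sa.astype(np.int8)
            ea = constraints.end.get(name)
            if ea is not None:
                endok[j] = ea.astype(np.int8)
            oc = constraints.occupancy.get(name)
            if oc is not None:
                has_occ[j] = 1
                pref = np.zeros(L + 1, dtype=np.int64)
                pref[1:] = np.cumsum(~oc[1:])
                occ[j] = pref

    V = np.full((S, L + 1), NEG)
    W = np.full((S, L + 1), NEG)
    Wpred = np.full((S, L + 1), -1, dtype=np.int64)
    bp_s = np.full((S, L + 1), -1, dtype=np.int64)
    bp_p = np.full((S, L + 1), -1, dtype=np.int64)

    jbest, fbest, tie = _decode_kernel(
        S, L, logA, logB, logE, is_var, fixlen, fixedE, kord,
        Cmat, Csel, corr, delta, ES, dur, dmin, dmax,
        startok, endok, occ, has_occ, V, W, Wpred, bp_s, bp_p, TIE_EPS,
    )
    if tie:
        return _FALLBACK
    if jbest < 0:
        return None
    segs = []
    j, t = jbest, L
    while t > 0:
        s = int(bp_s[j, t])
        segs.append((s + 1, t, j))
        pj = int(bp_p[j, t])
        t, j = s, pj
    segs = segs[::-1]
    segments = [(names[j], s, e) for s, e, j in segs]
    seg_scores = [float(V[j, e] - W[j, s - 1]) for s, e, j in segs]
    return StatePath(segments, float(fbest), seg_scores)
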