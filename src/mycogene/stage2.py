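"""Stage 2: transcript-constrained GHMM prediction from genome sequence.

The genome-space model adds an intron sub-model (donor, branch point and
acceptor first-order weighted array matrices, joined by variable-length
spacers) and treats UTRs as part of larger intergenic regions.  Reading
frame is carried across introns by expanding the coding-exon state by
entry/exit codon phase and triplicating the intron sub-path by phase;
the donor and acceptor windows extend two nucleotides into the adjacent
exons, so the phase advances by four coding nucleotides across each
intron.

RNA-seq evidence enters prediction through a constraint track: donor and
acceptor boundaries are disallowed wherever a same-strand aligned
transcript exon covers the genome, relaxed within 50 nt of the
transcript's ends, and introns must begin GT and end AG everywhere.

Stage-1 genes that are single-exon or suspected 5'-incomplete (their ORF
extends beyond the supporting transcript) are discarded, and genomic
windows covering the discarded loci, inter-gene flanks and transcript-
free gaps are re-predicted on both strands.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import RunConfig
from .dna import STOP_CODONS, encode, revcomp, translate_has_internal_stop
from .errors import TrainingError
from .formats_io import (FORWARD, REVERSE, UNKNOWN, GeneModel, Genome,
                         TranscriptAlignment, log)
from .ghmm import (DurationModel, GhmmSpec, LiteralMotifSet, MarkovChainModel,
                   State, ViterbiConstraints, WeightedArrayMatrix,
                   fixed_duration, smooth_durations, viterbi)
from .stage1 import Stage1Model, Stage1Result
from .transcript_space import SplicedTranscript, splice

S_INTERGENIC = "intergenic"
S_KOZAK = "kozak"
S_STOP = "stop"


def cds_state(entry: int, exit_: int) -> str:
    return f"cds{entry}{exit_}"


def intron_state(kind: str, phase: int) -> str:
    return f"{kind}{phase}"


# ---------------------------------------------------------------------------
# evidenced introns
# ---------------------------------------------------------------------------

@dataclass
class EvidencedIntron:
    """One intron implied by a transcript alignment, read 5'->3' on the
    transcript's strand, with two exonic context nucleotides each side."""

    contig: str
    start: int           # genomic first intron base (ascending coords)
    end: int             # genomic last intron base
    strand: str
    sequence: str        # oriented intron sequence
    exon_before: str     # oriented 2 nt of upstream exon
    exon_after: str      # oriented 2 nt of downstream exon

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical(self) -> bool:
        return self.sequence.startswith("GT") and self.sequence.endswith("AG")


def collect_evidenced_introns(
    genome: Genome,
    spliced: Sequence[SplicedTranscript],
) -> list[EvidencedIntron]:
    out = []
    seen = set()
    for st in spliced:
        for gs, ge in st.evidenced_introns:
            key = (st.contig, gs, ge, st.strand_used)
            if key in seen:
                continue
            seen.add(key)
            clen = genome.length(st.contig)
            if gs - 2 < 1 or ge + 2 > clen:
                continue
            raw = genome.fetch(st.contig, gs, ge)
            before = genome.fetch(st.contig, gs - 2, gs - 1)
            after = genome.fetch(st.contig, ge + 1, ge + 2)
            if st.strand_used == REVERSE:
                raw, before, after = revcomp(raw), revcomp(after), revcomp(before)
            out.append(EvidencedIntron(st.contig, gs, ge, st.strand_used,
                                       raw, before, after))
    return out


# ---------------------------------------------------------------------------
# boundary-length fitting and the max-intron rule
# ---------------------------------------------------------------------------

def _chi2_scan(columns: list[np.ndarray], interior: np.ndarray,
               crit: float) -> int:
    """Extent (1-based) of the contiguous run of boundary positions
    whose base composition differs significantly from the pooled intron
    interior.  The scan moves outward from the invariant dinucleotide
    and stops at the first non-significant position: splice signals are
    contiguous, and stopping there keeps an isolated chance-significant
    interior column from inflating the boundary."""
    exp_p = interior / interior.sum()
    extent = 0
    for i, col in enumerate(columns, start=1):
        n = col.sum()
        if n < 5:
            break
        expected = exp_p * n
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.nansum((col - expected) ** 2 /
                             np.where(expected > 0, expected, np.nan))
        if stat > crit:
            extent = i
        else:
            break
    return extent


def fit_boundary_lengths(
    introns: Sequence[EvidencedIntron], cfg: RunConfig
) -> tuple[int, int]:
    """Adjust donor/acceptor lengths to the data: extend to the furthest
    position whose composition differs from the adjacent intron interior
    by a chi-square test (df=3) at ``cfg.chi2_p``.  Lengths are totals
    including the 2-nt exon extension, in [4, 22]."""
    usable = [i for i in introns if i.canonical]
    ext = cfg.exon_extension
    if len(usable) < cfg.min_introns_for_fit:
        return cfg.default_donor_len, cfg.default_acceptor_len
    crit = float(stats.chi2.isf(cfg.chi2_p, df=3))
    margin = cfg.interior_margin
    max_in = cfg.donor_max - ext
    # pooled interior composition (>= margin from both ends, capped margin
    # for short introns so the pool is never empty)
    interior = np.zeros(4)
    for it in usable:
        m = min(margin, max(4, (it.length - 6) // 2))
        mid = it.sequence[m : it.length - m]
        e = encode(mid)
        for b in range(4):
            interior[b] += int((e == b).sum())
    if interior.sum() == 0:
        return cfg.default_donor_len, cfg.default_acceptor_len

    def columns(from_start: bool) -> list[np.ndarray]:
        cols = []
        for i in range(max_in):
            col = np.zeros(4)
            for it in usable:
                if it.length <= i + 6:   # keep clear of the other end
                    continue
                base = it.sequence[i] if from_start else it.sequence[-(i + 1)]
                e = "ACGT".find(base)
                if e >= 0:
                    col[e] += 1
            cols.append(col)
        return cols

    donor_in = _chi2_scan(columns(True), interior, crit)
    acceptor_in = _chi2_scan(columns(False), interior, crit)
    donor = min(cfg.donor_max, max(4, donor_in + ext))
    acceptor = min(cfg.acceptor_max, max(4, acceptor_in + ext))
    return donor, acceptor


def max_intron_length(intron_lengths: Sequence[int], cfg: RunConfig) -> int:
    """10% longer than the longest evidenced intron, capped at 5,000
    unless the cap is disabled."""
    if not intron_lengths:
        return cfg.default_max_intron
    m = math.ceil(cfg.intron_factor * max(intron_lengths))
    if cfg.disable_intron_cap:
        return m
    return min(m, cfg.intron_cap)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

@dataclass
class ConstraintTrack:
    """Per-contig, per-strand mask of positions where intron boundaries
    (donor/acceptor sites) may NOT be placed."""

    forbidden: dict[tuple[str, str], np.ndarray]  # (contig, strand) -> bool[len+1]

    def boundary_allowed(self, contig: str, strand: str, pos: int) -> bool:
        arr = self.forbidden.get((contig, strand))
        if arr is None:
            return True
        return not bool(arr[pos])


def build_constraints(
    transcripts: Sequence[TranscriptAlignment],
    genome: Genome,
    stranded: bool,
    cfg: RunConfig,
) -> ConstraintTrack:
    """Boundaries are forbidden where a same-strand transcript exon
    covers the genome, relaxed within ``cfg.relax_nt`` of the transcript
    ends; unstranded alignments constrain both strands."""
    forbidden: dict[tuple[str, str], np.ndarray] = {}

    def arr(contig, strand):
        key = (contig, strand)
        if key not in forbidden:
            forbidden[key] = np.zeros(genome.length(contig) + 1, dtype=bool)
        return forbidden[key]

    for t in transcripts:
        if stranded and t.strand in (FORWARD, REVERSE):
            strands = [t.strand]
        else:
            strands = [FORWARD, REVERSE]
        lo = t.start + cfg.relax_nt
        hi = t.end - cfg.relax_nt
        for s, e in t.exons:
            a, b = max(s, lo), min(e, hi)
            if a > b:
                continue
            for strand in strands:
                arr(t.contig, strand)[a : b + 1] = True
    return ConstraintTrack(forbidden)


# ---------------------------------------------------------------------------
# region selection
# ---------------------------------------------------------------------------

@dataclass
class RegionSelection:
    kept: list[GeneModel]
    discarded: list[tuple[GeneModel, str]]     # reason: single_exon | suspected_incomplete
    windows: list[tuple[str, int, int]]
    alt_windows: list[tuple[str, int, int]]


def _orf_extends_upstream(st: SplicedTranscript, gene: GeneModel) -> bool:
    """True when the reading frame of the gene is open all the way to the
    transcript's 5' end (no in-frame stop upstream of the ATG), i.e. the
    ORF could extend beyond the bounds of the supporting transcript."""
    five_prime_genomic = gene.start if gene.strand == FORWARD else gene.end
    try:
        a = st.from_genome(five_prime_genomic)
    except Exception:
        return True
    pos = a - 3
    seq = st.sequence
    while pos >= 1:
        if seq[pos - 1 : pos + 2] in STOP_CODONS:
            return False
        pos -= 3
    return True


def _readthrough_possible(genome: Genome, st: SplicedTranscript,
                          gs: int, ge: int, pad: int = 30) -> bool:
    """True if some reading frame crosses the intron (gs, ge) without a
    stop codon, i.e. removal of the intron could extend an ORF."""
    lo = max(1, gs - pad)
    hi = min(genome.length(st.contig), ge + pad)
    seq = genome.fetch(st.contig, lo, hi)
    if st.strand_used == REVERSE:
        seq = revcomp(seq)
    for frame in range(3):
        open_frame = True
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                open_frame = False
                break
        if open_frame:
            return True
    return False


def select_regions(
    stage1: Stage1Result,
    genome: Genome,
    cfg: RunConfig,
) -> RegionSelection:
    kept: list[GeneModel] = []
    discarded: list[tuple[GeneModel, str]] = []
    for g in stage1.genes:
        if len(g.cds_segments) == 1:
            discarded.append((g, "single_exon"))
            continue
        parse = stage1.parse_of(g.transcript_id) if g.transcript_id else None
        if parse is not None and _orf_extends_upstream(parse[0], g):
            discarded.append((g, "suspected_incomplete"))
            continue
        kept.append(g)

    # alternative-splice windows: evidenced introns a frame could read
    # through without terminating
    alt_windows = []
    for tid, (st, _path) in stage1.parses.items():
        for gs, ge in st.evidenced_introns:
            if _readthrough_possible(genome, st, gs, ge):
                alt_windows.append(
                    (st.contig,
                     max(1, st.genomic_start - cfg.flank_pad),
                     min(genome.length(st.contig),
                         st.genomic_end + cfg.flank_pad))
                )
                break

    # genomic windows: complement of kept CDS spans, padded
    windows = []
    spans_by_contig: dict[str, list[tuple[int, int]]] = {}
    for g in kept:
        spans_by_contig.setdefault(g.contig, []).append((g.start, g.end))
    for contig in genome.contigs:
        clen = genome.length(contig)
        spans = sorted(spans_by_contig.get(contig, []))
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        pos = 1
        gaps = []
        for s, e in merged:
            if s > pos:
                gaps.append((pos, s - 1))
            pos = e + 1
        if pos <= clen:
            gaps.append((pos, clen))
        pad = cfg.flank_pad
        padded = [
            (max(1, a - pad), min(clen, b + pad)) for a, b in gaps
        ]
        out: list[list[int]] = []
        for a, b in padded:
            if out and a <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        windows.extend((contig, a, b) for a, b in out if b - a + 1 >= 60)
    return RegionSelection(kept, discarded, windows, alt_windows)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class IntronModel:
    donor: WeightedArrayMatrix            # total donor_len incl. 2 exon nt
    acceptor: WeightedArrayMatrix
    branch: WeightedArrayMatrix
    spacer1: MarkovChainModel             # donor -> branch
    spacer2: MarkovChainModel             # branch -> acceptor
    donor_len: int
    acceptor_len: int
    s1_dur: DurationModel
    s2_dur: DurationModel
    min_intron: int
    max_intron: int


@dataclass
class Stage2Model:
    spec: GhmmSpec
    intron: IntronModel
    intergenic_chain: MarkovChainModel
    donor_len: int
    acceptor_len: int


def _clip_duration(dm: DurationModel, lo: int, hi: int) -> DurationModel:
    """Restrict an empirical duration model to [lo, hi] (tails off)."""
    lo = max(lo, 1)
    if hi < lo:
        hi = lo
    a = max(dm.support_min, lo)
    b = min(dm.support_max, hi)
    if a > b:
        # support entirely outside: uniform over [lo, hi]
        n = hi - lo + 1
        return DurationModel(kind="empirical", support_min=lo, support_max=hi,
                             log_pmf=np.full(n, -math.log(n)), tail_mass=0.0)
    pmf = np.exp(dm.log_pmf[a - dm.support_min : b - dm.support_min + 1])
    total = pmf.sum()
    if total <= 0:
        n = b - a + 1
        return DurationModel(kind="empirical", support_min=a, support_max=b,
                             log_pmf=np.full(n, -math.log(n)), tail_mass=0.0)
    with np.errstate(divide="ignore"):
        lp = np.log(pmf / total)
    return DurationModel(kind="empirical", support_min=a, support_max=b,
                         log_pmf=lp, tail_mass=0.0)


def _train_branch(introns: list[EvidencedIntron], cfg: RunConfig,
                  acceptor_in: int) -> tuple[WeightedArrayMatrix, list[tuple[str, int]]]:
    """Locate and model the branch point by a small fixed-iteration EM:
    initialise from every window in the search region, then re-pick the
    best-scoring window per intron and retrain (3 iterations)."""
    bw = cfg.branch_width
    regions = []
    for it in introns:
        n = it.length
        # window must end within [branch_search_min, branch_search_max]
        # nt of the intron 3' end and stay clear of the donor
        lo_end = max(bw + 8, n - cfg.branch_search_max + 1)
        hi_end = n - max(cfg.branch_search_min, acceptor_in)
        if hi_end - bw + 1 < lo_end - bw + 1 or hi_end < lo_end:
            continue
        regions.append((it.sequence, lo_end, hi_end))
    if not regions:
        raise TrainingError("no introns long enough for branch-point search")
    windows = []
    for seq, lo_end, hi_end in regions:
        for end in range(lo_end, hi_end + 1):
            windows.append(seq[end - bw : end])
    wam = WeightedArrayMatrix.train(windows, order=1, pseudocount=cfg.pseudocount)
    assignments: list[tuple[str, int]] = []
    for _ in range(3):
        assignments = []
        best_windows = []
        for seq, lo_end, hi_end in regions:
            best, best_end = None, lo_end
            for end in range(lo_end, hi_end + 1):
                sc = wam.score(seq[end - bw : end])
                if best is None or sc > best:
                    best, best_end = sc, end
            best_windows.append(seq[best_end - bw : best_end])
            assignments.append((seq, best_end))
        wam = WeightedArrayMatrix.train(best_windows, order=1,
                                        pseudocount=cfg.pseudocount)
    return wam, assignments


def train_stage2(
    stage1_model: Stage1Model,
    stage1: Stage1Result,
    genome: Genome,
    cfg: RunConfig,
) -> Stage2Model:
    spliced = [st for st, _ in stage1.parses.values()]
    introns = collect_evidenced_introns(genome, spliced)
    canonical = [i for i in introns if i.canonical]
    donor_len, acceptor_len = fit_boundary_lengths(introns, cfg)
    ext = cfg.exon_extension
    donor_in = donor_len - ext
    acc_in = acceptor_len - ext
    max_intron = max_intron_length([i.length for i in introns], cfg)
    min_intron = cfg.min_intron

    pc = cfg.pseudocount
    if canonical:
        donor_wams = [
            (i.exon_before + i.sequence[:donor_in])
            for i in canonical if i.length >= donor_in + acc_in + 4
        ]
        acceptor_wams = [
            (i.sequence[-acc_in:] + i.exon_after)
            for i in canonical if i.length >= donor_in + acc_in + 4
        ]
        donor = WeightedArrayMatrix.train(donor_wams, order=1, pseudocount=pc)
        acceptor = WeightedArrayMatrix.train(acceptor_wams, order=1, pseudocount=pc)
        branch, assignments = _train_branch(canonical, cfg, acc_in)
        s1_seqs, s2_seqs, s1_lens, s2_lens = [], [], [], []
        bw = cfg.branch_width
        for seq, b_end in assignments:
            s1 = seq[donor_in : b_end - bw]
            s2 = seq[b_end : len(seq) - acc_in]
            if s1:
                s1_seqs.append(s1)
                s1_lens.append(len(s1))
            if s2:
                s2_seqs.append(s2)
                s2_lens.append(len(s2))
        spacer1 = MarkovChainModel.train(
            [(s, 0) for s in s1_seqs] or [("ATAT", 0)], cfg.spacer_order,
            pseudocount=pc, order_quota=cfg.order_quota)
        spacer2 = MarkovChainModel.train(
            [(s, 0) for s in s2_seqs] or [("ATAT", 0)], cfg.spacer_order,
            pseudocount=pc, order_quota=cfg.order_quota)
    else:
        # canonical fallback: consensus-only splice models
        log("[stage2] no canonical evidenced introns; using canonical "
            "default intron model", 1, cfg.verbosity)
        donor = WeightedArrayMatrix.train(
            ["NN" + "GTAAGT"[:donor_in]], order=1, pseudocount=0.25)
        acceptor = WeightedArrayMatrix.train(
            ["TTACAG"[-acc_in:] + "NN"], order=1, pseudocount=0.25)
        branch = WeightedArrayMatrix.train(
            ["CTAACTT"[: cfg.branch_width]], order=1, pseudocount=0.25)
        spacer1 = spacer2 = stage1_model.utr_chain
        s1_lens, s2_lens = [30], [15]

    bw = cfg.branch_width
    s2_lo = max(1, cfg.branch_search_min - acc_in)
    s2_hi = max(s2_lo, cfg.branch_search_max - acc_in - bw)
    s2_dur = _clip_duration(
        smooth_durations(s2_lens or [10]), s2_lo, s2_hi)
    s1_lo = max(1, min_intron - donor_in - bw - s2_lo - acc_in)
    s1_hi = max(s1_lo, max_intron - donor_in - bw - s2_hi - acc_in)
    s1_dur = _clip_duration(
        smooth_durations(s1_lens or [30]), s1_lo, s1_hi)

    intron_model = IntronModel(donor, acceptor, branch, spacer1, spacer2,
                               donor_len, acceptor_len, s1_dur, s2_dur,
                               min_intron, max_intron)

    # intergenic chain: sequence near transcripts but outside stage-1 genes
    gene_mask: dict[str, np.ndarray] = {
        c: np.zeros(genome.length(c) + 2, dtype=bool) for c in genome.contigs
    }
    near_mask: dict[str, np.ndarray] = {
        c: np.zeros(genome.length(c) + 2, dtype=bool) for c in genome.contigs
    }
    for g in stage1.genes:
        gene_mask[g.contig][g.start : g.end + 1] = True
    for st in spliced:
        a = max(1, st.genomic_start - cfg.flank_pad)
        b = min(genome.length(st.contig), st.genomic_end + cfg.flank_pad)
        near_mask[st.contig][a : b + 1] = True
    intergenic_seqs = []
    for contig in genome.contigs:
        keep = near_mask[contig] & ~gene_mask[contig]
        seq = genome.contigs[contig]
        run_start = None
        for i in range(1, len(seq) + 2):
            if i <= len(seq) and keep[i]:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start >= 20:
                    intergenic_seqs.append(seq[run_start - 1 : i - 1])
                run_start = None
    if not intergenic_seqs:
        intergenic_seqs = [genome.contigs[c][:2000] for c in genome.contigs]
    intergenic_chain = MarkovChainModel.train(
        [(s, 0) for s in intergenic_seqs], cfg.utr_order, pseudocount=pc,
        order_quota=cfg.order_quota, n_floor=cfg.n_floor_logprob)

    # durations
    exon_lens = []
    n_introns = 0
    for g in stage1.genes:
        for s, e, _ in g.cds_segments:
            exon_lens.append(e - s + 1)
        n_introns += len(g.cds_segments) - 1
    if cfg.retrain_cds_stage2:
        bodies = [g.spliced_cds(genome)[3:-3] for g in stage1.genes
                  if g.cds_length >= cfg.min_cds_train]
        cds_chain = MarkovChainModel.train(
            [(s, 0) for s in bodies], cfg.cds_order, periodicity=3,
            pseudocount=pc, order_quota=cfg.order_quota)
    else:
        cds_chain = stage1_model.cds_chain
    exon_dur = smooth_durations(exon_lens or [400])
    gaps = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in stage1.genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig, gs in by_contig.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            gap = b.start - a.end - 1
            if gap > 0:
                gaps.append(gap)
    intergenic_dur = smooth_durations(gaps or [300])

    n_genes = max(1, len(stage1.genes))
    p_intron = n_introns / max(1, n_introns + n_genes)

    states = [
        State(S_INTERGENIC, intergenic_chain, intergenic_dur),
        State(S_KOZAK, stage1_model.kozak, fixed_duration(cfg.kozak_window)),
        State(S_STOP, stage1_model.stop_motif, fixed_duration(3)),
    ]
    transitions: dict[tuple[str, str], float] = {}
    begin = {S_INTERGENIC: 1.0}
    end = {S_INTERGENIC: 0.9, S_STOP: 0.1}
    transitions[(S_INTERGENIC, S_KOZAK)] = 0.5
    # intergenic -> end carries the rest (see `end`)
    end[S_INTERGENIC] = 0.5
    transitions[(S_STOP, S_INTERGENIC)] = 0.9

    for p in range(3):
        for q in range(3):
            name = cds_state(p, q)
            dur = dataclasses.replace(exon_dur, modulus=3, residue=(q - p) % 3)
            states.append(State(name, cds_chain, dur, start_phase=p))
            transitions[(S_KOZAK, cds_state(0, q))] = 1.0 / 3.0
    for q in range(3):
        d = intron_state("donor", q)
        s1 = intron_state("spacer1", q)
        br = intron_state("branch", q)
        s2 = intron_state("spacer2", q)
        ac = intron_state("acceptor", q)
        states.append(State(d, intron_model.donor, fixed_duration(donor_len),
                            start_phase=q))
        states.append(State(s1, intron_model.spacer1, intron_model.s1_dur))
        states.append(State(br, intron_model.branch, fixed_duration(bw)))
        states.append(State(s2, intron_model.spacer2, intron_model.s2_dur))
        states.append(State(ac, intron_model.acceptor,
                            fixed_duration(acceptor_len)))
        transitions[(d, s1)] = 1.0
        transitions[(s1, br)] = 1.0
        transitions[(br, s2)] = 1.0
        transitions[(s2, ac)] = 1.0
        entry = (q + 1) % 3
        for q2 in range(3):
            transitions[(ac, cds_state(entry, q2))] = 1.0 / 3.0
        for p in range(3):
            if q == 0:
                transitions[(cds_state(p, 0), S_STOP)] = 1.0 - p_intron
                transitions[(cds_state(p, 0), d)] = p_intron
            else:
                transitions[(cds_state(p, q), d)] = 1.0

    spec = GhmmSpec(states, transitions, begin, end)
    spec.validate()
    return Stage2Model(spec, intron_model, intergenic_chain,
                       donor_len, acceptor_len)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _window_constraints(
    model: Stage2Model,
    seq: str,
    contig: str,
    w_start: int,
    w_end: int,
    strand: str,
    track: Optional[ConstraintTrack],
) -> ViterbiConstraints:
    """Donor states may only start where the intron would begin with GT
    at an allowed boundary; acceptor states may only end where the intron
    ends AG at an allowed boundary."""
    L = len(seq)
    cons = ViterbiConstraints(L)
    enc = encode(seq)
    # gt[p]: intron may START at local 1-based p; ag[p]: intron may END at p
    gt = np.zeros(L + 2, dtype=bool)
    ag = np.zeros(L + 2, dtype=bool)
    if L >= 2:
        first, second = enc[:-1], enc[1:]
        gt[1:L] = (first == 2) & (second == 3)
        ag[2 : L + 1] = (first == 0) & (second == 2)
    if track is not None:
        arr = track.forbidden.get((contig, strand))
        if arr is not None:
            if strand == FORWARD:
                allowed = ~arr[w_start : w_end + 1]
            else:
                allowed = ~arr[w_start : w_end + 1][::-1]
            ok = np.zeros(L + 2, dtype=bool)
            ok[1 : L + 1] = allowed
            gt &= ok
            ag &= ok
    pos = np.arange(L + 2)
    donor_starts = (pos[gt] - 2)
    donor_starts = donor_starts[donor_starts >= 1]
    acceptor_ends = (pos[ag] + 2)
    acceptor_ends = acceptor_ends[acceptor_ends <= L]
    for q in range(3):
        cons.restrict_starts(intron_state("donor", q), donor_starts)
        cons.restrict_ends(intron_state("acceptor", q), acceptor_ends)
    return cons


@dataclass
class _WindowGene:
    segments: list[tuple[int, int]]   # local CDS segments
    score: float
    introns: list[tuple[int, int, float]] = None  # (local lo, hi, sub-path score)


def _genes_from_path(path) -> list[_WindowGene]:
    """Collect kozak..stop runs of a window parse as local gene models.

    The CDS includes the ATG (last 3 nt of the kozak window) through the
    stop codon; each intron spans donor_start+2 .. acceptor_end-2 (the
    donor/acceptor windows each keep 2 exonic nucleotides)."""
    out = []
    segs = path.segments
    n = len(segs)
    i = 0
    while i < n:
        name, _s, e = segs[i]
        if name != S_KOZAK:
            i += 1
            continue
        start_idx = i
        cds_segs: list[tuple[int, int]] = []
        introns: list[tuple[int, int, float]] = []
        cur_start = e - 2
        j = i + 1
        ok = False
        intron_lo = intron_score = None
        while j < n:
            nm, a, b = segs[j]
            if nm.startswith(("cds", "spacer", "branch")):
                if intron_lo is not None and not nm.startswith("cds"):
                    intron_score += (path.segment_scores[j]
                                     if path.segment_scores else 0.0)
                j += 1
            elif nm.startswith("donor"):
                cds_segs.append((cur_start, a + 1))
                intron_lo = a + 2      # first intron base
                intron_score = (path.segment_scores[j]
                                if path.segment_scores else 0.0)
                j += 1
            elif nm.startswith("acceptor"):
                cur_start = b - 1
                if intron_lo is not None:
                    intron_score += (path.segment_scores[j]
                                     if path.segment_scores else 0.0)
                    introns.append((intron_lo, b - 2, intron_score))
                    intron_lo = intron_score = None
                j += 1
            elif nm == S_STOP:
                cds_segs.append((cur_start, b))
                ok = True
                j += 1
                break
            else:
                break
        if ok and all(a <= b for a, b in cds_segs):
            score = (sum(path.segment_scores[start_idx:j])
                     if path.segment_scores else 0.0)
            out.append(_WindowGene(cds_segs, score, introns))
        i = j if j > i else i + 1
    return out


def predict_stage2(
    model: Stage2Model,
    selection: RegionSelection,
    track: Optional[ConstraintTrack],
    genome: Genome,
    cfg: RunConfig,
) -> list[GeneModel]:
    """Decode every selected genomic window on both strands; where the
    two strands' genes overlap in CDS, the higher-scoring one wins."""
    genes: list[GeneModel] = []
    windows = list(selection.windows) + [
        w for w in selection.alt_windows if w not in selection.windows
    ]
    for contig, ws, we in windows:
        fwd_seq = genome.fetch(contig, ws, we)
        cand: list[GeneModel] = []
        for strand in (FORWARD, REVERSE):
            seq = fwd_seq if strand == FORWARD else revcomp(fwd_seq)
            cons = _window_constraints(
                model, seq, contig, ws, we, strand, track)
            path = viterbi(model.spec, seq, cons)
            if path is None:
                continue
            for wg in _genes_from_path(path):
                lo = min(a for a, _ in wg.segments)
                hi = max(b for _, b in wg.segments)
                # gene evidence as log-odds against the intergenic model
                # over the same span: comparable across gene lengths
                bg = model.intergenic_chain.score(seq[lo - 1 : hi])
                odds = wg.score - bg
                if odds < cfg.min_stage2_odds:
                    continue
                # each intron must itself beat the background: rejects
                # fake introns placed only to dodge in-frame stop codons
                weak_intron = False
                for ilo, ihi, iscore in (wg.introns or []):
                    ibg = model.intergenic_chain.score(seq[ilo - 1 : ihi])
                    if iscore - ibg < cfg.min_intron_odds:
                        weak_intron = True
                        break
                if weak_intron:
                    continue
                # the 2-nt exon extensions of the splice windows are not
                # scored by the coding chain, so an in-frame stop can
                # slip through there: reject such invalid structures
                spliced = "".join(seq[a - 1 : b] for a, b in wg.segments)
                if translate_has_internal_stop(spliced):
                    continue
                if strand == FORWARD:
                    g_segs = [(ws + a - 1, ws + b - 1) for a, b in wg.segments]
                else:
                    g_segs = sorted(
                        (we - b + 1, we - a + 1) for a, b in wg.segments
                    )
                try:
                    gm = GeneModel(
                        gene_id="", contig=contig, strand=strand,
                        cds_segments=[(a, b, 0) for a, b in g_segs],
                        provenance="stage2", score=odds,
                    ).with_phases()
                except Exception:
                    continue
                cand.append(gm)
        # reconcile CDS overlaps between the two strand decodings:
        # stronger evidence (higher odds) wins
        cand.sort(key=lambda g: -(g.score or 0.0))
        chosen: list[GeneModel] = []
        for g in cand:
            clash = any(
                g.contig == h.contig and not (g.end < h.start or g.start > h.end)
                and _cds_overlap(g, h) > 0
                for h in chosen
            )
            if not clash:
                chosen.append(g)
        genes.extend(chosen)
    # windows may overlap (alt-splice windows): where two stage-2 genes
    # overlap in CDS on the same strand, keep the higher-odds one
    unique: list[GeneModel] = []
    seen = set()
    for g in sorted(genes, key=lambda g: -(g.score or 0.0)):
        key = g.segments_key()
        if key in seen:
            continue
        clash = any(
            g.contig == h.contig and g.strand == h.strand
            and not (g.end < h.start or g.start > h.end)
            and _cds_overlap(g, h) > 0
            for h in unique
        )
        if clash:
            continue
        seen.add(key)
        unique.append(g)
    unique.sort(key=lambda g: (g.contig, g.start))
    for i, g in enumerate(unique, start=1):
        g.gene_id = f"s2.{i:04d}"
    return unique


def _cds_overlap(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for s1, e1, _ in a.cds_segments:
        for s2, e2, _ in b.cds_segments:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total
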