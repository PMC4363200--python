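"""Stage 1: self-training GHMM prediction from spliced transcripts.

The transcript-space model reads a virtually spliced transcript 5'->3'
through the states

    begin -> [5'UTR] -> kozak(11 nt, ends at ATG) -> CDS -> stop codon
          -> [3'UTR | middle-UTR -> kozak -> ...] -> end
    begin -> noncoding transcript -> end

The middle-UTR state lets one transcript carry several same-direction
genes, which is how merged transcript assemblies (overlapping UTRs of
adjacent loci) are handled.  Training is unsupervised: parameters are
seeded from the longest Met-initiated ORF of each transcript and the
model is successively run and retrained a fixed number of times, with
conservative restrictions on what enters the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .config import RunConfig
from .dna import STOP_CODONS
from .errors import TrainingError
from .formats_io import FORWARD, GeneModel, Genome, TranscriptAlignment, log
from .ghmm import (DurationModel, GhmmSpec, LiteralMotifSet, MarkovChainModel,
                   State, StatePath, WeightedArrayMatrix, fixed_duration,
                   smooth_durations, viterbi)
from .transcript_space import SplicedTranscript, find_orfs, longest_met_orf, splice

STATE_UTR5 = "utr5"
STATE_KOZAK = "kozak"
STATE_CDS = "cds"
STATE_STOP = "stop"
STATE_UTR3 = "utr3"
STATE_MID = "mid_utr"
STATE_NONCODING = "noncoding"

OrientedTranscript = Union[SplicedTranscript, tuple[SplicedTranscript, SplicedTranscript]]


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

@dataclass
class _Candidate:
    """Per-transcript training material before restriction filtering."""

    st: SplicedTranscript
    genes: list[tuple[int, int]]          # CDS intervals (ATG..stop) in t-space
    utr5: Optional[str] = None
    utr3: Optional[str] = None
    middles: list[str] = field(default_factory=list)
    noncoding: bool = False


@dataclass
class TrainingSet:
    cds_bodies: list[str] = field(default_factory=list)   # between ATG and stop
    stop_codons: list[str] = field(default_factory=list)
    kozak_windows: list[str] = field(default_factory=list)
    utr5_examples: list[str] = field(default_factory=list)
    utr3_examples: list[str] = field(default_factory=list)
    middle_examples: list[str] = field(default_factory=list)
    noncoding_examples: list[str] = field(default_factory=list)
    cds_lengths: list[int] = field(default_factory=list)   # body lengths
    utr5_lengths: list[int] = field(default_factory=list)
    utr3_lengths: list[int] = field(default_factory=list)
    middle_lengths: list[int] = field(default_factory=list)
    noncoding_lengths: list[int] = field(default_factory=list)
    # structural counts for transition estimation
    n_with_utr5: int = 0
    n_without_utr5: int = 0
    n_with_utr3: int = 0
    n_without_utr3: int = 0
    n_middles: int = 0
    n_noncoding: int = 0

    def summary(self) -> str:
        return (f"{len(self.cds_bodies)} CDS, {len(self.kozak_windows)} Kozak "
                f"windows, {len(self.utr5_examples)+len(self.utr3_examples)} UTR, "
                f"{len(self.noncoding_examples)} noncoding examples")


def _excise_long_orfs(seq: str, max_orf: int) -> list[str]:
    """Remove every ORF of length >= max_orf (including ORFs running off
    the 3' end) from a UTR example, returning the remaining pieces."""
    drops = [
        (o.start, o.end) for o in find_orfs(seq) if o.length >= max_orf
    ]
    if not drops:
        return [seq] if seq else []
    keep = []
    pos = 1
    for s, e in sorted(drops):
        if s > pos:
            keep.append(seq[pos - 1 : s - 1])
        pos = max(pos, e + 1)
    if pos <= len(seq):
        keep.append(seq[pos - 1 :])
    return [k for k in keep if k]


def _drop_overlapping(cands: list[_Candidate]) -> set[tuple[str, int]]:
    """Return keys (transcript_id, gene_index) of genes to drop because a
    longer gene's genomic CDS span overlaps theirs."""
    spans = []
    for c in cands:
        for gi, (a, b) in enumerate(c.genes):
            segs = c.st.lift_to_genome(a, b)
            spans.append((c.st.contig, segs[0][0], segs[-1][1], b - a + 1,
                          (c.st.transcript_id, gi)))
    spans.sort(key=lambda x: (-x[3], x[1]))  # longest first
    kept: dict[str, list[tuple[int, int]]] = {}
    dropped = set()
    for contig, s, e, _ln, key in spans:
        clash = any(not (e < ks or s > ke) for ks, ke in kept.get(contig, []))
        if clash:
            dropped.add(key)
        else:
            kept.setdefault(contig, []).append((s, e))
    return dropped


def build_training_set(cands: list[_Candidate], cfg: RunConfig) -> TrainingSet:
    """Apply the self-training restrictions and assemble a TrainingSet.

    CDS examples must be >= ``cfg.min_cds_train`` nt; UTR examples have
    ORFs >= ``cfg.max_utr_orf`` nt excised; where training genes overlap
    on the genome only the longest is retained.
    """
    ts = TrainingSet()
    dropped = _drop_overlapping([c for c in cands if c.genes])
    for c in cands:
        if c.noncoding or not c.genes:
            ts.noncoding_examples.append(c.st.sequence)
            ts.noncoding_lengths.append(len(c.st.sequence))
            ts.n_noncoding += 1
            continue
        for gi, (a, b) in enumerate(c.genes):
            if (c.st.transcript_id, gi) in dropped:
                continue
            if b - a + 1 < cfg.min_cds_train:
                continue
            cds = c.st.sequence[a - 1 : b]
            ts.cds_bodies.append(cds[3:-3])
            ts.stop_codons.append(cds[-3:])
            ts.cds_lengths.append(len(cds) - 6)
            up = cfg.kozak_window - 3
            if a - 1 >= up:
                ts.kozak_windows.append(c.st.sequence[a - 1 - up : a + 2])
        if c.utr5 is not None:
            ts.n_with_utr5 += 1 if len(c.utr5) > 0 else 0
            ts.n_without_utr5 += 1 if len(c.utr5) == 0 else 0
            if c.utr5:
                ts.utr5_lengths.append(len(c.utr5))
                ts.utr5_examples.extend(
                    _excise_long_orfs(c.utr5, cfg.max_utr_orf))
        if c.utr3 is not None:
            ts.n_with_utr3 += 1 if len(c.utr3) > 0 else 0
            ts.n_without_utr3 += 1 if len(c.utr3) == 0 else 0
            if c.utr3:
                ts.utr3_lengths.append(len(c.utr3))
                ts.utr3_examples.extend(
                    _excise_long_orfs(c.utr3, cfg.max_utr_orf))
        for m in c.middles:
            ts.n_middles += 1
            if m:
                ts.middle_lengths.append(len(m))
                ts.middle_examples.extend(_excise_long_orfs(m, cfg.max_utr_orf))
    if not ts.cds_bodies:
        raise TrainingError(
            "no coding training examples survived filtering; supply more "
            "transcripts or lower min_cds_train"
        )
    return ts


def seed_training_set(
    oriented: Sequence[OrientedTranscript], cfg: RunConfig
) -> TrainingSet:
    """Initial training set: the longest Met-ORF of each transcript is a
    candidate gene, its flanks are UTR examples, ORF-less transcripts are
    noncoding examples."""
    cands = []
    for item in oriented:
        st = _seed_orientation(item)
        orf = longest_met_orf(st.sequence)
        if orf is None or orf.length < 3 * (cfg.min_protein_aa + 1):
            cands.append(_Candidate(st, [], noncoding=True))
            continue
        cands.append(_Candidate(
            st,
            genes=[(orf.start, orf.end)],
            utr5=st.sequence[: orf.start - 1],
            utr3=st.sequence[orf.end :],
        ))
    return build_training_set(cands, cfg)


def _seed_orientation(item: OrientedTranscript) -> SplicedTranscript:
    """For unknown-strand transcripts, seed from the orientation with the
    longer Met-ORF (forward on ties)."""
    if not isinstance(item, tuple):
        return item
    fwd, rev = item
    of = longest_met_orf(fwd.sequence)
    orv = longest_met_orf(rev.sequence)
    lf = of.length if of else 0
    lr = orv.length if orv else 0
    return rev if lr > lf else fwd


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

@dataclass
class Stage1Model:
    spec: GhmmSpec
    cds_chain: MarkovChainModel
    utr_chain: MarkovChainModel
    utr3_chain: MarkovChainModel           # == utr_chain unless separated
    noncoding_chain: MarkovChainModel
    kozak: WeightedArrayMatrix
    stop_motif: LiteralMotifSet
    durations: dict[str, DurationModel]


def train_stage1(ts: TrainingSet, cfg: RunConfig) -> Stage1Model:
    pc = cfg.pseudocount
    cds_chain = MarkovChainModel.train(
        [(s, 0) for s in ts.cds_bodies], cfg.cds_order, periodicity=3,
        pseudocount=pc, order_quota=cfg.order_quota,
        n_floor=cfg.n_floor_logprob,
    )
    utr_pool = ts.utr5_examples + ts.middle_examples
    utr3_pool = ts.utr3_examples
    if not cfg.separate_utr_tables:
        utr_pool = utr_pool + utr3_pool
    if not utr_pool:
        utr_pool = ts.noncoding_examples or ts.cds_bodies
    utr_chain = MarkovChainModel.train(
        [(s, 0) for s in utr_pool], cfg.utr_order, periodicity=1,
        pseudocount=pc, order_quota=cfg.order_quota,
        n_floor=cfg.n_floor_logprob,
    )
    if cfg.separate_utr_tables and utr3_pool:
        utr3_chain = MarkovChainModel.train(
            [(s, 0) for s in utr3_pool], cfg.utr_order, periodicity=1,
            pseudocount=pc, order_quota=cfg.order_quota,
            n_floor=cfg.n_floor_logprob,
        )
    else:
        utr3_chain = utr_chain
    if ts.noncoding_examples:
        noncoding_chain = MarkovChainModel.train(
            [(s, 0) for s in ts.noncoding_examples], cfg.utr_order,
            periodicity=1, pseudocount=pc, order_quota=cfg.order_quota,
            n_floor=cfg.n_floor_logprob,
        )
    else:
        noncoding_chain = utr_chain
    if ts.kozak_windows:
        kozak = WeightedArrayMatrix.train(
            ts.kozak_windows, cfg.kozak_order, pseudocount=pc)
        kozak.anchor = "ATG"     # the start window must end at a real ATG
    else:
        raise TrainingError("no Kozak windows in training set")
    stop_motif = LiteralMotifSet.train(ts.stop_codons, STOP_CODONS)

    def dur(lengths, fallback, modulus=1, residue=0):
        if not lengths:
            lengths = fallback
        bw = cfg.duration_bandwidth or None
        return smooth_durations(lengths, bandwidth=bw, modulus=modulus,
                                residue=residue)

    durations = {
        STATE_CDS: dur(ts.cds_lengths, [600], modulus=3, residue=0),
        STATE_UTR5: dur(ts.utr5_lengths, [50]),
        STATE_UTR3: dur(ts.utr3_lengths, [80]),
        STATE_MID: dur(ts.middle_lengths, ts.utr5_lengths + ts.utr3_lengths or [100]),
        STATE_NONCODING: dur(ts.noncoding_lengths, [500]),
        STATE_KOZAK: fixed_duration(cfg.kozak_window),
        STATE_STOP: fixed_duration(3),
    }

    # transition estimation: adjacency counts from the training parses
    # with pseudocount 1
    n_coding = max(1, len(ts.cds_bodies))
    b_utr5 = ts.n_with_utr5 + 1
    b_kozak = ts.n_without_utr5 + 1
    b_nc = ts.n_noncoding + 1
    btot = b_utr5 + b_kozak + b_nc
    s_utr3 = ts.n_with_utr3 + 1
    s_mid = ts.n_middles + 1
    s_end = ts.n_without_utr3 + 1
    stot = s_utr3 + s_mid + s_end

    states = [
        State(STATE_UTR5, utr_chain, durations[STATE_UTR5]),
        State(STATE_KOZAK, kozak, durations[STATE_KOZAK]),
        State(STATE_CDS, cds_chain, durations[STATE_CDS], start_phase=0),
        State(STATE_STOP, stop_motif, durations[STATE_STOP]),
        State(STATE_UTR3, utr3_chain, durations[STATE_UTR3]),
        State(STATE_MID, utr_chain, durations[STATE_MID]),
        State(STATE_NONCODING, noncoding_chain, durations[STATE_NONCODING]),
    ]
    transitions = {
        (STATE_UTR5, STATE_KOZAK): 1.0,
        (STATE_KOZAK, STATE_CDS): 1.0,
        (STATE_CDS, STATE_STOP): 1.0,
        (STATE_STOP, STATE_UTR3): s_utr3 / stot,
        (STATE_STOP, STATE_MID): s_mid / stot,
        (STATE_MID, STATE_KOZAK): 1.0,
    }
    begin = {
        STATE_UTR5: b_utr5 / btot,
        STATE_KOZAK: b_kozak / btot,
        STATE_NONCODING: b_nc / btot,
    }
    end = {
        STATE_STOP: s_end / stot,
        STATE_UTR3: 1.0,
        STATE_NONCODING: 1.0,
    }
    spec = GhmmSpec(states, transitions, begin, end)
    spec.validate()
    return Stage1Model(spec, cds_chain, utr_chain, utr3_chain,
                       noncoding_chain, kozak, stop_motif, durations)


def spec_without_noncoding(model: Stage1Model) -> GhmmSpec:
    """The stage-1 spec with the noncoding-transcript transition zeroed
    (used for forced 'dubious' predictions)."""
    begin = dict(model.spec.begin)
    nc = begin.pop(STATE_NONCODING, 0.0)
    tot = sum(begin.values())
    begin = {k: v / tot for k, v in begin.items()}
    return GhmmSpec(model.spec.states, dict(model.spec.transitions),
                    begin, dict(model.spec.end))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class Stage1Result:
    genes: list[GeneModel]
    parses: dict[str, tuple[SplicedTranscript, StatePath]]

    def parse_of(self, transcript_id: str):
        return self.parses.get(transcript_id)


def _extract_genes(st: SplicedTranscript, path: StatePath,
                   provenance: str = "stage1",
                   model: Optional["Stage1Model"] = None) -> list[GeneModel]:
    """Turn kozak->cds->stop runs of a parse into genome-space genes.

    Gene scores are log-odds of the gene sub-path against the UTR
    background model over the same interval, so they are comparable
    across gene lengths and with stage-2 scores."""
    genes = []
    segs = path.segments
    for i, (name, s, e) in enumerate(segs):
        if name != STATE_KOZAK:
            continue
        # kozak ends at the ATG; expect cds then stop
        if i + 2 >= len(segs):
            continue
        cname, cs, ce = segs[i + 1]
        sname, ss, se = segs[i + 2]
        if cname != STATE_CDS or sname != STATE_STOP:
            continue
        score = sum(path.segment_scores[i : i + 3]) if path.segment_scores else None
        a, b = e - 2, se
        if score is not None and model is not None:
            score -= model.utr_chain.score(st.sequence[a - 1 : b])
        g_segs = st.lift_to_genome(a, b)
        gene = GeneModel(
            gene_id="",
            contig=st.contig,
            strand=st.strand_used,
            cds_segments=[(gs, ge, 0) for gs, ge in g_segs],
            transcript_id=st.transcript_id,
            provenance=provenance,
            complete5prime=True,
            complete3prime=True,
            score=score,
        ).with_phases()
        genes.append(gene)
    return genes


def predict_stage1(
    model: Stage1Model,
    oriented: Sequence[OrientedTranscript],
    cfg: RunConfig,
    provenance: str = "stage1",
    spec: Optional[GhmmSpec] = None,
) -> Stage1Result:
    """Viterbi-parse every transcript (both orientations when the strand
    is unknown, keeping the higher-scoring parse; forward on ties)."""
    spec = spec or model.spec
    genes: list[GeneModel] = []
    parses: dict[str, tuple[SplicedTranscript, StatePath]] = {}
    for item in oriented:
        if isinstance(item, tuple):
            best = None
            for st in item:          # (forward, reverse): forward wins ties
                path = viterbi(spec, st.sequence)
                if path is None:
                    continue
                if best is None or path.log_prob > best[1].log_prob:
                    best = (st, path)
            if best is None:
                continue
            st, path = best
        else:
            st = item
            path = viterbi(spec, st.sequence)
            if path is None:
                continue
        parses[st.transcript_id] = (st, path)
        genes.extend(_extract_genes(st, path, provenance, model))
    ordered = sorted(genes, key=lambda g: (g.contig, g.start))
    for i, g in enumerate(ordered, start=1):
        g.gene_id = f"s1.{i:04d}"
    return Stage1Result(ordered, parses)


def training_set_from_parses(result: Stage1Result, cfg: RunConfig) -> TrainingSet:
    """Rebuild the training set from the current predictions, applying
    the same restrictions as at seeding."""
    cands = []
    for tid, (st, path) in result.parses.items():
        genes = []
        utr5 = utr3 = ""
        middles = []
        has_utr5 = False
        for i, (name, s, e) in enumerate(path.segments):
            if name == STATE_KOZAK:
                if (i + 2 < len(path.segments)
                        and path.segments[i + 1][0] == STATE_CDS
                        and path.segments[i + 2][0] == STATE_STOP):
                    genes.append((e - 2, path.segments[i + 2][2]))
            elif name == STATE_UTR5:
                utr5 = st.sequence[s - 1 : e]
                has_utr5 = True
            elif name == STATE_UTR3:
                utr3 = st.sequence[s - 1 : e]
            elif name == STATE_MID:
                middles.append(st.sequence[s - 1 : e])
        if not genes:
            cands.append(_Candidate(st, [], noncoding=True))
        else:
            cands.append(_Candidate(st, genes, utr5=utr5, utr3=utr3,
                                    middles=middles))
    return build_training_set(cands, cfg)


def orient_transcripts(
    genome: Genome,
    alignments: Sequence[TranscriptAlignment],
) -> list[OrientedTranscript]:
    """Splice every alignment; unknown-strand alignments yield both
    orientations for downstream competition."""
    return [splice(genome, aln) for aln in alignments]


def self_train(
    genome: Genome,
    alignments: Sequence[TranscriptAlignment],
    cfg: RunConfig,
) -> tuple[Stage1Model, Stage1Result, list[str]]:
    """Seed from longest ORFs, then run and retrain the GHMM exactly
    ``cfg.retrain_iterations`` times; returns the final model, final
    predictions and a per-iteration log."""
    oriented = orient_transcripts(genome, alignments)
    history: list[str] = []
    ts = seed_training_set(oriented, cfg)
    history.append(f"seed: {ts.summary()}")
    model = train_stage1(ts, cfg)
    for it in range(1, cfg.retrain_iterations + 1):
        result = predict_stage1(model, oriented, cfg)
        ts = training_set_from_parses(result, cfg)
        history.append(f"iteration {it}: {ts.summary()}")
        model = train_stage1(ts, cfg)
    result = predict_stage1(model, oriented, cfg)
    history.append(f"final: {len(result.genes)} stage-1 genes")
    for line in history:
        log("[stage1] " + line, 2, cfg.verbosity)
    return model, result, history
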