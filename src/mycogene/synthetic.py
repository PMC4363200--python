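"""Seeded synthetic fungal genomes with imperfect transcript assemblies.

The generator emulates the phenomena the two-stage predictor targets in
a compact, gene-dense genome with short introns:

* codon-biased coding sequences drawn codon-by-codon from a seeded
  biased codon distribution (so the true three-periodic conditionals are
  known in closed form and parameter recovery can be checked);
* a Kozak-like consensus context upstream of each ATG;
* GT..AG introns with planted donor/branch/acceptor signals and an
  AT-rich interior;
* transcript "assemblies" equal to the genes plus UTRs, optionally
  corrupted: 5'-truncated, merged with a same-strand neighbour through
  overlapping UTRs, merged tail-to-tail with an antisense neighbour
  (unstranded data), carrying a false-positive intron, or missing
  entirely (unexpressed gene).

Every corruption type is individually switchable so each pipeline
mechanism has an isolating fixture.  Output is deterministic under a
fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dna import STOP_CODONS, revcomp
from .errors import ConfigError
from .formats_io import (FORWARD, REVERSE, UNKNOWN, GeneModel, Genome,
                         TranscriptAlignment)

BASES = "ACGT"
SENSE_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]


@dataclass
class SynthParams:
    seed: int = 1
    n_genes: int = 200
    contig_id: str = "chr1"
    contig_length: Optional[int] = None     # optional cap; error if exceeded
    edge_pad: int = 500
    stranded: bool = True

    # geometry (1-based inclusive uniform ranges)
    intergenic_range: tuple[int, int] = (150, 600)
    utr5_range: tuple[int, int] = (30, 150)
    utr3_range: tuple[int, int] = (50, 200)
    cds_codons_range: tuple[int, int] = (120, 650)
    intron_length_range: tuple[int, int] = (40, 200)
    exons_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.20}
    )
    min_internal_exon: int = 30

    # sequence composition
    codon_bias_conc: float = 1.0       # Dirichlet concentration over 61 codons
    codon_gc_tilt: float = 1.5         # weight multiplier per G/C in a codon:
                                       # coding is GC-richer than the AT-rich
                                       # intergenic background, as in real
                                       # fungal genomes
    kozak_consensus: str = "AAACAAAA"  # 8 nt immediately upstream of ATG
    kozak_strength: float = 0.7
    donor_consensus: str = "GTAAGT"    # first 6 intron nt (GT fixed)
    acceptor_consensus: str = "TTACAG" # last 6 intron nt (AG fixed)
    splice_strength: float = 0.85
    branch_consensus: str = "CTAAC"    # CTRAC-like branch point
    branch_strength: float = 0.9
    intron_interior_probs: tuple[float, ...] = (0.35, 0.15, 0.15, 0.35)

    # corruption fractions (of genes)
    frac_expressed: float = 0.9
    frac_truncated5: float = 0.05
    frac_merged_same: float = 0.05
    frac_merged_sas: float = 0.05      # applied only in unstranded mode
    frac_fp_intron: float = 0.0

    def validate(self) -> None:
        for name in ("frac_expressed", "frac_truncated5", "frac_merged_same",
                     "frac_merged_sas", "frac_fp_intron"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        unexpr = 1.0 - self.frac_expressed
        if self.frac_truncated5 + self.frac_fp_intron + unexpr > 1.0:
            raise ConfigError("corruption fractions jointly infeasible")
        if abs(sum(self.exons_per_gene.values()) - 1.0) > 1e-6:
            raise ConfigError("exons_per_gene probabilities must sum to 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if min(self.utr5_range) < len(self.kozak_consensus) + 2:
            raise ConfigError("utr5 range too short to hold the Kozak context")


@dataclass
class SyntheticTruth:
    genome: Genome
    genes: list[GeneModel]
    transcripts: list[TranscriptAlignment]
    labels: dict[str, str]                 # transcript or gene id -> corruption
    params: SynthParams
    codon_probs: np.ndarray = None         # the generating codon distribution

    def coding_conditionals(self, order: int) -> np.ndarray:
        """Exact three-periodic order-``order`` conditionals of the
        generating codon process, in the same (phase, context, base)
        layout as MarkovChainModel (context little-endian by distance).

        Codons are i.i.d., so the conditional at codon position p given
        m preceding bases depends only on the within-codon prefix.
        """
        return coding_chain_conditionals(self.codon_probs, order)


def coding_chain_conditionals(codon_probs: np.ndarray, order: int) -> np.ndarray:
    b2i = {b: i for i, b in enumerate(BASES)}
    enc_codons = np.array(
        [[b2i[c[0]], b2i[c[1]], b2i[c[2]]] for c in SENSE_CODONS]
    )
    out = np.zeros((3, 4 ** order, 4))
    for phase in range(3):
        for ctx in range(4 ** order):
            # ctx digit d-1 = base at distance d before the emitted base
            ctx_bases = [(ctx // 4 ** d) % 4 for d in range(order)]
            # within-codon prefix: bases at distances 1..phase are in the
            # same codon as the emitted base
            usable = min(order, phase)
            mask = np.ones(len(SENSE_CODONS), dtype=bool)
            for d in range(1, usable + 1):
                mask &= enc_codons[:, phase - d] == ctx_bases[d - 1]
            w = codon_probs * mask
            tot = w.sum()
            if tot <= 0:
                out[phase, ctx, :] = 0.25
                continue
            for b in range(4):
                out[phase, ctx, b] = w[enc_codons[:, phase] == b].sum() / tot
    return out


class _Background:
    """Seeded order-2 background chain for intergenic/UTR sequence.

    Fungal intergenic DNA is AT-rich, which is also what makes the
    reverse complement of coding sequence (GC-richer, fewer stop codons)
    a closer match to the coding model than to the UTR model — the
    driver of the small antisense false positives the genome stage
    corrects.  The Dirichlet base weights encode that AT bias."""

    AT_ALPHA = (3.5, 1.5, 1.5, 3.5)       # A, C, G, T

    def __init__(self, rng: np.random.Generator):
        alpha = np.asarray(self.AT_ALPHA)
        self.cond = rng.dirichlet(alpha, size=16)  # (ctx4^2 -> 4)
        self.marg = rng.dirichlet(alpha)
        self.rng = rng

    def sample(self, n: int) -> str:
        if n <= 0:
            return ""
        rng = self.rng
        out = []
        b1 = int(rng.choice(4, p=self.marg))
        out.append(b1)
        if n > 1:
            b2 = int(rng.choice(4, p=self.marg))
            out.append(b2)
        u = rng.random(n)
        for i in range(2, n):
            ctx = out[i - 1] + 4 * out[i - 2]
            c = self.cond[ctx]
            # inverse-cdf draw using the pre-drawn uniforms
            r = u[i]
            acc = 0.0
            b = 3
            for k in range(4):
                acc += c[k]
                if r < acc:
                    b = k
                    break
            out.append(b)
        return "".join(BASES[b] for b in out[:n])

    def conditionals(self) -> np.ndarray:
        return self.cond


def _consensus_draw(rng, consensus: str, strength: float,
                    fixed_prefix: int = 0, fixed_suffix: int = 0) -> str:
    out = []
    n = len(consensus)
    for i, c in enumerate(consensus):
        if i < fixed_prefix or i >= n - fixed_suffix:
            out.append(c)
            continue
        if rng.random() < strength:
            out.append(c)
        else:
            out.append(BASES[int(rng.integers(0, 4))])
    return "".join(out)


def _sample_range(rng, rg: tuple[int, int]) -> int:
    return int(rng.integers(rg[0], rg[1] + 1))


@dataclass
class _LocalGene:
    seq: str                          # utr5 + cds-with-introns + utr3
    cds_exons: list[tuple[int, int]]  # 1-based within seq
    utr5_len: int
    utr3_len: int


def _build_intron(rng, p: SynthParams) -> str:
    total = _sample_range(rng, p.intron_length_range)
    tail = int(rng.integers(4, min(28, total - 22) + 1))
    donor = _consensus_draw(rng, p.donor_consensus, p.splice_strength,
                            fixed_prefix=2)
    acceptor = _consensus_draw(rng, p.acceptor_consensus, p.splice_strength,
                               fixed_suffix=2)
    branch = _consensus_draw(rng, p.branch_consensus, p.branch_strength)
    interior_len = total - len(donor) - len(branch) - tail - len(acceptor)
    probs = np.asarray(p.intron_interior_probs)
    def interior(n):
        if n <= 0:
            return ""
        idx = rng.choice(4, size=n, p=probs / probs.sum())
        return "".join(BASES[i] for i in idx)
    return donor + interior(interior_len) + branch + interior(tail) + acceptor


def _build_gene(rng, p: SynthParams, bg: _Background,
                codon_probs: np.ndarray) -> _LocalGene:
    utr5_len = _sample_range(rng, p.utr5_range)
    utr3_len = _sample_range(rng, p.utr3_range)
    utr5 = bg.sample(utr5_len)
    kz = _consensus_draw(rng, p.kozak_consensus, p.kozak_strength)
    utr5 = utr5[: utr5_len - len(kz)] + kz
    utr3 = bg.sample(utr3_len)
    n_codons = _sample_range(rng, p.cds_codons_range)
    idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=codon_probs)
    body = "".join(SENSE_CODONS[i] for i in idx)
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    cds = "ATG" + body + stop
    # choose intron insertion offsets within the CDS
    kk = list(p.exons_per_gene.keys())
    pp = np.array([p.exons_per_gene[k] for k in kk])
    n_exons = int(rng.choice(kk, p=pp / pp.sum()))
    cuts: list[int] = []
    lo, hi = 10, len(cds) - 10
    for _ in range(200):
        if len(cuts) == n_exons - 1:
            break
        c = int(rng.integers(lo, hi))
        if all(abs(c - x) >= p.min_internal_exon for x in cuts):
            cuts.append(c)
    cuts.sort()
    pieces = []
    exons = []
    pos = 0                       # offset within cds
    seq_pos = utr5_len            # offset within assembled gene sequence
    for cut in cuts + [len(cds)]:
        exon_seq = cds[pos:cut]
        pieces.append(exon_seq)
        exons.append((seq_pos + 1, seq_pos + len(exon_seq)))
        seq_pos += len(exon_seq)
        if cut < len(cds):
            intr = _build_intron(rng, p)
            pieces.append(intr)
            seq_pos += len(intr)
        pos = cut
    seq = utr5 + "".join(pieces) + utr3
    return _LocalGene(seq, exons, utr5_len, utr3_len)


def _mk_gene_model(gid, contig, strand, offset, local: _LocalGene,
                   block_len: int) -> GeneModel:
    """Map local CDS exons into genomic coordinates.

    ``offset`` is the genomic position (0-based) where the (possibly
    reverse-complemented) gene block starts; for reverse-strand genes
    local coordinates are flipped within the block first.
    """
    segs = []
    for s, e in local.cds_exons:
        if strand == FORWARD:
            gs, ge = offset + s, offset + e
        else:
            gs, ge = offset + block_len - e + 1, offset + block_len - s + 1
        segs.append((gs, ge, 0))
    gm = GeneModel(gene_id=gid, contig=contig, strand=strand,
                   cds_segments=sorted(segs))
    return gm.with_phases()


def _tx_exons(local: _LocalGene) -> list[tuple[int, int]]:
    """Transcript exon spans in local coordinates (UTRs extend the
    terminal exons)."""
    ex = [list(x) for x in local.cds_exons]
    ex[0][0] -= local.utr5_len
    ex[-1][1] += local.utr3_len
    return [(s, e) for s, e in ex]


def _flip_exons(exons, block_len):
    return sorted((block_len - e + 1, block_len - s + 1) for s, e in exons)


def generate(params: SynthParams) -> SyntheticTruth:
    """Generate a genome, true gene models and a corrupted transcript
    assembly according to ``params`` (deterministic under the seed)."""
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    bg = _Background(rng)
    codon_probs = rng.dirichlet(np.full(len(SENSE_CODONS), p.codon_bias_conc))
    gc = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS])
    codon_probs = codon_probs * (p.codon_gc_tilt ** gc)
    codon_probs = codon_probs / codon_probs.sum()

    n = p.n_genes
    # assign corruption roles
    idx = list(range(n))
    # S-AS pairs exist regardless of strandedness; unstranded data
    # additionally merges the pair into one unknown-strand alignment
    n_same = int(round(p.frac_merged_same * n / 2))
    n_sas = int(round(p.frac_merged_sas * n / 2))
    n_trunc = int(round(p.frac_truncated5 * n))
    n_fp = int(round(p.frac_fp_intron * n))
    n_unexpr = int(round((1.0 - p.frac_expressed) * n))
    units: list[tuple[str, list[int]]] = []
    pos = 0
    for _ in range(n_same):
        if pos + 1 >= n:
            break
        units.append(("merged_same", [idx[pos], idx[pos + 1]]))
        pos += 2
    for _ in range(n_sas):
        if pos + 1 >= n:
            break
        units.append(("merged_sas", [idx[pos], idx[pos + 1]]))
        pos += 2
    singles = idx[pos:]
    roles = (["truncated5"] * n_trunc + ["fp_intron"] * n_fp
             + ["unexpressed"] * n_unexpr)
    roles += ["clean"] * (len(singles) - len(roles))
    roles = roles[: len(singles)]
    rng.shuffle(roles)
    for gi, role in zip(singles, roles):
        units.append((role, [gi]))
    order = rng.permutation(len(units))

    chunks: list[str] = []
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        chunks.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    genes: list[GeneModel] = []
    gene_roles: dict[int, str] = {}        # id(GeneModel) -> role
    transcripts: list[TranscriptAlignment] = []
    labels: dict[str, str] = {}
    contig = p.contig_id

    emit(bg.sample(p.edge_pad))
    tcount = 0

    def new_tid():
        nonlocal tcount
        tcount += 1
        return f"t{tcount:04d}"

    def tx_strand(strand):
        return strand if p.stranded else UNKNOWN

    for ui in order:
        role, gidx = units[ui]
        emit(bg.sample(_sample_range(rng, p.intergenic_range)))
        if role in ("merged_same", "merged_sas"):
            a = _build_gene(rng, p, bg, codon_probs)
            b = _build_gene(rng, p, bg, codon_probs)
            if role == "merged_same":
                strand = FORWARD if rng.random() < 0.5 else REVERSE
                # forward layout: utr5A cdsA [shared: utr3A|utr5B] cdsB utr3B
                ov = int(rng.integers(10, 41))
                a_core = a.seq[: len(a.seq) - a.utr3_len]
                b_core = b.seq[b.utr5_len:]
                shared_len = a.utr3_len + b.utr5_len - ov
                shared = bg.sample(max(shared_len - len(p.kozak_consensus), 0))
                shared += _consensus_draw(rng, p.kozak_consensus, p.kozak_strength)
                block = a_core + shared + b_core
                bl = len(block)
                off = emit(block if strand == FORWARD else revcomp(block))
                # local coordinates of the two genes inside the block
                b_shift = len(a_core) + len(shared) - b.utr5_len
                b_local = _LocalGene(
                    "", [(s + b_shift, e + b_shift) for s, e in b.cds_exons],
                    b.utr5_len, b.utr3_len)
                ga = _mk_gene_model(None, contig, strand, off, a, bl)
                gb = _mk_gene_model(None, contig, strand, off, b_local, bl)
                tx_local = sorted(
                    _tx_exons(a) + [(s, e) for s, e in _tx_exons(b_local)]
                )
                # merge overlapping/adjacent local exon intervals
                merged = [list(tx_local[0])]
                for s, e in tx_local[1:]:
                    if s <= merged[-1][1] + 1:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                if strand == REVERSE:
                    merged = _flip_exons(merged, bl)
                tid = new_tid()
                transcripts.append(TranscriptAlignment(
                    tid, contig, tx_strand(strand),
                    [(off + s, off + e) for s, e in merged]))
                labels[tid] = "merged_same"
                for g in (ga, gb):
                    genes.append(g)
                    gene_roles[id(g)] = "merged_same"
            else:  # merged_sas: A forward, B reverse, overlapping 3' UTRs
                ov = int(rng.integers(10, 41))
                a_core = a.seq[: len(a.seq) - a.utr3_len]
                b_core_f = b.seq[: len(b.seq) - b.utr3_len]  # utr5B + cdsB
                shared_len = a.utr3_len + b.utr3_len - ov
                shared = bg.sample(shared_len)
                block = a_core + shared + revcomp(b_core_f)
                bl = len(block)
                off = emit(block)
                ga = _mk_gene_model(None, contig, FORWARD, off, a, bl)
                # B occupies the tail of the block, reverse strand
                b_bl = len(b_core_f)
                b_off = off + len(a_core) + len(shared)
                b_local = _LocalGene("", b.cds_exons, b.utr5_len, 0)
                gb = _mk_gene_model(None, contig, REVERSE, b_off, b_local, b_bl)
                # each transcript's 3' end reads through the shared region
                # and into the partner's CDS: deep tail-to-tail overlap,
                # the configuration behind antisense false positives
                b_cds_nt = sum(e - s + 1 for s, e in b.cds_exons)
                a_cds_nt = sum(e - s + 1 for s, e in a.cds_exons)
                reach_a = min(int(rng.integers(60, 201)), b_cds_nt // 2)
                reach_b = min(int(rng.integers(60, 201)), a_cds_nt // 2)
                tA = sorted(_tx_exons(a))
                tA[-1] = (tA[-1][0], len(a_core) + len(shared) + reach_a)
                tB_f = _tx_exons(_LocalGene("", b.cds_exons, b.utr5_len, b.utr3_len))
                # B transcript local (within b block + utr3 into shared)
                tB = _flip_exons(tB_f, b_bl + b.utr3_len)
                tB = [(s + len(a_core) + len(shared) - b.utr3_len,
                       e + len(a_core) + len(shared) - b.utr3_len) for s, e in tB]
                a_cds_end = max(e for _s, e in a.cds_exons)
                tB[0] = (max(1, a_cds_end - reach_b + 1), tB[0][1])
                if p.stranded:
                    tid_a, tid_b = new_tid(), new_tid()
                    transcripts.append(TranscriptAlignment(
                        tid_a, contig, FORWARD,
                        [(off + s, off + e) for s, e in tA]))
                    transcripts.append(TranscriptAlignment(
                        tid_b, contig, REVERSE,
                        [(off + s, off + e) for s, e in tB]))
                    labels[tid_a] = labels[tid_b] = "sas_pair"
                else:
                    allx = sorted(tA + tB)
                    merged = [list(allx[0])]
                    for s, e in allx[1:]:
                        if s <= merged[-1][1] + 1:
                            merged[-1][1] = max(merged[-1][1], e)
                        else:
                            merged.append([s, e])
                    tid = new_tid()
                    transcripts.append(TranscriptAlignment(
                        tid, contig, UNKNOWN,
                        [(off + s, off + e) for s, e in merged]))
                    labels[tid] = "merged_sas"
                genes.append(ga)
                genes.append(gb)
                gene_roles[id(ga)] = gene_roles[id(gb)] = (
                    "sas_pair" if p.stranded else "merged_sas"
                )
        else:
            g = _build_gene(rng, p, bg, codon_probs)
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            bl = len(g.seq)
            off = emit(g.seq if strand == FORWARD else revcomp(g.seq))
            gm = _mk_gene_model(None, contig, strand, off, g, bl)
            genes.append(gm)
            gene_roles[id(gm)] = role
            if role == "unexpressed":
                continue
            tx = _tx_exons(g)
            if role == "truncated5":
                cds_start = g.cds_exons[0][0]
                cds_len = sum(e - s + 1 for s, e in g.cds_exons)
                cut = cds_start + int(rng.integers(30, max(31, cds_len // 2)))
                clipped = []
                for s, e in tx:
                    if e < cut:
                        continue
                    clipped.append((max(s, cut), e))
                tx = clipped
            elif role == "fp_intron":
                # open a fake gap inside a CDS exon (in-frame, length 3m)
                cand = [x for x in g.cds_exons if x[1] - x[0] + 1 >= 160]
                if cand:
                    s, e = cand[0]
                    max_gap = min(30, (e - s + 1 - 70) // 3)
                    gap_len = 3 * int(rng.integers(10, max_gap + 1))
                    rel = int(rng.integers(0, max(1, (e - s + 1 - gap_len - 60) // 3)))
                    gs = s + 30 + 3 * rel
                    ge = gs + gap_len - 1
                    new_tx = []
                    for xs, xe in tx:
                        if xs <= gs and ge <= xe:
                            new_tx.append((xs, gs - 1))
                            new_tx.append((ge + 1, xe))
                        else:
                            new_tx.append((xs, xe))
                    tx = sorted(new_tx)
            if strand == REVERSE:
                tx = _flip_exons(tx, bl)
            tid = new_tid()
            transcripts.append(TranscriptAlignment(
                tid, contig, tx_strand(strand),
                [(off + s, off + e) for s, e in tx]))
            labels[tid] = role

    emit(bg.sample(p.edge_pad))
    seq = "".join(chunks)
    if p.contig_length is not None:
        if len(seq) > p.contig_length:
            raise ConfigError(
                f"genes do not fit contig: need {len(seq)} > {p.contig_length}"
            )
        seq = seq + bg.sample(p.contig_length - len(seq))
    genome = Genome({contig: seq})

    genes.sort(key=lambda g: g.start)
    for i, g in enumerate(genes, start=1):
        g.gene_id = f"g{i:04d}"
        labels[g.gene_id] = gene_roles.get(id(g), "clean")
    transcripts.sort(key=lambda t: t.start)
    return SyntheticTruth(genome, genes, transcripts, labels, p, codon_probs)
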