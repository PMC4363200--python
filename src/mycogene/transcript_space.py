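"""Virtually spliced transcripts, coordinate lifting and ORF scanning.

A spliced transcript is the concatenation of a transcript alignment's
exon blocks with introns removed; on the reverse strand the sequence is
reverse-complemented so that it always reads 5'->3'.  The coordinate map
back to the genome is invertible, so any transcript-space interval (for
example a predicted coding sequence) can be lifted to a minimal set of
genomic segments that split exactly at the evidenced introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .dna import STOP_CODONS, revcomp
from .errors import BoundsError
from .formats_io import FORWARD, REVERSE, UNKNOWN, Genome, TranscriptAlignment

#: exon gaps shorter than this are treated as alignment noise and merged
#: (a genuine GT..AG intron needs at least 4 nt)
MIN_EVIDENCED_INTRON = 4


@dataclass
class SplicedTranscript:
    transcript_id: str
    contig: str
    sequence: str
    strand_used: str                       # '+' or '-'
    exons: list[tuple[int, int]]           # ascending genomic, gaps >= 4 nt
    source_strand: str = UNKNOWN           # strand of the input alignment

    def __post_init__(self) -> None:
        self._cum = [0]
        for s, e in self.exons:
            self._cum.append(self._cum[-1] + (e - s + 1))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def genomic_start(self) -> int:
        return self.exons[0][0]

    @property
    def genomic_end(self) -> int:
        return self.exons[-1][1]

    @property
    def evidenced_introns(self) -> list[tuple[int, int]]:
        """Genomic (first, last) positions of each intron, ascending."""
        return [
            (e0 + 1, s1 - 1)
            for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:])
        ]

    # -- coordinate map -----------------------------------------------------

    def to_genome(self, pos: int) -> int:
        """Map a 1-based transcript position to its genomic position."""
        if pos < 1 or pos > len(self.sequence):
            raise BoundsError(
                f"transcript position {pos} outside 1..{len(self.sequence)}"
            )
        if self.strand_used == REVERSE:
            pos = len(self.sequence) - pos + 1
        # find exon containing forward-orientation offset
        lo, hi = 0, len(self.exons) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if self._cum[mid + 1] >= pos:
                hi = mid
            else:
                lo = mid + 1
        s, _e = self.exons[lo]
        return s + (pos - self._cum[lo] - 1)

    def from_genome(self, gpos: int) -> int:
        """Inverse coordinate map: genomic position -> transcript position.

        The position must lie inside an exon."""
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos <= e:
                f = self._cum[i] + (gpos - s + 1)
                if self.strand_used == REVERSE:
                    return len(self.sequence) - f + 1
                return f
        raise BoundsError(f"genomic position {gpos} not inside an exon")

    def lift_to_genome(self, start: int, end: int) -> list[tuple[int, int]]:
        """Lift a transcript-space interval to genomic segments.

        Segments are maximal, split exactly at evidenced introns, and
        returned in ascending genomic order.
        """
        if start < 1 or end > len(self.sequence) or start > end:
            raise BoundsError(
                f"interval ({start},{end}) outside transcript of length "
                f"{len(self.sequence)}"
            )
        if self.strand_used == REVERSE:
            L = len(self.sequence)
            start, end = L - end + 1, L - start + 1
        segments = []
        pos = start
        while pos <= end:
            # exon index containing pos (in forward orientation offsets)
            lo, hi = 0, len(self.exons) - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if self._cum[mid + 1] >= pos:
                    hi = mid
                else:
                    lo = mid + 1
            ex_s, ex_e = self.exons[lo]
            g_start = ex_s + (pos - self._cum[lo] - 1)
            take = min(end, self._cum[lo + 1]) - pos + 1
            segments.append((g_start, g_start + take - 1))
            pos += take
        return segments


@dataclass
class OrfInterval:
    """An open reading frame in transcript space (1-based inclusive)."""

    start: int
    end: int
    has_start_codon: bool
    has_stop_codon: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _merge_small_gaps(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = [exons[0]]
    for s, e in exons[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 < MIN_EVIDENCED_INTRON:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def splice(
    genome: Genome,
    aln: TranscriptAlignment,
    assume_strand: Optional[str] = None,
):
    """Build the virtually spliced transcript(s) for an alignment.

    Returns a single :class:`SplicedTranscript` when the orientation is
    determined (stranded data or ``assume_strand``), or a (forward,
    reverse) pair when the strand is unknown, for downstream competition.
    """
    exons = _merge_small_gaps(sorted(aln.exons))
    contig_len = genome.length(aln.contig)
    for s, e in exons:
        if s < 1 or e > contig_len:
            raise BoundsError(
                f"transcript {aln.transcript_id}: exon {s}-{e} outside contig "
                f"{aln.contig} (length {contig_len})"
            )
    fwd_seq = "".join(genome.fetch(aln.contig, s, e) for s, e in exons)

    def build(strand: str) -> SplicedTranscript:
        seq = fwd_seq if strand == FORWARD else revcomp(fwd_seq)
        return SplicedTranscript(
            transcript_id=aln.transcript_id,
            contig=aln.contig,
            sequence=seq,
            strand_used=strand,
            exons=exons,
            source_strand=aln.strand,
        )

    strand = assume_strand or aln.strand
    if strand in (FORWARD, REVERSE):
        return build(strand)
    return build(FORWARD), build(REVERSE)


def find_orfs(sequence: str) -> list[OrfInterval]:
    """All ATG-initiated ORFs in the three forward frames.

    An ORF extends from ATG to the first in-frame stop codon (inclusive);
    if no stop occurs before the 3' end the ORF is reported running to
    the last complete codon with ``has_stop_codon=False``.  Nested ATGs
    within an already-open ORF start their own (shorter) ORF.
    """
    orfs: list[OrfInterval] = []
    n = len(sequence)
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = sequence[i : i + 3]
            if codon == "ATG":
                open_starts.append(i)
            if codon in STOP_CODONS and open_starts:
                for s in open_starts:
                    orfs.append(OrfInterval(s + 1, i + 3, True, True))
                open_starts = []
        if open_starts:
            last_full = frame + ((n - frame) // 3) * 3  # 0-based end of last codon
            for s in open_starts:
                orfs.append(OrfInterval(s + 1, last_full, True, False))
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def longest_met_orf(sequence: str) -> Optional[OrfInterval]:
    """The longest stop-terminated ATG ORF; ties broken leftmost.

    ORFs that run off the 3' end (no stop codon) are not eligible.
    """
    best: Optional[OrfInterval] = None
    for orf in find_orfs(sequence):
        if not orf.has_stop_codon:
            continue
        if best is None or orf.length > best.length or (
            orf.length == best.length and orf.start < best.start
        ):
            best = orf
    return best
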