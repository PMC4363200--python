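"""Standard-format I/O and the core genomic domain types.

Reads a genome FASTA and Cufflinks-style transcript alignments (GTF or
GFF3), and writes predictions as GFF3.  All coordinates are 1-based
inclusive at every interface, following the GFF convention.

The FASTA/GFF line parsers are deliberately minimal and line-oriented so
that malformed input can be reported with its file line number, which
the downstream training code relies on for actionable errors.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .dna import VALID_BASES, revcomp
from .errors import BoundsError, ConsistencyError, FormatError

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Assembled genome: contig id -> uppercase DNA string (A,C,G,T,N)."""

    contigs: dict[str, str]

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive subsequence."""
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end:
            raise BoundsError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start - 1 : end]


@dataclass
class TranscriptAlignment:
    """One assembled transcript's exon blocks on a contig.

    ``exons`` are (start, end) 1-based inclusive genomic intervals sorted
    ascending and non-overlapping, regardless of strand.  ``strand`` may
    be '.', meaning unknown (unstranded RNA-seq).
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    source_line_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE, UNKNOWN):
            raise ConsistencyError(
                f"transcript {self.transcript_id}: bad strand {self.strand!r}"
            )
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise FormatError(
                    f"transcript {self.transcript_id}: exon start {s} > end {e}"
                )
            if s <= prev_end:
                raise ConsistencyError(
                    f"transcript {self.transcript_id}: overlapping/abutting exons"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic (first, last) coordinates of each exon gap."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            out.append((e0 + 1, s1 - 1))
        return out


@dataclass
class GeneModel:
    """A predicted (or reference) coding sequence on a contig.

    ``cds_segments`` is a list of (start, end, phase) with genomic
    1-based inclusive coordinates, stored in ascending genomic order.
    Phase follows the GFF3 convention: number of bases to skip at the
    segment's 5' (translation-order) end to reach the next codon start.
    """

    gene_id: str
    contig: str
    strand: str
    cds_segments: list[tuple[int, int, int]]
    transcript_id: Optional[str] = None
    provenance: str = "stage1"
    complete5prime: bool = True
    complete3prime: bool = True
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ConsistencyError(f"gene {self.gene_id}: strand must be + or -")
        self.cds_segments = sorted(self.cds_segments)
        prev = 0
        for s, e, p in self.cds_segments:
            if s > e or s <= prev:
                raise ConsistencyError(
                    f"gene {self.gene_id}: bad/overlapping CDS segment ({s},{e})"
                )
            prev = e

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s0, e0, _), (s1, e1, _) in zip(self.cds_segments, self.cds_segments[1:]):
            out.append((e0 + 1, s1 - 1))
        return out

    def spliced_cds(self, genome: Genome) -> str:
        """Coding sequence 5'->3' (reverse-complemented on the - strand)."""
        parts = [genome.fetch(self.contig, s, e) for s, e, _ in self.cds_segments]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == REVERSE else seq

    def segments_key(self) -> tuple:
        """Identity used for exact gene-level comparison (CDS only)."""
        return (self.contig, self.strand,
                tuple((s, e) for s, e, _ in self.cds_segments))

    def with_phases(self) -> "GeneModel":
        """Return a copy whose phases are recomputed from the translation start."""
        segs = list(self.cds_segments)
        order = segs if self.strand == FORWARD else segs[::-1]
        fixed = []
        cum = 0
        for s, e, _ in order:
            phase = (3 - cum % 3) % 3
            fixed.append((s, e, phase))
            cum += e - s + 1
        if self.strand == REVERSE:
            fixed = fixed[::-1]
        import dataclasses
        return dataclasses.replace(self, cds_segments=fixed)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> Genome:
    """Read a genome FASTA.

    Lowercase input is uppercased; header text after the first whitespace
    is dropped from the contig id; duplicate ids and characters outside
    {A,C,G,T,N} are rejected.
    """
    path = Path(path)
    contigs: dict[str, list[str]] = {}
    current: Optional[str] = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in contigs:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate contig id {name!r}"
                    )
                contigs[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first FASTA header"
                    )
                chunk = line.upper()
                bad = set(chunk) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)} "
                        f"in contig {current!r}"
                    )
                contigs[current].append(chunk)
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    joined = {name: "".join(parts) for name, parts in contigs.items()}
    for name, seq in joined.items():
        if not seq:
            raise FormatError(f"{path}: contig {name!r} has an empty sequence")
    return Genome(joined)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3 transcript alignments
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_col: str, dialect: str) -> dict[str, str]:
    if dialect == "gtf":
        return dict(_GTF_ATTR.findall(attr_col))
    out = {}
    for item in attr_col.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def detect_dialect(attr_col: str) -> str:
    """Cufflinks emits GTF (quoted values); GFF3 uses key=value."""
    if _GTF_ATTR.search(attr_col):
        return "gtf"
    return "gff3"


def read_transcripts(
    path: str | Path, dialect: Optional[str] = None
) -> list[TranscriptAlignment]:
    """Read transcript-to-genome alignments from GTF or GFF3.

    Only ``exon`` features are used; the grouping attribute is
    ``transcript_id`` (GTF) or ``Parent`` (GFF3).  A '.' strand is kept
    as unknown.  The dialect is auto-detected from the attribute syntax
    unless forced.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
            if ftype.lower() != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start > end:
                raise FormatError(f"{path}:{lineno}: exon start {start} > end {end}")
            d = dialect or detect_dialect(attrs)
            parsed = _parse_attrs(attrs, d)
            tid = parsed.get("transcript_id") or parsed.get("Parent")
            if not tid:
                raise FormatError(
                    f"{path}:{lineno}: exon lacks transcript_id/Parent attribute"
                )
            if strand not in (FORWARD, REVERSE, UNKNOWN):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            g = groups.setdefault(
                tid, {"contig": contig, "strand": strand, "exons": [], "lines": []}
            )
            if g["contig"] != contig:
                raise ConsistencyError(
                    f"transcript {tid!r} has exons on multiple contigs "
                    f"({g['contig']!r} and {contig!r})"
                )
            if g["strand"] != strand:
                raise ConsistencyError(
                    f"transcript {tid!r} has exons with conflicting strands"
                )
            g["exons"].append((start, end))
            g["lines"].append(lineno)
    out = []
    for tid, g in groups.items():
        out.append(
            TranscriptAlignment(
                transcript_id=tid,
                contig=g["contig"],
                strand=g["strand"],
                exons=g["exons"],
                source_line_numbers=g["lines"],
            )
        )
    out.sort(key=lambda t: (t.contig, t.start, t.transcript_id))
    return out


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptAlignment], path: str | Path,
    source: str = "mycogene",
) -> None:
    with Path(path).open("w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'transcript_id "{t.transcript_id}"; gene_id "{t.transcript_id}";'
                fh.write(
                    f"{t.contig}\t{source}\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               source: str = "mycogene") -> None:
    """Write gene models as GFF3: gene + mRNA + CDS features per model.

    Attribute vocabulary is this package's own stable set: ``provenance``,
    ``complete5``, ``complete3`` and ``supporting_transcript``.
    """
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            g = g.with_phases()
            score = "." if g.score is None else f"{g.score:.3f}"
            attrs = [f"ID={g.gene_id}", f"provenance={g.provenance}",
                     f"complete5={'true' if g.complete5prime else 'false'}",
                     f"complete3={'true' if g.complete3prime else 'false'}"]
            if g.transcript_id:
                attrs.append(f"supporting_transcript={g.transcript_id}")
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start}\t{g.end}\t{score}\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            mrna_id = f"{g.gene_id}.mRNA"
            fh.write(
                f"{g.contig}\t{source}\tmRNA\t{g.start}\t{g.end}\t{score}\t"
                f"{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e, phase) in enumerate(g.cds_segments, start=1):
                fh.write(
                    f"{g.contig}\t{source}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (this package's output or any GFF3
    whose CDS features carry a Parent attribute)."""
    path = Path(path)
    meta: dict[str, dict] = {}          # feature id -> attributes (gene/mRNA)
    parent_of: dict[str, str] = {}
    cds: dict[str, list[tuple[int, int, int, str, str]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start_s, end_s, _score, strand, frame, attr_col = cols[:9]
            attrs = _parse_attrs(attr_col, "gff3")
            ftype = ftype.lower()
            if ftype in ("gene", "mrna"):
                fid = attrs.get("ID")
                if fid:
                    meta[fid] = attrs
                    if "Parent" in attrs:
                        parent_of[fid] = attrs["Parent"]
            elif ftype == "cds":
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: CDS without Parent")
                phase = int(frame) if frame in ("0", "1", "2") else 0
                cds.setdefault(parent, []).append(
                    (int(start_s), int(end_s), phase, contig, strand)
                )
    genes = []
    for parent, segs in cds.items():
        contig = segs[0][3]
        strand = segs[0][4]
        top = parent_of.get(parent, parent)
        attrs = meta.get(top, meta.get(parent, {}))
        genes.append(
            GeneModel(
                gene_id=top,
                contig=contig,
                strand=strand if strand in (FORWARD, REVERSE) else FORWARD,
                cds_segments=[(s, e, p) for s, e, p, _, _ in segs],
                transcript_id=attrs.get("supporting_transcript"),
                provenance=attrs.get("provenance", "stage1"),
                complete5prime=attrs.get("complete5", "true") == "true",
                complete3prime=attrs.get("complete3", "true") == "true",
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


def log(msg: str, level: int = 1, verbosity: int = 1) -> None:
    if verbosity >= level:
        print(msg, file=sys.stderr)
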