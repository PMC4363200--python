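"""Merging, false-positive filtering, dubious-gene discovery and the
merged-transcript (fusion) report.

Three filters run in a fixed order after stage-1 and stage-2 predictions
are combined: (1) genes translating to fewer than 30 amino acids are
removed; (2) among overlapping splice variants only those with at least
one unique intron or 10+ unique amino acids are retained; (3) a gene
overlapping a larger gene on the opposite strand is removed when less
than 20% of its coding sequence lies outside the larger gene's bounds.

Transcripts left without any overlapping prediction get a forced coding
parse (the stage-1 model with its noncoding transition zeroed); these
"dubious" genes are reported separately, never in the main annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .config import RunConfig
from .formats_io import FORWARD, REVERSE, GeneModel, TranscriptAlignment
from .stage1 import (OrientedTranscript, Stage1Model, predict_stage1,
                     spec_without_noncoding)


def _cds_overlap_nt(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for s1, e1, _ in a.cds_segments:
        for s2, e2, _ in b.cds_segments:
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def _span_overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


# ---------------------------------------------------------------------------
# combining stage 1 and stage 2
# ---------------------------------------------------------------------------

def combine(kept_stage1: Sequence[GeneModel],
            stage2_genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Union of the two sets; where a stage-2 gene's CDS overlaps a kept
    stage-1 gene's CDS on the same strand, the RNA-seq-supported stage-1
    gene wins.  Ids are re-assigned in genomic order."""
    out = list(kept_stage1)
    for g2 in stage2_genes:
        clash = any(
            g1.contig == g2.contig and g1.strand == g2.strand
            and _cds_overlap_nt(g1, g2) > 0
            for g1 in kept_stage1
        )
        if not clash:
            out.append(g2)
    out.sort(key=lambda g: (g.contig, g.start, g.strand))
    for i, g in enumerate(out, start=1):
        g.gene_id = f"gene_{i:04d}"
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_short(genes: Sequence[GeneModel],
                 cfg: Optional[RunConfig] = None) -> list[GeneModel]:
    """Remove genes whose CDS translates to fewer than 30 amino acids
    (CDS < 93 nt including the stop codon)."""
    min_aa = (cfg.min_protein_aa if cfg else 30)
    return [g for g in genes if g.cds_length >= 3 * min_aa + 3]


def _same_locus(a: GeneModel, b: GeneModel) -> bool:
    """Variant grouping: same strand, sharing an intron or >= 50% CDS
    overlap of the shorter gene."""
    if a.contig != b.contig or a.strand != b.strand:
        return False
    if set(a.introns) & set(b.introns):
        return True
    ov = _cds_overlap_nt(a, b)
    return ov >= 0.5 * min(a.cds_length, b.cds_length)


def filter_variants(genes: Sequence[GeneModel],
                    cfg: Optional[RunConfig] = None) -> list[GeneModel]:
    """Within each variant locus keep the best-scoring variant, plus any
    variant contributing >= 1 unique intron or >= 10 unique amino acids."""
    min_aa = (cfg.variant_unique_aa if cfg else 10)
    genes = list(genes)
    n = len(genes)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if genes[j].start > genes[i].end or genes[i].contig != genes[j].contig:
                continue
            if _same_locus(genes[i], genes[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep: set[int] = set()
    for members in groups.values():
        if len(members) == 1:
            keep.add(members[0])
            continue
        def rank(i):
            g = genes[i]
            return (g.score if g.score is not None else float(g.cds_length))
        members = sorted(members, key=rank, reverse=True)
        kept_members = [members[0]]
        for i in members[1:]:
            g = genes[i]
            kept_introns = set()
            for kidx in kept_members:
                kept_introns |= set(genes[kidx].introns)
            unique_intron = bool(set(g.introns) - kept_introns)
            covered = set()
            for kidx in kept_members:
                for s, e, _ in genes[kidx].cds_segments:
                    covered.update(range(s, e + 1))
            outside = sum(
                1
                for s, e, _ in g.cds_segments
                for pnt in range(s, e + 1)
                if pnt not in covered
            )
            if unique_intron or outside >= 3 * min_aa:
                kept_members.append(i)
        keep.update(kept_members)
    return [g for i, g in enumerate(genes) if i in keep]


def filter_nested(genes: Sequence[GeneModel],
                  cfg: Optional[RunConfig] = None) -> list[GeneModel]:
    """Remove genes overlapping a larger opposite-strand gene when less
    than 20% of their CDS lies outside the larger gene's bounds.
    Applied iteratively largest-first; equal-length pairs both survive."""
    frac = (cfg.nested_outside_frac if cfg else 0.2)
    ordered = sorted(genes, key=lambda g: -g.cds_length)
    kept: list[GeneModel] = []
    for g in ordered:
        removed = False
        for h in kept:
            if (h.contig == g.contig and h.strand != g.strand
                    and h.cds_length > g.cds_length
                    and _span_overlap(g.start, g.end, h.start, h.end) > 0):
                outside = 0
                for s, e, _ in g.cds_segments:
                    if e < h.start or s > h.end:
                        outside += e - s + 1
                    else:
                        outside += max(0, h.start - s) + max(0, e - h.end)
                if outside < frac * g.cds_length:
                    removed = True
                    break
        if not removed:
            kept.append(g)
    kept.sort(key=lambda g: (g.contig, g.start))
    return kept


def apply_filters(genes: Sequence[GeneModel],
                  cfg: Optional[RunConfig] = None) -> list[GeneModel]:
    """The fixed filter chain: short -> variants -> nested."""
    return filter_nested(filter_variants(filter_short(genes, cfg), cfg), cfg)


# ---------------------------------------------------------------------------
# dubious genes
# ---------------------------------------------------------------------------

@dataclass
class DubiousGeneSet:
    genes: list[GeneModel]


def predict_dubious(
    stage1_model: Stage1Model,
    oriented: Sequence[OrientedTranscript],
    final_genes: Sequence[GeneModel],
    cfg: RunConfig,
) -> DubiousGeneSet:
    """Force a coding parse in every transcript that no final gene
    overlaps, using the stage-1 model with the noncoding-transcript
    transition probability set to zero."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in final_genes:
        by_contig.setdefault(g.contig, []).append(g)

    def covered(st) -> bool:
        for g in by_contig.get(st.contig, []):
            if _span_overlap(st.genomic_start, st.genomic_end, g.start, g.end) > 0:
                return True
        return False

    uncovered = []
    for item in oriented:
        st = item[0] if isinstance(item, tuple) else item
        if not covered(st):
            uncovered.append(item)
    if not uncovered:
        return DubiousGeneSet([])
    spec = spec_without_noncoding(stage1_model)
    result = predict_stage1(stage1_model, uncovered, cfg,
                            provenance="dubious", spec=spec)
    for i, g in enumerate(result.genes, start=1):
        g.gene_id = f"dubious_{i:04d}"
    return DubiousGeneSet(result.genes)


# ---------------------------------------------------------------------------
# fusion report
# ---------------------------------------------------------------------------

@dataclass
class FusionRow:
    transcript_id: str
    n_constituents: int
    strand_pattern: str


@dataclass
class FusionReport:
    rows: list[FusionRow]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("transcript_id\tn_constituents\tstrand_pattern\n")
            for r in self.rows:
                fh.write(f"{r.transcript_id}\t{r.n_constituents}\t"
                         f"{r.strand_pattern}\n")


def report_fusions(final_genes: Sequence[GeneModel],
                   transcripts: Sequence[TranscriptAlignment]) -> FusionReport:
    """A transcript is a suspected fusion when >= 2 final genes' CDSs
    overlap its genomic extent; the strand pattern lists the constituent
    genes' strands in genomic order."""
    rows = []
    for t in transcripts:
        hits = [
            g for g in final_genes
            if g.contig == t.contig
            and any(_span_overlap(t.start, t.end, s, e) > 0
                    for s, e, _ in g.cds_segments)
        ]
        if len(hits) >= 2:
            hits.sort(key=lambda g: g.start)
            rows.append(FusionRow(
                t.transcript_id, len(hits),
                "".join(g.strand for g in hits)))
    return FusionReport(rows)
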