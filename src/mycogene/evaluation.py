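"""Burset–Guigó sensitivity/specificity at nucleotide, exon, intron and
gene level.

Sensitivity is the proportion of reference features correctly predicted;
specificity is the proportion of predicted features that are correct.  A
nucleotide is correct when it lies inside coding sequence of both sets
on the same strand; exons and introns require exact boundary matches;
a gene is correct only when its ordered CDS segment list is identical
(UTRs are ignored — predictions are CDS-only).

In ``bounded`` mode (used against high-confidence reference subsets)
counting is restricted to the reference gene spans extended by any
overlapping predicted gene: predicted genes that overlap no reference
span are excluded from the denominators entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConsistencyError
from .formats_io import FORWARD, REVERSE, GeneModel, Genome

LEVELS = ("nucleotide", "exon", "intron", "gene")


@dataclass
class LevelStats:
    tp: int
    reference_total: int
    predicted_total: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.reference_total if self.reference_total else 0.0

    @property
    def specificity(self) -> float:
        return 100.0 * self.tp / self.predicted_total if self.predicted_total else 0.0


@dataclass
class EvaluationReport:
    levels: dict[str, LevelStats]
    mode: str = "full"

    def __getitem__(self, level: str) -> LevelStats:
        return self.levels[level]

    def pretty(self) -> str:
        lines = [f"# mode: {self.mode}",
                 f"{'level':<12}{'Sn':>8}{'Sp':>8}{'TP':>10}{'ref':>10}{'pred':>10}"]
        for lv in LEVELS:
            st = self.levels[lv]
            lines.append(
                f"{lv:<12}{st.sensitivity:>8.1f}{st.specificity:>8.1f}"
                f"{st.tp:>10}{st.reference_total:>10}{st.predicted_total:>10}"
            )
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("level\tsensitivity\tspecificity\ttp\treference\tpredicted\n")
            for lv in LEVELS:
                st = self.levels[lv]
                fh.write(f"{lv}\t{st.sensitivity:.2f}\t{st.specificity:.2f}\t"
                         f"{st.tp}\t{st.reference_total}\t{st.predicted_total}\n")


def _contig_lengths(predicted, reference, genome: Optional[Genome]):
    lengths: dict[str, int] = {}
    if genome is not None:
        for c, s in genome.contigs.items():
            lengths[c] = len(s)
        for g in list(predicted) + list(reference):
            if g.contig not in lengths:
                raise ConsistencyError(
                    f"gene {g.gene_id} on contig {g.contig!r} absent from genome"
                )
        return lengths
    for g in list(predicted) + list(reference):
        lengths[g.contig] = max(lengths.get(g.contig, 0), g.end)
    return lengths


def _bounded_mask(predicted, reference, lengths):
    """Union of reference gene spans extended by overlapping predictions."""
    mask = {c: np.zeros(n + 2, dtype=bool) for c, n in lengths.items()}
    for r in reference:
        mask[r.contig][r.start : r.end + 1] = True
    changed = True
    while changed:
        changed = False
        for p in predicted:
            m = mask[p.contig]
            if m[p.start : p.end + 1].any() and not m[p.start : p.end + 1].all():
                m[p.start : p.end + 1] = True
                changed = True
    return mask


def evaluate(
    predicted: Sequence[GeneModel],
    reference: Sequence[GeneModel],
    mode: str = "full",
    genome: Optional[Genome] = None,
) -> EvaluationReport:
    if mode not in ("full", "bounded"):
        raise ValueError("mode must be 'full' or 'bounded'")
    lengths = _contig_lengths(predicted, reference, genome)

    if mode == "bounded":
        mask = _bounded_mask(predicted, reference, lengths)
        pred_used = [
            p for p in predicted
            if mask[p.contig][p.start : p.end + 1].any()
        ]
    else:
        mask = None
        pred_used = list(predicted)

    # --- nucleotide level -------------------------------------------------
    def cds_arrays(genes):
        arrs = {
            (c, s): np.zeros(lengths[c] + 2, dtype=bool)
            for c in lengths for s in (FORWARD, REVERSE)
        }
        for g in genes:
            a = arrs[(g.contig, g.strand)]
            for s, e, _ in g.cds_segments:
                a[s : e + 1] = True
        return arrs

    ref_arr = cds_arrays(reference)
    pred_arr = cds_arrays(pred_used)
    tp_nt = ref_total_nt = pred_total_nt = 0
    for key in ref_arr:
        r, p = ref_arr[key], pred_arr[key]
        if mask is not None:
            m = np.zeros_like(r)
            mm = mask[key[0]]
            m[: len(mm)] = mm
            r = r & m
            p = p & m
        tp_nt += int((r & p).sum())
        ref_total_nt += int(r.sum())
        pred_total_nt += int(p.sum())

    # --- exon / intron levels ---------------------------------------------
    def exon_set(genes):
        return {
            (g.contig, g.strand, s, e)
            for g in genes for s, e, _ in g.cds_segments
        }

    def intron_set(genes):
        return {
            (g.contig, g.strand, s, e) for g in genes for s, e in g.introns
        }

    ref_ex, pred_ex = exon_set(reference), exon_set(pred_used)
    ref_in, pred_in = intron_set(reference), intron_set(pred_used)

    # --- gene level ---------------------------------------------------------
    ref_genes = {g.segments_key() for g in reference}
    pred_genes = {g.segments_key() for g in pred_used}

    levels = {
        "nucleotide": LevelStats(tp_nt, ref_total_nt, pred_total_nt),
        "exon": LevelStats(len(ref_ex & pred_ex), len(ref_ex), len(pred_ex)),
        "intron": LevelStats(len(ref_in & pred_in), len(ref_in), len(pred_in)),
        "gene": LevelStats(len(ref_genes & pred_genes), len(ref_genes),
                           len(pred_genes)),
    }
    return EvaluationReport(levels, mode)
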