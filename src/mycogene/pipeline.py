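"""End-to-end orchestration: stage 1 -> region selection -> stage 2 ->
combine -> filters -> dubious genes and fusion report."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import RunConfig
from .errors import MycogeneError
from .formats_io import (GeneModel, Genome, TranscriptAlignment, log,
                         read_genome, read_transcripts, write_gff3)
from .postprocess import (DubiousGeneSet, FusionReport, apply_filters,
                          combine, predict_dubious, report_fusions)
from .stage1 import (Stage1Result, orient_transcripts, predict_stage1,
                     self_train, _extract_genes, _seed_orientation)
from .stage2 import (RegionSelection, build_constraints, predict_stage2,
                     select_regions, train_stage2)
from .transcript_space import longest_met_orf


@dataclass
class PipelineResult:
    seed_genes: list[GeneModel]          # longest-ORF initial annotation
    stage1_genes: list[GeneModel]
    kept_stage1: list[GeneModel]
    stage2_genes: list[GeneModel]
    combined_genes: list[GeneModel]      # pre-filter union
    final_genes: list[GeneModel]
    dubious: DubiousGeneSet
    fusions: FusionReport
    selection: RegionSelection
    stage1_result: Stage1Result
    history: list[str] = field(default_factory=list)


def _seed_orf_genes(oriented) -> list[GeneModel]:
    """The 'longest ORF per transcript' annotation that seeds training —
    kept for staged accuracy accounting."""
    genes = []
    for item in oriented:
        st = _seed_orientation(item)
        orf = longest_met_orf(st.sequence)
        if orf is None:
            continue
        segs = st.lift_to_genome(orf.start, orf.end)
        genes.append(GeneModel(
            gene_id=f"orf.{len(genes)+1:04d}", contig=st.contig,
            strand=st.strand_used,
            cds_segments=[(a, b, 0) for a, b in segs],
            transcript_id=st.transcript_id, provenance="stage1",
        ).with_phases())
    return genes


def run_pipeline_objects(
    genome: Genome,
    transcripts: Sequence[TranscriptAlignment],
    cfg: RunConfig,
) -> PipelineResult:
    t0 = time.time()
    history: list[str] = []

    def note(msg):
        history.append(msg)
        log("[pipeline] " + msg, 1, cfg.verbosity)

    oriented = orient_transcripts(genome, transcripts)
    seed_genes = _seed_orf_genes(oriented)
    note(f"{len(transcripts)} transcripts; {len(seed_genes)} seed ORFs")

    model1, s1res, hist1 = self_train(genome, transcripts, cfg)
    history.extend(hist1)
    note(f"stage 1: {len(s1res.genes)} genes")

    selection = select_regions(s1res, genome, cfg)
    reasons = {}
    for _g, r in selection.discarded:
        reasons[r] = reasons.get(r, 0) + 1
    note(f"kept {len(selection.kept)} stage-1 genes; discarded {reasons}; "
         f"{len(selection.windows)} genomic windows, "
         f"{len(selection.alt_windows)} alt-splice windows")

    track = build_constraints(transcripts, genome, cfg.stranded, cfg)
    model2 = train_stage2(model1, s1res, genome, cfg)
    note(f"stage 2 model: donor/acceptor lengths "
         f"{model2.donor_len}/{model2.acceptor_len}, "
         f"max intron {model2.intron.max_intron}")

    stage2_genes = predict_stage2(model2, selection, track, genome, cfg)
    note(f"stage 2: {len(stage2_genes)} genes")

    combined = combine(selection.kept, stage2_genes)
    final = apply_filters(combined, cfg)
    for i, g in enumerate(final, start=1):
        g.gene_id = f"gene_{i:04d}"
    note(f"combined {len(combined)} -> final {len(final)} after filters")

    dubious = predict_dubious(model1, oriented, final, cfg)
    fusions = report_fusions(final, transcripts)
    note(f"{len(dubious.genes)} dubious genes; "
         f"{len(fusions.rows)} suspected fusions; "
         f"total {time.time()-t0:.1f}s")
    return PipelineResult(
        seed_genes=seed_genes,
        stage1_genes=s1res.genes,
        kept_stage1=selection.kept,
        stage2_genes=stage2_genes,
        combined_genes=combined,
        final_genes=final,
        dubious=dubious,
        fusions=fusions,
        selection=selection,
        stage1_result=s1res,
        history=history,
    )


def run_pipeline(
    genome_path: str | Path,
    transcripts_path: str | Path,
    out_dir: str | Path,
    config_path: Optional[str | Path] = None,
    **overrides,
) -> PipelineResult:
    """File-level entry point: reads inputs, runs the pipeline and writes
    predictions, dubious genes, the fusion report and a run log."""
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if overrides:
        cfg = cfg.replace(**overrides)
    genome = read_genome(genome_path)
    transcripts = read_transcripts(transcripts_path)
    if not transcripts:
        raise MycogeneError(f"no transcripts found in {transcripts_path}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_pipeline_objects(genome, transcripts, cfg)
    write_gff3(result.final_genes, out / "predicted.gff3")
    write_gff3(result.dubious.genes, out / "dubious.gff3")
    result.fusions.write_tsv(out / "fusions.tsv")
    cfg.to_yaml(out / "config.yaml")
    with (out / "run.log").open("w") as fh:
        fh.write("\n".join(result.history) + "\n")
    return result
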