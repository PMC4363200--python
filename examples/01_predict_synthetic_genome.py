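"""Generate a small synthetic fungal genome, run the full two-stage
prediction pipeline on its transcript assembly, and score the result
against the known truth.

The printed table reports Burset-Guigó sensitivity (fraction of true
features recovered) and specificity (fraction of predictions that are
correct) at nucleotide, exon, intron and gene level; the gene row counts
only predictions whose CDS segments match a true gene exactly.
"""

from mycogene import RunConfig, SynthParams, evaluate, generate
from mycogene.pipeline import run_pipeline_objects

params = SynthParams(seed=1, n_genes=60)
truth = generate(params)
print(f"synthetic genome: {truth.genome.length(params.contig_id):,} bp, "
      f"{len(truth.genes)} genes, {len(truth.transcripts)} transcripts")

cfg = RunConfig(seed=1, verbosity=0)
result = run_pipeline_objects(truth.genome, truth.transcripts, cfg)
print(f"predicted {len(result.final_genes)} genes "
      f"({sum(g.provenance == 'stage1' for g in result.final_genes)} from "
      f"transcripts, {sum(g.provenance == 'stage2' for g in result.final_genes)} "
      f"from genome sequence)")

report = evaluate(result.final_genes, truth.genes, genome=truth.genome)
print(report.pretty())
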