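"""Self-train the transcript-space GHMM alone and inspect one parse.

Shows the state segmentation of a single virtually spliced transcript:
UTRs, the 11-nt Kozak window ending at the ATG, the coding segment and
the stop codon.  A merged transcript (two genes sharing one assembled
transcript) parses through the middle-UTR state instead.
"""

from mycogene import RunConfig, SynthParams, generate
from mycogene.stage1 import self_train

truth = generate(SynthParams(seed=3, n_genes=40, frac_merged_same=0.2,
                             frac_expressed=1.0, frac_truncated5=0.0,
                             frac_merged_sas=0.0))
cfg = RunConfig(seed=3, verbosity=0)
model, result, history = self_train(truth.genome, truth.transcripts, cfg)
for line in history:
    print(line)

tid, (st, path) = next(iter(result.parses.items()))
print(f"\nparse of {tid} ({len(st.sequence)} nt, strand {st.strand_used}):")
for state, s, e in path.segments:
    print(f"  {state:10s} {s:5d}..{e:<5d} ({e - s + 1} nt)")

merged = [t for t, (s, p) in result.parses.items()
          if any(seg[0] == "mid_utr" for seg in p.segments)]
print(f"\n{len(merged)} transcripts parsed as multi-gene (middle UTR): "
      f"{', '.join(merged[:5])}")
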