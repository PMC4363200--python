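"""Fit the stage-2 intron boundary lengths from evidenced introns.

The donor/acceptor windows are extended position by position away from
the invariant GT/AG until the base composition stops differing from the
intron interior (chi-square, df=3, p=0.01).  On this fixture the
generator plants a 6-position donor consensus, so the fitted donor
length should be 6 intronic + 2 exonic = 8 nt.
"""

from mycogene import RunConfig, SynthParams, generate
from mycogene.stage1 import orient_transcripts
from mycogene.stage2 import (collect_evidenced_introns, fit_boundary_lengths,
                             max_intron_length)

truth = generate(SynthParams(seed=5, n_genes=150, frac_expressed=1.0,
                             frac_truncated5=0.0, frac_merged_same=0.0,
                             frac_merged_sas=0.0))
cfg = RunConfig(seed=5, verbosity=0)
spliced = orient_transcripts(truth.genome, truth.transcripts)
introns = collect_evidenced_introns(truth.genome, spliced)
print(f"{len(introns)} evidenced introns, "
      f"{sum(i.canonical for i in introns)} canonical GT..AG")
donor, acceptor = fit_boundary_lengths(introns, cfg)
print(f"fitted donor length: {donor} nt (incl. 2 exonic)")
print(f"fitted acceptor length: {acceptor} nt (incl. 2 exonic)")
print(f"max decodable intron: "
      f"{max_intron_length([i.length for i in introns], cfg)} nt "
      f"(1.1 x longest evidenced, capped at {cfg.intron_cap})")
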