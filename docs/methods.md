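# Methods

`mycogene` predicts protein-coding genes in compact, gene-dense fungal
genomes from two inputs: the assembled genome (FASTA) and assembled
transcript-to-genome alignments (Cufflinks-style GTF, or GFF3).  The
method exploits a property of fungal RNA-seq data — short introns and
little alternative splicing make transcript assemblies largely
full-length and correctly spliced — by predicting coding sequences
*directly from transcript sequences* first, and only falling back to
genome-sequence prediction where transcript evidence is known to be
error-prone.

## Stage 1: transcript-space GHMM

Each alignment is virtually spliced (exon blocks concatenated, reverse-
complemented for minus-strand transcripts) and decoded with an
explicit-duration (generalised) hidden Markov model whose states are:

    begin → [5'UTR] → Kozak window → CDS → stop codon
          → { 3'UTR → end | middle UTR → Kozak → … }
    begin → noncoding transcript → end

* **Coding emission**: fifth-order, three-periodic Markov chain (one
  conditional table per codon position), with shortened-context backoff
  for the first five bases of a segment.
* **UTR / noncoding emissions**: fifth-order non-periodic chains; by
  default 5', 3' and middle UTRs share one table and noncoding
  transcripts have their own.
* **Kozak / start**: order-2 weighted array matrix over an 11-nt window
  ending at (and including) the ATG.
* **Stop codon**: literal TAA/TAG/TGA with trained frequencies.
* **Durations**: smoothed empirical length frequencies (below).

The *middle UTR* state lets a single transcript carry several same-
direction genes, which is how transcripts merged through overlapping
UTRs of adjacent loci are annotated correctly.  For unstranded data both
orientations of each transcript are decoded and the higher-scoring parse
is kept (forward on exact ties).

**Self-training.**  Parameters are seeded from the longest
Met-initiated, stop-terminated ORF of each transcript; the model is then
run and retrained exactly twice.  Training sets are filtered
conservatively: coding examples must be ≥ 600 nt; ORFs ≥ 300 nt are
excised from UTR examples; where training genes overlap on the genome
only the longest is kept.  The noncoding-transcript prior is
re-estimated each iteration from the fraction of transcripts parsed as
noncoding (via adjacency counts with pseudocount 1, which is also how
all transition probabilities are estimated).

## Stage 2: genome-space GHMM

Stage-1 genes train a second GHMM that reads genome sequence.  UTRs are
absorbed into *intergenic* regions; an intron sub-model is added:

* donor, branch point and acceptor are first-order weighted array
  matrices; donor and acceptor extend 2 nt into the adjacent exon and
  are at most 22 nt long in total;
* donor/acceptor widths are fitted to the data: each position moving
  away from the invariant GT (toward the AG) is compared with the pooled
  intron-interior composition by a chi-square test (df = 3, p = 0.01,
  critical value 11.345), and the boundary extends to the furthest
  significant position.  With fewer than 50 evidenced introns the fit
  falls back to 9 intronic + 2 exonic positions.  The interior reference
  excludes 22 nt at each intron end (less for short introns, so the pool
  is never empty);
* the two variable-length spacers (donor→branch, branch→acceptor) are
  order-2 chains; their duration supports are clipped so that every
  decodable intron length lies in [20, max], where max is 10% longer
  than the longest evidenced intron, capped at 5,000 (cap removable);
* the branch-point model is trained by a small fixed-iteration EM:
  initialise the WAM from every window whose end lies 6–50 nt from the
  intron's 3' end, re-pick the best-scoring window per intron, retrain;
  three iterations.

Reading frame is carried across introns by indexing the coding-exon
state by (entry phase, exit phase) — nine states whose duration models
share one smoothed exon-length distribution with a modulus-3 residue
constraint — and triplicating the intron sub-path by phase.  Because the
splice WAMs consume 2 coding nt on each side, the phase advances by four
coding positions across an intron.

**Evidence constraints.**  Donor/acceptor boundaries are forbidden
wherever a same-strand transcript *exon* covers the genome (alignment
gaps — evidenced introns — do not count as coverage), relaxed within
50 nt of each transcript's ends; unstranded alignments constrain both
strands.  Everywhere, introns must begin GT and end AG.

**Region selection.**  All single-exon stage-1 genes are discarded, as
are genes whose reading frame is open all the way to the supporting
transcript's 5' end (the ORF could extend beyond the transcript —
suspected incomplete).  Genomic windows are the complement of the
retained genes' CDS spans, padded by 200 nt; loci where an evidenced
intron could be read through without hitting a stop codon are
additionally decoded as alternative-splice windows.  Each window is
decoded independently on both strands.

**Scoring and reconciliation.**  Each stage-2 gene is scored by the
log-odds of its sub-path against the intergenic model over the same
span, which is comparable across gene lengths.  Genes whose odds are
negative are dropped, as are genes containing an intron whose own
sub-path does not beat the intergenic model over the intron span (this
rejects "introns" placed only to dodge in-frame stop codons, the
dominant failure mode of antisense predictions).  Where genes from the
two strand decodings, or from overlapping windows, overlap in CDS, the
higher-odds gene wins.

## Combination, filters, discovery, fusions

Stage-1 and stage-2 predictions are united; on same-strand CDS overlap
the RNA-seq-supported stage-1 gene wins.  Three filters then run in a
fixed order:

1. genes translating to fewer than 30 amino acids are removed;
2. within each variant locus (same strand, shared intron or ≥ 50% CDS
   overlap of the shorter gene) the best-scoring variant is kept, plus
   any variant with ≥ 1 unique intron or ≥ 10 unique amino acids;
3. a gene overlapping a larger opposite-strand gene is removed when
   less than 20% of its CDS lies outside the larger gene's bounds
   (largest-first; equal lengths both survive).

Transcripts that end up with no overlapping prediction are re-decoded
with the stage-1 model whose noncoding transition is zeroed; the forced
genes are written to a separate "dubious" set, never to the main
annotation.  A fusion report lists every transcript whose extent
overlaps the CDS of two or more final genes, with the constituent
strands in genomic order (e.g. `++`, `+-`).

## Durations and numerical choices

Empirical duration models are histograms convolved with a triangular
kernel (half-width max(2, width/50), configurable), normalised to
1 − 2·10⁻³, with geometric tails on *both* sides.  The high tail is the
usual continuation beyond the longest observed length; the low tail
keeps shorter-than-observed segments admissible but heavily penalised —
necessary because coding examples are restricted to ≥ 600 nt while
genuine shorter genes must remain predictable.  All decoding is in log
space; emission pseudocounts default to 0.01 per table cell; characters
other than ACGT score log(¼).  If fewer than 50·4ᵏ events support an
order-k table the order is reduced until the quota is met.

Viterbi decoding is explicit-duration with per-position constraints
(state occupancy, segment starts, segment ends).  Scores are compared
exactly; differences below 10⁻⁹ are treated as ties and broken toward
the path whose earliest differing segment boundary is leftmost, then by
state index — the same declarative rule the exhaustive enumeration
oracle applies, so decoder and oracle are path-comparable.  A compiled
(numba) kernel decodes long sequences and defers to the pure-Python
reference implementation whenever it detects a near-tie.

## Synthetic data: what it emulates, and what it does not

The generator builds a single contig of genes with: codon-biased CDS
drawn codon-by-codon from a seeded Dirichlet codon distribution tilted
toward G/C (coding is GC-richer than the AT-rich intergenic background,
as in real fungal genomes — this composition asymmetry is what makes
reverse-complement CDS resemble the coding model); an 8-nt Kozak-like
consensus before each ATG; GT..AG introns (40–200 nt) with planted
donor/branch/acceptor consensus and an i.i.d. AT-rich interior; UTRs
and intergenic spacers from a seeded order-2 AT-rich chain.  Transcript
corruptions — 5'-truncation into the CDS, same-strand merging through
overlapping UTRs, deep tail-to-tail sense–antisense overlap (merged
into one unknown-strand alignment for unstranded data), false-positive
introns, and missing transcripts — are individually switchable, so each
pipeline mechanism has an isolating fixture.  Because codons are drawn
i.i.d., the true three-periodic conditionals are available in closed
form, which is what the parameter-recovery checks compare against.

The generator does **not** model sequencing noise, fragmented or
chimeric assemblies beyond the cases above, alternative splicing,
non-canonical splice sites, overlapping genes on the same strand, or
inhomogeneous composition along the genome.  Passing tests therefore
demonstrate that the *mechanisms* work under the stated idealisations,
not that accuracy on real genomes will match the synthetic numbers.

### Problem sizes used by the test suite

Fixtures use 80–300 genes on a single few-hundred-kb contig: 200 genes
for the clean end-to-end fixture, 300 for parameter recovery, 80–120
for the mechanism fixtures, chosen so each check has enough events to
be statistically stable while the whole suite stays quick on one CPU.

## Known limitations

* Stage-2 start-codon choice is fully ab initio; in regions where the
  transcript 5' end was discarded, an upstream in-frame ATG without an
  intervening stop can displace the true start.  This is the dominant
  residual error class on the synthetic fixtures.
* The implementation's orientation competition and duration priors
  suppress the small antisense single-exon stage-1 false positives that
  motivate discarding single-exon genes; the discard-and-repredict
  machinery is still exercised (stage 2 produces and then removes
  antisense false candidates), but the stage-1 false-positive count on
  the sense–antisense fixture is typically zero rather than positive.
* One gene per ORF: no nested same-strand genes, no non-ATG starts, no
  selenocysteine readthrough, no trans-splicing.
* Intron total length is bounded via the spacer duration supports;
  within the bounds the three intron sub-segments are only jointly,
  not exactly, length-distributed.
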