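# mycogene

Two-stage, self-training generalised-HMM gene prediction for compact
fungal genomes, driven by assembled RNA-seq transcripts.

## The problem

Fungal genomes are gene-dense with short introns and little alternative
splicing, so RNA-seq transcript assemblies (e.g. TopHat + Cufflinks) are
largely full-length and correctly spliced. `mycogene` exploits this by
predicting protein-coding sequences **directly from the spliced
transcript sequences** — every predicted intron then agrees exactly with
the transcript-to-genome alignment — and only predicting from genome
sequence in the regions where transcript evidence is known to be
error-prone: merged transcripts from overlapping UTRs, transcripts
truncated at the 5' end, sense–antisense merges in unstranded data, and
genes that were simply not expressed.  No protein homology and no
curated training set are needed: the model trains itself from the
transcripts, seeded by each transcript's longest Met-initiated ORF.

Stage 1 decodes each virtually spliced transcript with an
explicit-duration HMM (5'UTR → 11-nt Kozak/start window → coding
sequence under a fifth-order three-periodic Markov chain → stop codon →
3'UTR, with a "middle UTR" state that lets one transcript carry several
genes).  Stage 2 trains a genome-space GHMM from the stage-1 genes,
adds a fungal intron sub-model (first-order donor / branch-point /
acceptor weighted array matrices whose widths are fitted by a χ² scan,
df = 3, p = 0.01), discards single-exon and suspected-incomplete
stage-1 genes, and re-predicts those loci plus all transcript-free
regions on both strands, with intron boundaries disallowed wherever a
same-strand transcript exon covers the genome (relaxed within 50 nt of
transcript ends, GT..AG everywhere).  Predictions are merged, filtered
(< 30 aa; redundant splice variants; genes nested in larger antisense
genes), and reported together with forced "dubious" predictions in
otherwise empty transcripts and a merged-transcript (fusion) report.
Accuracy is measured with Burset–Guigó sensitivity/specificity at
nucleotide, exon, intron and gene level.

See `docs/methods.md` for the full model description and its
assumptions.

## Worked example

`examples/01_predict_synthetic_genome.py` builds a small seeded
synthetic genome (60 genes with UTRs, short GT..AG introns, Kozak-like
start context, and realistic transcript corruptions: some transcripts
truncated, merged or missing), runs the full pipeline, and scores the
result against the known truth:

```
synthetic genome: 117,893 bp, 60 genes, 52 transcripts
predicted 56 genes (32 from transcripts, 24 from genome sequence)
# mode: full
level             Sn      Sp        TP       ref      pred
nucleotide      89.6    99.6     65481     73044     65772
exon            85.8    93.8       121       141       129
intron          90.1   100.0        73        81        73
gene            80.0    85.7        48        60        56
```

Gene-level Sn = 80.0 means 48 of the 60 true genes are predicted with
exactly the right CDS segments; Sp = 85.7 means 48 of the 56 predictions
are exactly right.  Intron Sp = 100 reflects the transcript-constrained
intron model: every predicted intron matches an evidenced one.  On the
larger 200-gene corruption-free fixture the pipeline reaches ~98% gene
sensitivity and ~97% specificity (see the acceptance checks below).

The other examples show the stage-1 transcript parses (including a
merged transcript resolved through the middle-UTR state) and the χ²
fitting of the intron boundary widths.

### Command line

```sh
mycogene synth   --seed 1 --out fixture/          # synthetic genome + truth
mycogene predict --genome fixture/genome.fasta \
                 --transcripts fixture/transcripts.gtf --out run/
mycogene eval    --pred run/predicted.gff3 --ref fixture/truth.gff3 [--bounded]
```

`predict` writes `predicted.gff3`, `dubious.gff3`, `fusions.tsv`, the
effective configuration and a run log; `--unstranded` treats transcript
strands as unknown, `--no-intron-cap` lifts the intron-length limits.

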