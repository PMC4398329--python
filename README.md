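# plastome

Analysis toolkit for chloroplast (plastid) genomes, built around the standard
battery of analyses run on a newly assembled plastome — here the sweet potato
(*Ipomoea batatas*) chloroplast genome and its companion transcriptome data:

- **Quadripartite structure** — detect the two inverted repeats (IRa/IRb) of a
  circular plastome, partition it into LSC → IRa → SSC → IRb, profile
  per-region GC, and classify genes at the four IR junctions (ILa/ILb between
  the IRs and the LSC, ISa/ISb between the IRs and the SSC), including
  gene-flow comparisons between two genomes (e.g. a gene duplicated in the IR
  of one species becoming single-copy in the LSC of another).
- **Gene inventory** — functional-group classification (photosynthesis,
  chloro-respiration, expression machinery, metabolic pathway, pseudogenes),
  single/double-copy accounting (`total copies = singles + 2 × duplicated`)
  and an intron census.
- **Codon usage** — frame-0 codon counts over spliced CDS features under the
  plastid/bacterial genetic code (NCBI table 11), amino-acid totals and
  third-codon-position A+U composition.
- **Maximal repeats** — forward, reverse and palindromic repeated pairs under
  REPuter-style cutoffs (length ≥ 17 bp, identity ≥ 90 %, non-overlapping),
  with genomic location annotation (coding / intron / tRNA / IGS).
- **RNA editing** — C→U (and rarer U→C, G→A) sites called from DNA-vs-cDNA
  mismatches, with codon position, amino-acid change, synonymy and compact
  PREPACT-style labels (`atpAeU914SL` = *atpA*, exonic, edited to U at CDS
  position 914, Ser→Leu).
- **Expression** — FPKM (`reads·10⁹ / (length·library)`), NlaIII digital-tag
  TPM (21-bp `CATG`+17 tags, tags per million), and differential-expression
  calls by a two-sided hypergeometric test with p ≤ 0.05 and |log₂FC| ≥ 1.
- **Contig triage** — chloroplast / mitochondrial / nuclear classification of
  assembly contigs by mapped read depth (≳2000×, ~200×, ~20×).
- **Synthetic data** — a seeded generator producing miniature quadripartite
  genomes, spliced gene models, planted repeats, planted editing events,
  negative-binomial count tables and contig depths, each with serialized
  ground truth, so the whole pipeline is testable offline.

Worked-example tables transcribed from the published sweet-potato plastome
analysis (gene inventory, codon usage, 13 repeats, 43 editing sites) ship in
`src/plastome/data/` with loaders that validate the transcription; printed
irregularities are preserved verbatim and flagged, never silently corrected.

## Worked example

Generate a miniature synthetic plastome (34 kb: LSC 18 kb, IR 6 kb, SSC 4 kb)
with transcripts, then run structure detection and editing calling:

```bash
plastome simulate transcripts --seed 1 --out sim
plastome structure --fasta sim/plastome.fasta --out structure
plastome editing --genbank sim/plastome.gb --transcripts sim/transcripts.fasta --out editing
```

`structure.tsv` shows the recovered partition (coordinates 1-based
inclusive); the boundaries match the generator's plan exactly and the two IRs
are exact reverse complements (identity 1.0000):

```
region  interval     length  gc
LSC     1-18000      18000   0.369111
IRa     18001-24000  6000    0.4235
SSC     24001-28000  4000    0.3585
IRb     28001-34000  6000    0.4235
genome  1-34000      34000   0.387059
```

`editing.tsv` recovers all ten planted editing events (6 C→U, 3 U→C, 1 G→A;
nine exonic, one intronic), each with its codon context and label:

```
gene  genome_pos  gene_pos  ...  bases  codon_change  aa_change  region  label        support
psbA  802         302            C->U   UCU->UUU      S->F       exon    psbAeU302SF  5
psbA  1099        599            C->U   UCC->UUC      S->F       exon    psbAeU599SF  5
matK  2584        317            U->C   UUC->UCC      F->S       exon    matKeC317FS  5
...
```

The library surface mirrors the CLI: `plastome.structure.partition`,
`plastome.codon.count_codons`, `plastome.editing.call_editing_sites`,
`plastome.expression.call_dets`, … — see the module docstrings.

On the packaged tables the same operations reproduce the published tallies:
leucine is the most frequent amino acid with 2,330 codons and cysteine the
least with 280; the 43 editing sites split 36 C→U / 5 U→C / 2 G→A with 3
intronic sites and 31 non-synonymous changes; the 13 repeats tally 7 in
coding regions, 2 in introns and 4 in tRNAs with sizes 17–39 nt; and the gene
inventory counts 94 protein-coding copies (72 single + 2×11 duplicated) and
43 tRNA copies (31 + 2×6).

## Scope

Genome assembly, BLAST/DOGMA annotation, whole-genome alignment and
phylogenetics are out of scope: the toolkit starts from an assembled,
annotated genome (FASTA + GenBank/GFF3) and count/depth tables.
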