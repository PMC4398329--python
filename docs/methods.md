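# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and sequence model

Internally every interval is 0-based half-open; user-facing reports are
1-based inclusive. Circular sequences allow intervals that wrap the origin,
stored as `(start, end)` with `end <= start` and length `end − start + L`.
The alphabet is {A,C,G,T,N}: U is normalised to T on input, report columns
that quote codons print RNA letters, and N never matches anything (including
another N) in repeat or editing comparisons and is excluded from GC
denominators. Translation uses the plastid/bacterial genetic code (NCBI
table 11); codons containing N render `X`, stops render `*`.

## Repeat finding

Classes follow REPuter's vocabulary: the second copy equals the first
(forward), its plain reversal (reverse) or its reverse complement
(palindromic). Comparing the sequence S against its class transform T, a
*valid segment* on an alignment diagonal starts and ends on a match, has
Hamming identity ≥ `min_identity`, and is at least `min_len` long; a reported
hit is a valid segment not properly contained in another valid segment on the
same diagonal. At identity 1 this is exactly the classical maximal exact
repeat set. We chose containment maximality over "no 1-bp extension stays
above threshold" deliberately: at 90 % identity any long exact repeat could
absorb flanking mismatches one at a time and overrun its true boundaries,
whereas the containment rule keeps hits match-bounded and is directly
checkable by an exhaustive oracle (the test suite compares the seeded
implementation against a full all-diagonal enumeration).

Two consequences are worth knowing. First, around a repeat much longer than
`1/(1−identity)` the rule admits a *staircase* of overlapping maximal
segments that trade left-flank for right-flank mismatch budget; on a real
plastome the IR itself produces such a family at the default 90 % threshold,
just as REPuter reports the IR as the dominant palindromic repeat. Second,
seeding is on exact shared k-mers (default k = 12): this guarantees every
exact repeat ≥ 17 bp and every hit containing a 12-mer exact run, but a short
near-threshold hit whose longest run is < 12 can be missed.
`complete_seed_k(min_len, min_identity)` returns the largest provably
complete seed (from the pigeonhole bound `run ≥ ⌈(L−m)/(m+1)⌉` with
`m ≤ ⌊L(1−id)⌋`); tests use it, and callers scanning small sequences can too.
Circular sequences are scanned on the doubled string with hits normalised
modulo the length; truncated window images of one circular diagonal are
containment-deduplicated. Identity comparisons carry a 1e-9 slack so that
`matches ≥ identity × length` is decided identically in the implementation
and the oracle at exact-threshold boundaries.

Location annotation assigns each copy by midpoint containment with precedence
intron > tRNA > coding > IGS, and a repeat's joint category is the
highest-precedence class either copy touches. This convention reproduces the
published 7 coding / 2 intron / 4 tRNA split of the packaged 13-repeat
catalogue; the publication does not state its own convention, so ours is a
reconstruction.

## Quadripartite structure

IR detection runs the palindromic repeat finder at `min_len` 1000 bp and
`min_identity` 0.99 and takes the longest disjoint pair (ties break on the
smaller start coordinate). Because a kilobase-scale exact IR can stay above
99 % identity while absorbing tens of flanking mismatches, the winning
candidate is trimmed to its maximum-score core under the scoring
match = +1, mismatch = −id/(1−id) (Kadane's maximum-subarray on the match
vector): interior mismatches are retained (each is amortised by the
surrounding matches), mismatch-dense fringes are cut. Exact IRs are then
recovered at their exact boundaries; with planted interior mismatches the
reported identity is `1 − mismatches/|IR|`.

Partition assigns the longer single-copy gap to the LSC (ties warn and take
the smaller start) and labels the IRs so the traversal order from the LSC
start is LSC → IRa → SSC → IRb. The SSC is reported in the orientation found;
the two SSC orientations that co-exist in real plastome preparations are not
normalised. Junction categories depend only on region containment: a feature
wholly inside an IR is `duplicated-in-IR`, wholly inside the LSC/SSC is
`single-copy-in-SC`, anything else is `junction-spanning`; comparing two
reports emits one event per gene whose category changed, and is antisymmetric
by construction.

## Gene inventory and codon usage

Functional classification is a packaged name → group table (plastid papers
assign groups by name, not computation), overridable per call; unknown names
fall back to pseudogene/unknown with a warning. Copy accounting treats a gene
present once in each IR as duplicated (2 copies). Codon usage reads frame-0
codons of every spliced, non-degenerate CDS with pseudogenes excluded by
default; stop codons are counted in their own row rather than under any amino
acid — the printed sweet-potato table lists UAA under Tyr, which contradicts
the genetic code, so the packaged transcription keeps the printed value with
an anomaly flag and aggregation follows the code (the published leucine and
cysteine totals are unaffected and reproduce exactly).

## RNA editing

Transcripts are compared to the gene's genomic span (introns included,
5'→3' on the gene strand) by ungapped comparison after anchoring on shared
21-mers; pairs diverging by more than 5 % are rejected as mispairings.
Intronic sites are therefore observable when transcripts retain intron
sequence (the generator emits unspliced pre-mRNA copies for exactly this
reason). A mismatch becomes a site when supported by at least `min_support`
transcripts (default 2) and an edited fraction ≥ `min_fraction` (default
0.5, ties call the site). Exonic sites carry codon position, amino-acid
change and synonymy recomputed through the genetic code; intronic sites carry
an intron-relative position and no synonymy by default. The published table
prints pseudo-codons for its three intron rows and counts one of them
(petB, Ser→Leu) as non-synonymous; `paper_compat` mode lets those printed
pseudo-codon amino acids drive the synonymy tallies, which is required to
reproduce the published 31-of-43 non-synonymous count. Labels follow the
compact grammar gene + e|i + edited-to base (RNA letter) + gene position +
amino acids before/after; the edited-to base letter was inferred from all 43
printed labels (U for C→U, C for U→C, A for G→A). Two printed label
irregularities (the ycf3 row's 1168-vs-1668 position and the psbK row's
amino acids, which contradict its own codons) are preserved with anomaly
flags and whitelisted in validation.

## Expression and differential expression

FPKM is `count × 10⁹ / (length_bp × library_size)`; tag-based TPM is
`count × 10⁶ / total_clean_tags`, so TPM over all clean tags (mapped plus
unmapped mass) is conserved at 10⁶ exactly. Tags are the 21-mers anchored at
each `CATG` with at least 17 downstream bases; both an all-occurrences mode
(default) and a 3'-most mode are provided because the source protocol is
ambiguous on this point, and a tag matching more than one gene is assigned to
none and reported as ambiguous.

Differential expression per gene uses the two-sided hypergeometric test
conditioning on the margins (population n₁+n₂, successes x₁+x₂, sample n₁),
with p = min(1, 2·min(P[X ≤ x₁], P[X ≥ x₁])). The smaller tail is summed
directly from log-space pmf terms (log-gamma binomials, compensated `fsum`
of exponentials); the larger tail is its complement plus the point mass.
Against exact rational enumeration the relative error stays below 1e-12 for
margins up to 200. Significance requires p ≤ α (default 0.05) **and**
|log₂FC| ≥ 1, with a pseudocount of 1 applied to the fold-change rates only
(never to the test), preventing infinite log-ratios at zero counts.
Benjamini–Hochberg adjustment is available but off by default, matching the
raw-p convention of the source analysis. The source names both edgeR and a
hypergeometric test without reconciling them; the hypergeometric procedure is
what is implemented here.

## Contig triage

Half-open depth bands with chloroplast precedence at overlaps: depth ≥ 2000×
→ chloroplast, 100–500× → mitochondrial, ≤ 100× → nuclear, gaps between
bands → ambiguous rather than a forced call. The mitochondrial band width is
our choice (the source states only "~200×") and is configurable. An optional
exact 31-mer sharing check against a user-supplied reference (≥ 0.5 of contig
k-mers present confirms) replaces the original BLAST confirmation step.

## Synthetic data: what it emulates, and what it does not

The default plastome plan is a 34 kb miniature (LSC 18 kb, IR 6 kb, SSC 4 kb;
region GC targets 0.36/0.41/0.34) carrying 15 gene models — both strands,
one- to three-exon structures, an IR-duplicated CDS/rRNA/tRNA trio — three
planted repeats (39 bp forward, 24 bp reverse, 19 bp palindromic) and ten
planted editing events (6 C→U, 3 U→C, 1 G→A, one of them intronic),
mirroring the composition of the real analysis at desk scale so the full
pipeline runs in seconds. CDS sequences are random at the region GC with
in-frame stop codons patched; every random draw flows from the plan's single
seed, so outputs are byte-identical per seed.

Planted repeats are flanked by 12 bp anti-match guards and region boundaries
by 3 bp anti-complement guards. This makes the planted coordinates coincide
with the contract-maximal ones — the property real plastome IR boundaries
have by virtue of being annotation-sharp — and it is what makes the
exact-recovery tests meaningful rather than fragile. Count tables are
negative-binomial (dispersion 0.05, the standard overdispersion scale for
RNA-seq-like counts) with a baseline mean of 500 per gene, 25 genes of which
5 carry a planted log₂FC of 2, and a nominal library of 10⁵ tags; contig
depths are Poisson around 2500/200/20×.

What passing on this generator does **not** show: robustness to indels
(alignment is ungapped throughout; indel-containing IRs and repeats are out
of scope), to sequencing error in transcripts (copies are error-free apart
from the planted edits), to multi-mapping reads, or to annotation errors.
Real-genome numbers that depend on the deposited accession or the undeposited
transcriptome libraries (total length, genome-wide GC, FPKM values, the
43-of-83 DET count) are reproducible only with those inputs and are not
asserted by the test suite.

## Test and validation scales

The suite verifies repeat finding against an exhaustive all-diagonal oracle
on 21 random sequences up to 2 kb; quadripartite recovery on 50 seeded
plastomes (IR 2–8 kb, 0–2 planted mismatches; exact when exact, ±1 bp per
mismatch otherwise); editing precision and recall of 1.0 over 20 seeds at
clean 5× coverage; hypergeometric p-values against exact rational enumeration
(all margins with n₁,n₂ ≤ 10–12 exhaustively, plus hundreds of random margins
to 200) at 1e-12 relative tolerance; a null differential-expression
false-positive rate ≤ 0.05 over 20 seeds × 1000 genes; and exact TPM
conservation. These sizes keep the full suite under a minute on one core
while leaving every statistical check comfortably powered.
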