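"""RNA-editing site calling and PREPACT-style labelling.

Editing sites are DNA-vs-cDNA single-base mismatches (predominantly C->U in
plant organelles).  Transcripts are compared to the gene's genomic span
(introns included, 5'->3' on the gene strand) by ungapped alignment after
k-mer anchoring, so both exonic and intronic sites are observable.

Labels follow the compact nomenclature gene + e|i (exon/intron) + edited-to
base (RNA letter) + gene position + amino acid before/after, e.g.
``atpAeU914SL``.  Intronic positions count from the intron start and carry no
codon/synonymy fields unless printed pseudo-codon context is supplied
(paper-compat reporting).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

from .codon import DNA_TO_RNA, codon_amino_acid
from .errors import NoAlignmentError
from .seqio import (
    AnnotatedGenome,
    GeneFeature,
    genomic_span_sequence,
    interval_length,
    spliced_sequence,
)


@dataclass
class EditingSite:
    gene: str
    genome_pos: int            # 1-based genomic coordinate
    gene_pos: int              # 1-based in spliced CDS (exon) or intron (intron)
    region: str                # 'exon' | 'intron'
    dna_base: str              # RNA letters (C->U printed as C, U)
    rna_base: str
    aa_pos: int | None = None
    codon_pos: int | None = None
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None
    synonymous: bool | None = None
    support: tuple[int, float] | None = None  # (edited reads, edited fraction)
    label: str | None = None


def classify_site(codon_before: str, codon_pos: int, rna_base: str) -> dict:
    """Classify one exonic substitution from its codon context.

    ``codon_before`` is the RNA triplet, ``codon_pos`` in {1,2,3} and
    ``rna_base`` the edited-to RNA letter.  Synonymous iff the amino acid is
    unchanged under the plastid code.
    """
    codon_before = codon_before.upper().replace("T", "U")
    if len(codon_before) != 3 or any(b not in "ACGU" for b in codon_before):
        raise ValueError(f"invalid codon {codon_before!r}")
    if codon_pos not in (1, 2, 3):
        raise ValueError(f"codon position must be 1..3, got {codon_pos}")
    rna_base = rna_base.upper().replace("T", "U")
    dna_base = codon_before[codon_pos - 1]
    codon_after = (
        codon_before[: codon_pos - 1] + rna_base + codon_before[codon_pos:]
    )
    aa_before = codon_amino_acid(codon_before)
    aa_after = codon_amino_acid(codon_after)
    return {
        "dna_base": dna_base,
        "rna_base": rna_base,
        "codon_before": codon_before,
        "codon_after": codon_after,
        "aa_before": aa_before,
        "aa_after": aa_after,
        "synonymous": aa_before == aa_after,
    }


# ---------------------------------------------------------------------------
# labels

_LABEL_RE = re.compile(
    r"^(?P<gene>[A-Za-z][A-Za-z0-9.\-]*?)"
    r"(?P<region>[ei])"
    r"(?P<base>[ACGU])"
    r"(?P<pos>[0-9]+)"
    r"(?:(?P<aa1>[A-Z*])(?P<aa2>[A-Z*]))?$"
)


def format_label(site: EditingSite) -> str:
    region = "e" if site.region == "exon" else "i"
    aa = ""
    if site.aa_before and site.aa_after:
        aa = f"{site.aa_before}{site.aa_after}"
    return f"{site.gene}{region}{site.rna_base}{site.gene_pos}{aa}"


def parse_label(text: str) -> EditingSite:
    """Inverse of :func:`format_label` (partial site: positional fields only)."""
    m = _LABEL_RE.match(text)
    if not m:
        raise ValueError(f"malformed editing-site label {text!r}")
    return EditingSite(
        gene=m["gene"],
        genome_pos=0,
        gene_pos=int(m["pos"]),
        region="exon" if m["region"] == "e" else "intron",
        dna_base="",
        rna_base=m["base"],
        aa_before=m["aa1"],
        aa_after=m["aa2"],
        label=text,
    )


# ---------------------------------------------------------------------------
# gene coordinate map (span offset <-> spliced/intron/genomic coordinates)


class GeneCoordinateMap:
    """Maps offsets along a gene's genomic span (5'->3', introns included) to
    spliced-CDS positions, intron-relative positions and genomic coordinates.
    """

    def __init__(self, genome: AnnotatedGenome, feature: GeneFeature):
        self.feature = feature
        n = len(genome.sequence)
        self.seqlen = n
        span = feature.span(n)
        self.span_len = sum(
            interval_length(e, n) for e in feature.exons
        ) + self._intron_total(feature, n)
        self.span_start = span[0]
        # walk 5'->3': label every span offset
        self.kind: list[tuple[str, int, int]] = []  # (region, index, rel_pos)
        off = 0
        spliced_pos = 0
        exon_lengths = [interval_length(e, n) for e in feature.exons]
        gaps = self._intron_lengths(feature, n)
        for k, elen in enumerate(exon_lengths):
            for _ in range(elen):
                self.kind.append(("exon", k, spliced_pos))
                spliced_pos += 1
                off += 1
            if k < len(gaps):
                for r in range(gaps[k]):
                    self.kind.append(("intron", k, r))
                    off += 1

    @staticmethod
    def _intron_lengths(feature: GeneFeature, n: int) -> list[int]:
        # gap between consecutive exons, measured along the gene's strand
        out = []
        for a, b in zip(feature.exons, feature.exons[1:]):
            if feature.strand == "+":
                gap = (b[0] - a[1]) % n
            else:
                gap = (a[0] - b[1]) % n
            out.append(gap)
        return out

    @classmethod
    def _intron_total(cls, feature: GeneFeature, n: int) -> int:
        return sum(cls._intron_lengths(feature, n))

    def genomic_position(self, off: int) -> int:
        if self.feature.strand == "+":
            return (self.span_start + off) % self.seqlen
        return (self.span_start + self.span_len - 1 - off) % self.seqlen

    def describe(self, off: int):
        """(region, gene_pos 1-based, intron_index or None) for a span offset."""
        region, idx, rel = self.kind[off]
        if region == "exon":
            return ("exon", rel + 1, None)
        return ("intron", rel + 1, idx)


# ---------------------------------------------------------------------------
# transcript alignment and site calling


def align_transcript(
    gene_seq: str,
    transcript: str,
    anchor_k: int = 21,
    max_divergence: float = 0.05,
):
    """Ungapped comparison of a transcript to its gene after k-mer anchoring.

    Returns (mismatches, (start, end)) where mismatches are
    (gene position 0-based, gene base, transcript base) tuples and the
    interval is the gene region the transcript covers.  Raises
    :class:`NoAlignmentError` when no anchor exists or divergence exceeds
    ``max_divergence`` (signals a wrong transcript/gene pairing).
    """
    gene_seq = gene_seq.upper().replace("U", "T")
    transcript = transcript.upper().replace("U", "T")
    if len(gene_seq) < anchor_k or len(transcript) < anchor_k:
        raise NoAlignmentError("sequences shorter than the anchor k-mer")
    index: dict[str, int] = {}
    for i in range(len(gene_seq) - anchor_k + 1):
        index.setdefault(gene_seq[i : i + anchor_k], i)
    offsets = Counter()
    for j in range(len(transcript) - anchor_k + 1):
        i = index.get(transcript[j : j + anchor_k])
        if i is not None:
            offsets[i - j] += 1
    if not offsets:
        raise NoAlignmentError("no shared anchor k-mer between gene and transcript")
    offset = offsets.most_common(1)[0][0]
    g0 = max(0, offset)
    t0 = max(0, -offset)
    span = min(len(gene_seq) - g0, len(transcript) - t0)
    if span <= 0:
        raise NoAlignmentError("anchored offset leaves no overlap")
    mismatches = []
    for k in range(span):
        gb, tb = gene_seq[g0 + k], transcript[t0 + k]
        if gb != tb and gb != "N" and tb != "N":
            mismatches.append((g0 + k, gb, tb))
    if len(mismatches) / span > max_divergence:
        raise NoAlignmentError(
            f"divergence {len(mismatches) / span:.3f} exceeds {max_divergence}"
        )
    return mismatches, (g0, g0 + span)


def call_editing_sites(
    genome: AnnotatedGenome,
    gene: GeneFeature,
    transcripts,
    min_support: int = 2,
    min_fraction: float = 0.5,
) -> list[EditingSite]:
    """Call editing sites for one gene from a set of transcript sequences.

    Each transcript covering a position votes; a mismatch becomes a site when
    supported by >= ``min_support`` transcripts and an edited fraction
    >= ``min_fraction`` (ties call the site).
    """
    gene_seq = genomic_span_sequence(genome, gene)
    if not transcripts:
        warnings.warn(f"gene {gene.name!r} has no transcripts; no sites called")
        return []
    coverage = [0] * len(gene_seq)
    votes: dict[tuple[int, str], int] = defaultdict(int)
    for tr in transcripts:
        bases = tr.bases if hasattr(tr, "bases") else str(tr)
        mismatches, (lo, hi) = align_transcript(gene_seq, bases)
        for p in range(lo, hi):
            coverage[p] += 1
        for pos, _ref, alt in mismatches:
            votes[(pos, alt)] += 1
    cmap = GeneCoordinateMap(genome, gene)
    spliced = spliced_sequence(genome, gene).translate(DNA_TO_RNA)
    sites = []
    for (pos, alt), support in sorted(votes.items()):
        frac = support / coverage[pos]
        if support < min_support or frac < min_fraction:
            continue
        region, gene_pos, _intron_idx = cmap.describe(pos)
        dna_rna = gene_seq[pos].translate(DNA_TO_RNA)
        alt_rna = alt.translate(DNA_TO_RNA)
        site = EditingSite(
            gene=gene.name,
            genome_pos=cmap.genomic_position(pos) + 1,
            gene_pos=gene_pos,
            region=region,
            dna_base=dna_rna,
            rna_base=alt_rna,
            support=(support, frac),
        )
        if region == "exon":
            spliced_idx = gene_pos - 1
            codon_idx = spliced_idx // 3
            codon_pos = spliced_idx % 3 + 1
            codon_before = spliced[codon_idx * 3 : codon_idx * 3 + 3]
            if len(codon_before) == 3:
                info = classify_site(codon_before, codon_pos, alt_rna)
                site.aa_pos = codon_idx + 1
                site.codon_pos = codon_pos
                site.codon_before = info["codon_before"]
                site.codon_after = info["codon_after"]
                site.aa_before = info["aa_before"]
                site.aa_after = info["aa_after"]
                site.synonymous = info["synonymous"]
        site.label = format_label(site)
        sites.append(site)
    return sites


def call_editing_for_genome(
    genome: AnnotatedGenome,
    transcripts_by_gene: dict,
    min_support: int = 2,
    min_fraction: float = 0.5,
) -> list[EditingSite]:
    """Call sites for every CDS feature that has transcripts (one IR copy)."""
    seen = set()
    sites = []
    for f in genome.features:
        if f.kind != "CDS" or f.name in seen:
            continue
        if f.name not in transcripts_by_gene:
            continue
        seen.add(f.name)
        sites.extend(
            call_editing_sites(
                genome, f, transcripts_by_gene[f.name], min_support, min_fraction
            )
        )
    return sites


# ---------------------------------------------------------------------------
# summaries


@dataclass
class EditingSummary:
    total: int
    per_gene: dict
    by_change: dict          # 'C->U' style keys
    by_codon_pos: dict
    exon: int
    intron: int
    synonymous: int
    non_synonymous: int
    max_per_gene: int
    gene_ranking: list       # genes sorted by descending site count


def summarize_editing(sites, paper_compat: bool = False) -> EditingSummary:
    """Tally editing sites by type, position and synonymy.

    With ``paper_compat`` the printed pseudo-codon amino acids of intronic
    rows drive synonymy (they count as synonymous/non-synonymous like exonic
    sites); otherwise intronic sites are excluded from the synonymy tallies.
    """
    per_gene = Counter(s.gene for s in sites)
    by_change = Counter(f"{s.dna_base}->{s.rna_base}" for s in sites)
    by_codon_pos = Counter(
        s.codon_pos for s in sites if s.codon_pos is not None
    )
    exon = sum(1 for s in sites if s.region == "exon")
    intron = len(sites) - exon
    syn = nonsyn = 0
    for s in sites:
        if s.region == "exon":
            flag = s.synonymous
            if flag is None and s.aa_before and s.aa_after:
                flag = s.aa_before == s.aa_after
        elif paper_compat and s.aa_before and s.aa_after:
            flag = s.aa_before == s.aa_after
        else:
            continue
        if flag is None:
            continue
        if flag:
            syn += 1
        else:
            nonsyn += 1
    ranking = [g for g, _ in per_gene.most_common()]
    return EditingSummary(
        total=len(sites),
        per_gene=dict(per_gene),
        by_change=dict(by_change),
        by_codon_pos=dict(by_codon_pos),
        exon=exon,
        intron=intron,
        synonymous=syn,
        non_synonymous=nonsyn,
        max_per_gene=max(per_gene.values(), default=0),
        gene_ranking=ranking,
    )
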