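"""Sequence and annotation data model, standard-format I/O and basic transforms.

Internal coordinates are 0-based half-open throughout; user-facing report
writers convert to 1-based inclusive.  Circular sequences allow intervals that
wrap the origin: a wrapping interval is stored as ``(start, end)`` with
``end <= start`` and its length is ``end - start + len(seq)``.

The allowed alphabet is {A,C,G,T,N}.  RNA input (U) is normalised to T on
load; reports that quote codons use RNA letters.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    CoordinateError,
    FormatError,
    SequenceParseError,
    UndefinedValueError,
)

ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "pseudogene")
FUNCTIONAL_GROUPS = (
    "photosynthesis",
    "chloro-respiration",
    "expression-machinery",
    "metabolic-pathway",
    "pseudogene",
)


def normalize_bases(raw: str, line: int | None = None) -> str:
    """Uppercase, convert U->T and validate against the allowed alphabet."""
    bases = raw.upper().replace("U", "T")
    bad = set(bases) - ALPHABET
    if bad:
        raise SequenceParseError(
            f"illegal base(s) {sorted(bad)} in sequence", line=line
        )
    return bases


# ---------------------------------------------------------------------------
# interval arithmetic on a circle


def interval_length(iv: tuple[int, int], seqlen: int) -> int:
    start, end = iv
    if end > start:
        return end - start
    return end - start + seqlen


def interval_wraps(iv: tuple[int, int]) -> bool:
    return iv[1] <= iv[0]


def interval_positions(iv: tuple[int, int], seqlen: int):
    """Yield the genomic positions covered by ``iv`` in order."""
    start, end = iv
    n = interval_length(iv, seqlen)
    for k in range(n):
        yield (start + k) % seqlen


def interval_contains(iv: tuple[int, int], pos: int, seqlen: int) -> bool:
    start, end = iv
    pos %= seqlen
    if end > start:
        return start <= pos < end
    return pos >= start or pos < end


def interval_within(inner: tuple[int, int], outer: tuple[int, int], seqlen: int) -> bool:
    """True if ``inner`` lies entirely inside ``outer`` (circle-aware)."""
    ilen = interval_length(inner, seqlen)
    olen = interval_length(outer, seqlen)
    if ilen > olen:
        return False
    off = (inner[0] - outer[0]) % seqlen
    return off + ilen <= olen


def intervals_overlap(a: tuple[int, int], b: tuple[int, int], seqlen: int) -> bool:
    # small intervals relative to genome; positional test is simplest and safe
    la, lb = interval_length(a, seqlen), interval_length(b, seqlen)
    if la > lb:
        a, b, la, lb = b, a, lb, la
    return any(interval_contains(b, p, seqlen) for p in interval_positions(a, seqlen))


# ---------------------------------------------------------------------------
# domain types


@dataclass
class NucSequence:
    """A nucleotide sequence over {A,C,G,T,N}, optionally circular."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self):
        if not self.bases:
            raise FormatError(f"sequence {self.id!r} is empty")
        self.bases = normalize_bases(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def region(self, iv: tuple[int, int]) -> str:
        """Extract the bases of a (possibly wrapping) interval."""
        start, end = iv
        n = len(self.bases)
        if 0 <= start < end <= n:
            return self.bases[start:end]
        if not self.circular:
            raise CoordinateError(
                f"interval {iv} wraps or exceeds a linear sequence of length {n}"
            )
        start %= n
        end %= n
        if end > start:
            return self.bases[start:end]
        return self.bases[start:] + self.bases[:end]


@dataclass
class GeneFeature:
    """A strand-aware, possibly multi-exon gene feature.

    ``exons`` are 0-based half-open genomic intervals ordered 5'->3' on the
    feature's strand (i.e. descending genomic coordinate for minus-strand
    features).  An exon may wrap the origin on circular genomes.
    """

    name: str
    kind: str
    strand: str
    exons: list[tuple[int, int]]
    copy_tag: str | None = None
    functional_group: str | None = None
    degenerate: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"feature {self.name!r} has no exons")
        self.exons = [tuple(e) for e in self.exons]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def length(self, seqlen: int) -> int:
        return sum(interval_length(e, seqlen) for e in self.exons)

    def span(self, seqlen: int) -> tuple[int, int]:
        """Smallest single interval covering all exons (genomic orientation)."""
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        start = exons[0][0]
        end = exons[-1][1]
        return (start, end)

    def key(self) -> tuple[str, str | None]:
        return (self.name, self.copy_tag)


@dataclass
class AnnotatedGenome:
    sequence: NucSequence
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.exons:
                if not (0 <= s < n and 0 < e <= n):
                    if not self.sequence.circular:
                        raise CoordinateError(
                            f"exon ({s},{e}) of {f.name!r} outside sequence"
                        )
                    if not (0 <= s < n and 0 <= e <= n):
                        raise CoordinateError(
                            f"exon ({s},{e}) of {f.name!r} outside [0,{n}]"
                        )
            if f.kind == "CDS" and not f.degenerate:
                if self.spliced_length(f) % 3 != 0:
                    warnings.warn(
                        f"CDS {f.name!r} spliced length not a multiple of 3; "
                        "flagging degenerate"
                    )
                    f.degenerate = True

    def spliced_length(self, feature: GeneFeature) -> int:
        return feature.length(len(self.sequence))

    def get(self, name: str, copy_tag: str | None = None) -> GeneFeature:
        for f in self.features:
            if f.name == name and (copy_tag is None or f.copy_tag == copy_tag):
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# transforms


def transform(seq: str, kind: str) -> str:
    """Apply one of the three repeat-class transforms to a base string."""
    seq = normalize_bases(seq)
    if kind == "reverse":
        return seq[::-1]
    if kind == "complement":
        return seq.translate(_COMPLEMENT)
    if kind == "reverse_complement":
        return seq.translate(_COMPLEMENT)[::-1]
    raise ValueError(f"unknown transform {kind!r}")


def reverse_complement(seq: str) -> str:
    return transform(seq, "reverse_complement")


def spliced_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Concatenate exons 5'->3'; minus-strand exons are reverse-complemented."""
    parts = []
    for iv in feature.exons:
        s = genome.sequence.region(iv)
        parts.append(s if feature.strand == "+" else reverse_complement(s))
    return "".join(parts)


def genomic_span_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """The gene's full genomic span (introns included), 5'->3' on its strand."""
    span = feature.span(len(genome.sequence))
    s = genome.sequence.region(span)
    return s if feature.strand == "+" else reverse_complement(s)


# ---------------------------------------------------------------------------
# translation (plastid/bacterial code, NCBI table 11, by default)

PLASTID_TABLE_ID = 11


def translate(cds: str, table: int = PLASTID_TABLE_ID) -> str:
    """Translate a CDS; stops render '*', codons containing N render 'X'."""
    cds = normalize_bases(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    code = CodonTable.unambiguous_dna_by_id[table]
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in code.stop_codons:
            out.append("*")
        else:
            out.append(code.forward_table[codon])
    return "".join(out)


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    seq = normalize_bases(seq)
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise UndefinedValueError("GC fraction undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[NucSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        raw = str(rec.seq)
        try:
            bases = normalize_bases(raw)
        except SequenceParseError:
            _raise_with_line(path, rec.id)
        out.append(NucSequence(id=rec.id, bases=bases))
    return out


def _raise_with_line(path, rec_id):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            try:
                normalize_bases(line.strip())
            except SequenceParseError as exc:
                raise SequenceParseError(
                    f"{path}: illegal character in record {rec_id!r}", line=lineno
                ) from exc
    raise SequenceParseError(f"{path}: illegal character in record {rec_id!r}")


def write_fasta(seqs, path, width: int = 70) -> None:
    seqs = [seqs] if isinstance(seqs, NucSequence) else list(seqs)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotation I/O (GenBank flat file and GFF3)
#
# Both dialects are 1-based inclusive on disk and converted to the internal
# 0-based half-open convention.  Multi-exon features round-trip through
# join()/complement() (GenBank) or multiple exon rows sharing a Parent (GFF3).

_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "misc_feature"}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}


def _feature_to_location(feature: GeneFeature, seqlen: int):
    strand = 1 if feature.strand == "+" else -1
    parts = []
    genomic_order = feature.exons if feature.strand == "+" else list(reversed(feature.exons))
    for s, e in genomic_order:
        if e > s:
            parts.append(SimpleLocation(s, e, strand))
        else:  # origin-spanning exon: split at the origin
            parts.append(SimpleLocation(s, seqlen, strand))
            parts.append(SimpleLocation(0, e, strand))
    if len(parts) == 1:
        return parts[0]
    if strand == -1:
        parts = list(reversed(parts))
    return CompoundLocation(parts)


def _location_to_exons(location, seqlen: int, strand: str) -> list[tuple[int, int]]:
    parts = sorted(location.parts, key=lambda p: int(p.start))
    ivs = [(int(p.start), int(p.end)) for p in parts]
    # merge a split origin-spanning exon back into one wrapping interval
    if len(ivs) >= 2 and ivs[0][0] == 0 and ivs[-1][1] == seqlen:
        wrapped = (ivs[-1][0], ivs[0][1])
        ivs = [wrapped] + ivs[1:-1]
        ivs.sort(key=lambda iv: iv[0])
    if strand == "-":
        ivs = sorted(ivs, key=lambda iv: iv[0], reverse=True)
    return ivs


def write_annotation(genome: AnnotatedGenome, path, dialect: str = "genbank") -> None:
    if dialect == "genbank":
        _write_genbank(genome, path)
    elif dialect == "gff3":
        _write_gff3(genome, path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


def _write_genbank(genome: AnnotatedGenome, path) -> None:
    seqlen = len(genome.sequence)
    rec = SeqRecord(
        Seq(genome.sequence.bases),
        id=genome.sequence.id,
        name=genome.sequence.id[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.sequence.circular else "linear",
        },
    )
    for f in genome.features:
        quals = {"gene": [f.name]}
        notes = []
        if f.copy_tag:
            notes.append(f"copy_tag:{f.copy_tag}")
        if f.functional_group:
            notes.append(f"functional_group:{f.functional_group}")
        if f.degenerate:
            notes.append("degenerate")
        if notes:
            quals["note"] = notes
        rec.features.append(
            SeqFeature(
                _feature_to_location(f, seqlen),
                type=_KIND_TO_GB[f.kind],
                qualifiers=quals,
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def _write_gff3(genome: AnnotatedGenome, path) -> None:
    seqid = genome.sequence.id
    seqlen = len(genome.sequence)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {seqlen}\n")
        for i, f in enumerate(genome.features):
            fid = f"feat{i}"
            attrs = [f"ID={fid}", f"Name={f.name}", f"kind={f.kind}"]
            if f.copy_tag:
                attrs.append(f"copy_tag={f.copy_tag}")
            if f.functional_group:
                attrs.append(f"functional_group={f.functional_group}")
            if f.degenerate:
                attrs.append("degenerate=true")
            span = f.span(seqlen)
            span_end = span[0] + interval_length(span, seqlen)  # may exceed seqlen (wrap)
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "plastome",
                        "gene",
                        str(span[0] + 1),
                        str(span_end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            genomic_order = f.exons if f.strand == "+" else list(reversed(f.exons))
            for j, (s, e) in enumerate(genomic_order):
                end = e if e > s else e + seqlen  # wrapping exon written past seqlen
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            "plastome",
                            "exon",
                            str(s + 1),
                            str(end),
                            ".",
                            f.strand,
                            ".",
                            f"ID={fid}.e{j};Parent={fid}",
                        ]
                    )
                    + "\n"
                )
        fh.write("##FASTA\n")
        fh.write(f">{seqid}\n")
        for i in range(0, seqlen, 70):
            fh.write(genome.sequence.bases[i : i + 70] + "\n")


def read_annotation(path, dialect: str = "genbank") -> AnnotatedGenome:
    """Read an annotated genome from a GenBank flat file or GFF3 (+##FASTA)."""
    if dialect == "genbank":
        return _read_genbank(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _parse_notes(notes):
    copy_tag = group = None
    degenerate = False
    for n in notes:
        if n.startswith("copy_tag:"):
            copy_tag = n.split(":", 1)[1]
        elif n.startswith("functional_group:"):
            group = n.split(":", 1)[1]
        elif n == "degenerate":
            degenerate = True
    return copy_tag, group, degenerate


def _read_genbank(path) -> AnnotatedGenome:
    rec = SeqIO.read(str(path), "genbank")
    circular = rec.annotations.get("topology", "linear") == "circular"
    seq = NucSequence(id=rec.id, bases=str(rec.seq), circular=circular)
    seqlen = len(seq)
    features = []
    for bf in rec.features:
        if bf.type not in _GB_TO_KIND:
            continue
        kind = _GB_TO_KIND[bf.type]
        name = bf.qualifiers.get("gene", bf.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if bf.location.strand == -1 else "+"
        exons = _location_to_exons(bf.location, seqlen, strand)
        copy_tag, group, degenerate = _parse_notes(bf.qualifiers.get("note", []))
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                strand=strand,
                exons=exons,
                copy_tag=copy_tag,
                functional_group=group,
                degenerate=degenerate,
            )
        )
    return AnnotatedGenome(sequence=seq, features=features)


def _read_gff3(path) -> AnnotatedGenome:
    import gffutils

    text = open(path).read()
    gff_part, seq = text, None
    if "##FASTA" in text:
        gff_part, fasta_part = text.split("##FASTA", 1)
        buf = io.StringIO(fasta_part.lstrip("\n"))
        recs = list(SeqIO.parse(buf, "fasta"))
        if recs:
            seq = NucSequence(
                id=recs[0].id, bases=str(recs[0].seq), circular=True
            )
    if seq is None:
        raise FormatError(f"{path}: GFF3 file has no ##FASTA section")
    db = gffutils.create_db(
        gff_part, ":memory:", from_string=True, merge_strategy="create_unique"
    )
    seqlen = len(seq)
    features = []
    for gene in db.features_of_type("gene"):
        attrs = gene.attributes
        name = attrs.get("Name", ["?"])[0]
        kind = attrs.get("kind", ["CDS"])[0]
        strand = gene.strand
        exon_rows = list(db.children(gene.id, featuretype="exon"))
        ivs = []
        for ex in sorted(exon_rows, key=lambda r: r.start):
            s, e = ex.start - 1, ex.end  # 1-based inclusive -> 0-based half-open
            if e > seqlen:  # wrapping exon written past the end
                s, e = s % seqlen, e % seqlen
            if not (0 <= s < seqlen):
                raise CoordinateError(f"exon of {name!r} outside sequence")
            ivs.append((s, e))
        if strand == "-":
            ivs = sorted(ivs, key=lambda iv: iv[0], reverse=True)
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                strand=strand,
                exons=ivs,
                copy_tag=attrs.get("copy_tag", [None])[0],
                functional_group=attrs.get("functional_group", [None])[0],
                degenerate=attrs.get("degenerate", ["false"])[0] == "true",
            )
        )
    return AnnotatedGenome(sequence=seq, features=features)
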