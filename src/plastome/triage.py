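"""Contig triage by mapped read depth.

Organellar genomes are present in many copies per cell, so assembled contigs
separate cleanly by coverage: plastid contigs run in the thousands-x, and
mitochondrial contigs sit well above nuclear ones.  Classification uses
configurable depth bands; depths falling between bands stay 'ambiguous'
rather than being forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class TriageParams:
    cp_min_depth: float = 2000.0
    mt_depth_range: tuple[float, float] = (100.0, 500.0)
    nuclear_max_depth: float = 100.0

    def __post_init__(self):
        lo, hi = self.mt_depth_range
        if not (self.nuclear_max_depth <= lo <= hi):
            raise ValueError("depth bands must be ordered (nuclear <= mt range)")
        # the mt upper bound may meet cp_min_depth; cp takes precedence there


@dataclass
class ContigRecord:
    id: str
    length: int
    mean_depth: float
    klass: str


def classify_contig_depth(depth: float, params: TriageParams) -> str:
    if depth < 0:
        raise ValueError("negative depth")
    if depth >= params.cp_min_depth:
        return "chloroplast"
    lo, hi = params.mt_depth_range
    if lo <= depth <= hi:
        return "mitochondrial"
    if depth <= params.nuclear_max_depth:
        return "nuclear"
    return "ambiguous"


def classify_contigs(records, params: TriageParams | None = None) -> list[ContigRecord]:
    """Classify (id, length, mean_depth) records; monotone in depth."""
    params = params or TriageParams()
    return [
        ContigRecord(
            id=cid,
            length=int(length),
            mean_depth=float(depth),
            klass=classify_contig_depth(float(depth), params),
        )
        for cid, length, depth in records
    ]


def kmer_sharing_fraction(contig: str, reference: str, k: int = 31) -> float:
    """Fraction of the contig's k-mers present in a reference sequence.

    Optional confirmation step for depth-based calls: >= 0.5 sharing supports
    assignment to the reference's genome.
    """
    contig = contig.upper()
    reference = reference.upper()
    if len(contig) < k:
        return 0.0
    ref_kmers = {reference[i : i + k] for i in range(len(reference) - k + 1)}
    total = len(contig) - k + 1
    hits = sum(1 for i in range(total) if contig[i : i + k] in ref_kmers)
    return hits / total
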