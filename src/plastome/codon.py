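"""Codon usage over annotated CDS features under the plastid genetic code.

Counts are keyed by RNA-letter codons (AUG, UUA, ...) to match the way
plastome papers print codon tables; stop codons are tallied separately from
the twenty amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UndefinedValueError
from .inventory import PSEUDOGENE_NAMES
from .seqio import AnnotatedGenome, spliced_sequence, translate

RNA_TO_DNA = str.maketrans("U", "T")
DNA_TO_RNA = str.maketrans("T", "U")


@dataclass
class CodonUsage:
    counts: dict = field(default_factory=dict)  # RNA codon -> count
    skipped_with_n: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, codon_rna: str, count: int = 1) -> None:
        self.counts[codon_rna] = self.counts.get(codon_rna, 0) + count


def codon_amino_acid(codon_rna: str) -> str:
    """One-letter amino acid for an RNA codon under the plastid code ('*' stop)."""
    return translate(codon_rna.translate(RNA_TO_DNA))


def count_codons(
    genome: AnnotatedGenome,
    include_pseudogenes: bool = False,
    force_degenerate: bool = False,
) -> CodonUsage:
    """Tally frame-0 codons of every included spliced CDS.

    Default filter: kind CDS, non-degenerate, pseudogenes excluded.  Codons
    containing N are skipped and tallied in ``skipped_with_n``.
    """
    usage = CodonUsage()
    for f in genome.features:
        if f.kind not in ("CDS", "pseudogene"):
            continue
        if not include_pseudogenes and (
            f.kind == "pseudogene"
            or f.name in PSEUDOGENE_NAMES
            or f.functional_group == "pseudogene"
        ):
            continue
        if f.degenerate and not force_degenerate:
            continue
        cds = spliced_sequence(genome, f)
        usable = len(cds) - len(cds) % 3
        for i in range(0, usable, 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                usage.skipped_with_n += 1
            else:
                usage.add(codon.translate(DNA_TO_RNA))
    return usage


def aggregate_by_amino_acid(usage: CodonUsage) -> dict:
    """Totals per amino acid under the plastid code; stops reported separately."""
    totals: dict[str, int] = {}
    stop_total = 0
    for codon, count in usage.counts.items():
        aa = codon_amino_acid(codon)
        if aa == "*":
            stop_total += count
        else:
            totals[aa] = totals.get(aa, 0) + count
    return {"aa_totals": totals, "stop_total": stop_total}


def third_position_composition(usage: CodonUsage) -> float:
    """Fraction of codons whose third letter is A or U."""
    total = usage.total
    if total == 0:
        raise UndefinedValueError("third-position composition of an empty table")
    at = sum(c for codon, c in usage.counts.items() if codon[2] in "AU")
    return at / total
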