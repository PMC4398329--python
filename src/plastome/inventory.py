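"""Gene inventory: functional-group classification, copy accounting and
intron census for an annotated plastome.

The five functional groups follow the conventional plastid breakdown:
photosynthesis, chloro-respiration (ndh genes), expression machinery
(rpo/rpl/rps/matK), metabolic pathway (accD/clpP/cemA), and pseudogenes.
Classification is a packaged name->group table (plastid genes are assigned
by name, not by computation) and is overridable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .errors import PlastomeError
from .seqio import AnnotatedGenome, FUNCTIONAL_GROUPS

# explicit assignments that prefixes cannot decide
_EXPLICIT_GROUPS = {
    "rbcL": "photosynthesis",
    "ccsA": "photosynthesis",
    "ycf3": "photosynthesis",
    "ycf4": "photosynthesis",
    "matK": "expression-machinery",
    "accD": "metabolic-pathway",
    "clpP": "metabolic-pathway",
    "cemA": "metabolic-pathway",
    "lhbA": "pseudogene",
    "ycf2": "pseudogene",
    "ycf15": "pseudogene",
    "ycf68": "pseudogene",
}

_PREFIX_GROUPS = [
    ("psa", "photosynthesis"),
    ("psb", "photosynthesis"),
    ("pet", "photosynthesis"),
    ("atp", "photosynthesis"),
    ("ndh", "chloro-respiration"),
    ("rpo", "expression-machinery"),
    ("rpl", "expression-machinery"),
    ("rps", "expression-machinery"),
    ("orf", "pseudogene"),
]

PSEUDOGENE_NAMES = frozenset(
    {"ycf2", "ycf15", "ycf68", "lhbA", "orf42", "orf56", "orf188"}
)


def classify_function(gene_name: str, overrides: dict | None = None) -> str:
    """Deterministic gene-name -> functional-group mapping.

    Unknown names fall back to 'pseudogene' (unknown function) with a warning.
    """
    if overrides and gene_name in overrides:
        return overrides[gene_name]
    if gene_name in _EXPLICIT_GROUPS:
        return _EXPLICIT_GROUPS[gene_name]
    for prefix, group in _PREFIX_GROUPS:
        if gene_name.startswith(prefix):
            return group
    warnings.warn(f"gene name {gene_name!r} not in the plastid nomenclature; "
                  "classifying as pseudogene/unknown")
    return "pseudogene"


@dataclass(frozen=True)
class GeneRecord:
    """One distinct gene name with its copy count and intron count."""

    name: str
    kind: str           # CDS / tRNA / rRNA (pseudogenes carry kind CDS)
    copies: int
    introns: int = 0
    group: str | None = None


@dataclass
class InventorySummary:
    total_genes: int = 0                 # total copies, all kinds
    protein_coding_total: int = 0        # copies
    protein_single: int = 0
    protein_duplicated: int = 0          # distinct duplicated gene names
    trna_total: int = 0
    trna_single: int = 0
    trna_duplicated: int = 0
    rrna_total: int = 0
    group_genes: dict = field(default_factory=dict)   # group -> sorted names
    group_counts: dict = field(default_factory=dict)
    intron_one: int = 0                  # distinct genes with exactly 1 intron
    intron_two: int = 0
    intron_genes: dict = field(default_factory=dict)  # name -> intron count


def _records_from_genome(genome: AnnotatedGenome) -> list[GeneRecord]:
    by_name: dict[str, list] = {}
    for f in genome.features:
        by_name.setdefault(f.name, []).append(f)
    records = []
    for name, feats in sorted(by_name.items()):
        tags = [f.copy_tag for f in feats]
        if len(tags) != len(set(tags)) and any(t is not None for t in tags):
            raise PlastomeError(f"duplicate copy_tag on gene {name!r}")
        if len(feats) > 2:
            raise PlastomeError(f"gene {name!r} has {len(feats)} copies (max 2)")
        kind = feats[0].kind
        if kind == "pseudogene":
            kind = "CDS"
        group = feats[0].functional_group
        if group is None and kind == "CDS":
            group = classify_function(name)
        records.append(
            GeneRecord(
                name=name,
                kind=kind,
                copies=len(feats),
                introns=max(f.n_introns for f in feats),
                group=group,
            )
        )
    return records


def summarize_inventory(source) -> InventorySummary:
    """Copy-accounting summary from an AnnotatedGenome or GeneRecord list.

    A gene present once in each IR counts as duplicated (2 copies):
    total copies = singles + 2 x duplicated names, per kind.
    """
    records = (
        _records_from_genome(source)
        if isinstance(source, AnnotatedGenome)
        else list(source)
    )
    s = InventorySummary()
    group_names: dict[str, list] = {g: [] for g in FUNCTIONAL_GROUPS}
    for r in records:
        s.total_genes += r.copies
        if r.kind == "CDS":
            s.protein_coding_total += r.copies
            if r.copies == 2:
                s.protein_duplicated += 1
            else:
                s.protein_single += 1
            group = r.group or classify_function(r.name)
            group_names.setdefault(group, []).append(r.name)
        elif r.kind == "tRNA":
            s.trna_total += r.copies
            if r.copies == 2:
                s.trna_duplicated += 1
            else:
                s.trna_single += 1
        elif r.kind == "rRNA":
            s.rrna_total += r.copies
        if r.introns == 1:
            s.intron_one += 1
        elif r.introns == 2:
            s.intron_two += 1
        if r.introns:
            s.intron_genes[r.name] = r.introns
    s.group_genes = {g: sorted(names) for g, names in group_names.items()}
    s.group_counts = {g: len(names) for g, names in s.group_genes.items()}
    return s


def intron_census(source) -> dict:
    """Per-gene intron counts plus totals (exon count - 1 per feature)."""
    records = (
        _records_from_genome(source)
        if isinstance(source, AnnotatedGenome)
        else list(source)
    )
    per_gene = {r.name: r.introns for r in records if r.introns > 0}
    counter = Counter(per_gene.values())
    return {
        "per_gene": per_gene,
        "genes_with_introns": len(per_gene),
        "genes_one_intron": counter.get(1, 0),
        "genes_two_introns": counter.get(2, 0),
        "total_introns": sum(per_gene.values()),
    }
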