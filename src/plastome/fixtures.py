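"""Loaders for the packaged worked-example tables (plastome gene inventory,
codon usage, repeat catalogue and RNA-editing sites).

Each loader validates the transcription on load: row counts, repeat-sequence
lengths, codon-substitution consistency and label grammar.  Printed
irregularities are preserved verbatim and flagged in each row's ``anomaly``
field rather than silently corrected; validation whitelists exactly those
flagged rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .codon import CodonUsage
from .editing import EditingSite
from .errors import FixtureError
from .inventory import GeneRecord

TABLE_FILES = {
    "table1": "table1_genes.tsv",
    "table2": "table2_codon_usage.tsv",
    "table3": "table3_repeats.tsv",
    "table4": "table4_editing.tsv",
}

EXPECTED_ROWS = {"table1": 124, "table2": 60, "table3": 13, "table4": 43}


@dataclass
class Fixture:
    table_id: str
    rows: list[dict]
    provenance: str


def _read_rows(table_id: str) -> list[dict]:
    try:
        fname = TABLE_FILES[table_id]
    except KeyError:
        raise FixtureError(f"unknown fixture table {table_id!r}") from None
    ref = resources.files("plastome").joinpath("data", fname)
    with ref.open() as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    rows = [dict(r) for r in reader]
    if len(rows) != EXPECTED_ROWS[table_id]:
        raise FixtureError(
            f"{table_id}: expected {EXPECTED_ROWS[table_id]} rows, got {len(rows)}"
        )
    return rows


def load_fixture(table_id: str) -> Fixture:
    rows = _read_rows(table_id)
    validator = {
        "table1": _validate_table1,
        "table2": _validate_table2,
        "table3": _validate_table3,
        "table4": _validate_table4,
    }[table_id]
    validator(rows)
    return Fixture(table_id=table_id, rows=rows, provenance=TABLE_FILES[table_id])


# ---------------------------------------------------------------------------
# validation


def _validate_table1(rows):
    for r in rows:
        r["copies"] = int(r["copies"])
        r["introns"] = int(r["introns"])
        if r["copies"] not in (1, 2):
            raise FixtureError(f"table1: bad copy count for {r['name']}")
    protein = [r for r in rows if r["kind"] == "CDS"]
    if sum(r["copies"] for r in protein) != 94:
        raise FixtureError("table1: protein copy arithmetic broken")


def _validate_table2(rows):
    seen = set()
    for r in rows:
        r["count"] = int(r["count"])
        codon = r["codon"]
        if len(codon) != 3 or any(b not in "ACGU" for b in codon):
            raise FixtureError(f"table2: bad codon {codon!r}")
        if codon in seen:
            raise FixtureError(f"table2: duplicate codon {codon!r}")
        seen.add(codon)


def _validate_table3(rows):
    for r in rows:
        r["size"] = int(r["size"])
        if r["anomaly"] == "." and len(r["sequence"]) != r["size"]:
            raise FixtureError(
                f"table3: sequence length {len(r['sequence'])} != size {r['size']}"
            )


def _validate_table4(rows):
    for r in rows:
        r["genome_pos"] = int(r["genome_pos"])
        r["gene_pos"] = int(r["gene_pos"])
        r["aa_pos"] = None if r["aa_pos"] == "." else int(r["aa_pos"])
        r["triplet_pos"] = None if r["triplet_pos"] == "." else int(r["triplet_pos"])
        cb, ca = r["codon_before"], r["codon_after"]
        diffs = [i for i in range(3) if cb[i] != ca[i]]
        if len(diffs) != 1:
            raise FixtureError(f"table4: codons {cb}->{ca} differ at {len(diffs)} sites")
        if cb[diffs[0]] != r["dna_base"] or ca[diffs[0]] != r["rna_base"]:
            raise FixtureError(f"table4: base change inconsistent in {r['label']}")
        if r["triplet_pos"] is not None and diffs[0] != r["triplet_pos"] - 1:
            raise FixtureError(f"table4: triplet position inconsistent in {r['label']}")
        expected = (
            f"{r['gene']}{'e' if r['region'] == 'exon' else 'i'}"
            f"{r['rna_base']}{r['gene_pos']}{r['aa_before']}{r['aa_after']}"
        )
        if expected != r["label"] and r["anomaly"] == ".":
            raise FixtureError(f"table4: label {r['label']!r} != derived {expected!r}")


# ---------------------------------------------------------------------------
# typed converters


def table1_records() -> list[GeneRecord]:
    rows = load_fixture("table1").rows
    return [
        GeneRecord(
            name=r["name"],
            kind=r["kind"],
            copies=r["copies"],
            introns=r["introns"],
            group=None if r["group"] == "." else r["group"],
        )
        for r in rows
    ]


def table2_usage() -> CodonUsage:
    usage = CodonUsage()
    for r in load_fixture("table2").rows:
        usage.add(r["codon"], r["count"])
    return usage


def table3_hits() -> list[dict]:
    """Repeat rows with location kinds parsed from the printed strings."""
    rows = load_fixture("table3").rows
    for r in rows:
        r["kind1"] = _parse_location_kind(r["loc1"])
        r["kind2"] = _parse_location_kind(r["loc2"])
    return rows


def _parse_location_kind(text: str) -> str:
    if text.startswith("Intron"):
        return "intron"
    if text.startswith("IGS"):
        return "IGS"
    if text.startswith("trn"):
        return "tRNA"
    return "coding"


def table4_sites() -> list[EditingSite]:
    sites = []
    for r in load_fixture("table4").rows:
        site = EditingSite(
            gene=r["gene"],
            genome_pos=r["genome_pos"],
            gene_pos=r["gene_pos"],
            region=r["region"],
            dna_base=r["dna_base"],
            rna_base=r["rna_base"],
            aa_pos=r["aa_pos"],
            codon_pos=r["triplet_pos"],
            codon_before=r["codon_before"],
            codon_after=r["codon_after"],
            aa_before=r["aa_before"],
            aa_after=r["aa_after"],
            synonymous=(r["aa_before"] == r["aa_after"])
            if r["region"] == "exon"
            else None,
            label=r["label"],
        )
        sites.append(site)
    return sites
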