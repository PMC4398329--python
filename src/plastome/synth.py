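"""Synthetic plastome, transcript, count and depth generators with ground truth.

The default plastome plan is a miniature quadripartite circle (LSC 18 kb,
IR 6 kb, SSC 4 kb; region GC 0.36/0.41/0.34) carrying spliced gene models on
both strands, IR-duplicated genes, planted repeats of the three classes and
planted editing events of the three observed base-change types.  All
randomness flows from the plan's single seed; the same seed reproduces
byte-identical output.

Planted features are flanked by short anti-match guard zones so that the
planted coordinates are also the maximal ones under the repeat-hit contract
(real plastome IR boundaries are similarly sharp); region boundaries get the
same treatment so quadripartite recovery is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import PlanError
from .seqio import (
    AnnotatedGenome,
    GeneFeature,
    NucSequence,
    genomic_span_sequence,
    transform,
)
from .editing import GeneCoordinateMap

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

GUARD = 12  # anti-match flank length around planted repeats


# ---------------------------------------------------------------------------
# plans


@dataclass
class GenePlan:
    name: str
    kind: str                   # CDS / tRNA / rRNA
    region: str                 # LSC / IRa / SSC
    offset: int                 # within the region; may be negative (spills
                                # into the previous region, e.g. across ISa)
    strand: str
    exon_lengths: list[int]
    intron_lengths: list[int] = field(default_factory=list)
    group: str | None = None


@dataclass
class RepeatPlan:
    klass: str
    length: int
    loc1: tuple[str, int]       # (region, offset)
    loc2: tuple[str, int]


@dataclass
class EditPlan:
    gene: str
    region: str                 # 'exon' | 'intron'
    dna_base: str               # RNA letters: C->U stored as ('C','U')
    rna_base: str
    at: float = 0.5             # relative position within the CDS/intron


def default_gene_plans() -> list[GenePlan]:
    return [
        GenePlan("psbA", "CDS", "LSC", 500, "+", [999]),
        GenePlan("matK", "CDS", "LSC", 2000, "-", [900]),
        GenePlan("atpF", "CDS", "LSC", 3500, "+", [300, 450], [350]),
        GenePlan("ycf3", "CDS", "LSC", 5200, "-", [150, 231, 249], [300, 280]),
        GenePlan("rbcL", "CDS", "LSC", 7000, "+", [1200]),
        GenePlan("trnG-UCC", "tRNA", "LSC", 9000, "+", [30, 40], [400]),
        GenePlan("trnS-GCU", "tRNA", "LSC", 10000, "-", [85]),
        GenePlan("rps16", "CDS", "LSC", 11000, "+", [240, 261], [500]),
        GenePlan("accD", "CDS", "LSC", 13000, "+", [999]),
        GenePlan("rps19", "CDS", "LSC", 17000, "+", [279]),
        GenePlan("ndhB", "CDS", "IRa", 800, "+", [738, 723], [600]),
        GenePlan("rrn16", "rRNA", "IRa", 3000, "+", [1490]),
        GenePlan("trnV-GAC", "tRNA", "IRa", 4800, "+", [72]),
        GenePlan("ndhF", "CDS", "SSC", 300, "-", [1800]),
        GenePlan("ndhA", "CDS", "SSC", 2300, "+", [540, 543], [500]),
    ]


def default_repeat_plans() -> list[RepeatPlan]:
    return [
        RepeatPlan("forward", 39, ("LSC", 8400), ("LSC", 15500)),
        RepeatPlan("palindromic", 19, ("LSC", 12400), ("LSC", 15800)),
        RepeatPlan("reverse", 24, ("LSC", 4700), ("LSC", 16400)),
    ]


def default_edit_plans() -> list[EditPlan]:
    # 6 C->U, 3 U->C, 1 G->A planted events
    return [
        EditPlan("psbA", "exon", "C", "U", 0.30),
        EditPlan("psbA", "exon", "C", "U", 0.60),
        EditPlan("rbcL", "exon", "C", "U", 0.50),
        EditPlan("accD", "exon", "C", "U", 0.50),
        EditPlan("ndhB", "exon", "C", "U", 0.40),
        EditPlan("ndhA", "intron", "C", "U", 0.50),
        EditPlan("matK", "exon", "U", "C", 0.35),
        EditPlan("matK", "exon", "U", "C", 0.70),
        EditPlan("ycf3", "exon", "U", "C", 0.50),
        EditPlan("ndhB", "exon", "G", "A", 0.70),
    ]


@dataclass
class PlastomePlan:
    lsc_len: int = 18000
    ir_len: int = 6000
    ssc_len: int = 4000
    gc: dict = field(
        default_factory=lambda: {"LSC": 0.36, "IRa": 0.41, "SSC": 0.34}
    )
    genes: list[GenePlan] = field(default_factory=default_gene_plans)
    repeats: list[RepeatPlan] = field(default_factory=default_repeat_plans)
    edits: list[EditPlan] = field(default_factory=default_edit_plans)
    ir_mismatches: int = 0
    seed: int = 1
    genome_id: str = "synthetic-plastome"

    @property
    def total_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    def region_start(self, region: str) -> int:
        return {
            "LSC": 0,
            "IRa": self.lsc_len,
            "SSC": self.lsc_len + self.ir_len,
            "IRb": self.lsc_len + self.ir_len + self.ssc_len,
        }[region]

    def region_interval(self, region: str) -> tuple[int, int]:
        start = self.region_start(region)
        length = self.ir_len if region in ("IRa", "IRb") else getattr(
            self, f"{region.lower()}_len"
        )
        return (start, start + length)


@dataclass
class PlannedEdit:
    gene: str
    region: str
    gene_pos: int               # 1-based in spliced CDS or within the intron
    intron_index: int | None
    span_offset: int            # along the gene's genomic span, 5'->3'
    genome_pos: int             # 1-based
    dna_base: str               # RNA letters
    rna_base: str


@dataclass
class PlastomeTruth:
    regions: dict
    ir_identity: float
    repeats: list
    edits: list[PlannedEdit]
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "regions": {k: list(v) for k, v in self.regions.items()},
            "ir_identity": self.ir_identity,
            "repeats": self.repeats,
            "edits": [asdict(e) for e in self.edits],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# plastome generation


class _Canvas:
    """Mutable genome under construction with collision tracking."""

    def __init__(self, arr: np.ndarray):
        self.arr = arr
        self.claims: list[tuple[int, int, str]] = []

    def claim(self, start: int, end: int, what: str) -> None:
        for s, e, w in self.claims:
            if start < e and s < end:
                raise PlanError(f"{what} [{start},{end}) collides with {w} [{s},{e})")
        self.claims.append((start, end, what))

    def write(self, start: int, text: str) -> None:
        self.arr[start : start + len(text)] = list(text)


def _random_bases(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


_STOPS = {"TAA", "TAG", "TGA"}


def _make_cds(rng, length: int, gc: float) -> str:
    """Random CDS at the target GC: internal stop codons patched in frame."""
    if length % 3 or length < 9:
        raise PlanError(f"CDS length {length} must be a multiple of 3 and >= 9")
    body = list(_random_bases(rng, length - 6, gc))
    for i in range(0, len(body) - 2, 3):
        if "".join(body[i : i + 3]) in _STOPS:
            body[i] = "C"  # CAA/CAG/CGA are all sense codons
    return "ATG" + "".join(body) + "TAA"


def _build_gene(rng, plan: GenePlan, gc: float):
    """Return (+strand genomic segment, exon rel-intervals ordered 5'->3')."""
    if len(plan.intron_lengths) != max(0, len(plan.exon_lengths) - 1):
        raise PlanError(f"gene {plan.name}: intron/exon count mismatch")
    spliced_len = sum(plan.exon_lengths)
    if plan.kind == "CDS":
        spliced = _make_cds(rng, spliced_len, gc)
    else:
        spliced = _random_bases(rng, spliced_len, gc)
    parts = []
    pos = 0
    rel = []  # 5'->3' layout positions
    cursor = 0
    for k, elen in enumerate(plan.exon_lengths):
        parts.append(spliced[pos : pos + elen])
        rel.append((cursor, cursor + elen))
        pos += elen
        cursor += elen
        if k < len(plan.intron_lengths):
            parts.append(_random_bases(rng, plan.intron_lengths[k], gc))
            cursor += plan.intron_lengths[k]
    layout = "".join(parts)
    if plan.strand == "+":
        return layout, rel
    seg = transform(layout, "reverse_complement")
    total = len(layout)
    rel_minus = [(total - e, total - s) for s, e in rel]  # keep 5'->3' order
    return seg, rel_minus


def _mirror_interval(iv, ira_start, ir_len, irb_start):
    s, e = iv
    return (irb_start + (ira_start + ir_len - e), irb_start + (ira_start + ir_len - s))


def generate_plastome(plan: PlastomePlan | None = None, seed: int | None = None):
    """Build the planned circular genome; returns (AnnotatedGenome, truth)."""
    plan = plan or PlastomePlan()
    if seed is not None:
        plan = replace(plan, seed=seed)
    rng = np.random.default_rng(plan.seed)
    n = plan.total_len
    arr = np.empty(n, dtype="<U1")
    for region in ("LSC", "IRa", "SSC"):
        s, e = plan.region_interval(region)
        arr[s:e] = list(_random_bases(rng, e - s, plan.gc[region]))
    canvas = _Canvas(arr)
    ira_start = plan.region_start("IRa")
    irb_start = plan.region_start("IRb")
    ssc_end = plan.region_start("IRb")

    features: list[GeneFeature] = []
    # --- genes -------------------------------------------------------------
    for gp in plan.genes:
        seg, rel = _build_gene(rng, gp, plan.gc.get(gp.region, 0.38))
        start = plan.region_start(gp.region) + gp.offset
        if start < 0 or start + len(seg) > ssc_end:
            raise PlanError(f"gene {gp.name} outside the writable LSC+IRa+SSC range")
        canvas.claim(start, start + len(seg), f"gene {gp.name}")
        canvas.write(start, seg)
        exons = [(start + s, start + e) for s, e in rel]
        in_ir = gp.region == "IRa" and gp.offset >= 0 and start + len(seg) <= ira_start + plan.ir_len
        features.append(
            GeneFeature(
                name=gp.name,
                kind=gp.kind,
                strand=gp.strand,
                exons=exons,
                copy_tag="A" if in_ir else None,
                functional_group=gp.group,
            )
        )
    # --- repeats -----------------------------------------------------------
    planted_repeats = []
    for rp in plan.repeats:
        seq1 = _random_bases(rng, rp.length, plan.gc.get(rp.loc1[0], 0.38))
        copy2 = seq1 if rp.klass == "forward" else transform(
            seq1, "reverse" if rp.klass == "reverse" else "reverse_complement"
        )
        starts = []
        for (region, off), text in (((rp.loc1), seq1), ((rp.loc2), copy2)):
            start = plan.region_start(region) + off
            canvas.claim(start - GUARD, start + len(text) + GUARD, f"repeat@{start}")
            canvas.write(start, text)
            starts.append(start)
        _write_repeat_guards(canvas.arr, rng, rp.klass, starts[0], starts[1], rp.length)
        planted_repeats.append(
            {
                "klass": rp.klass,
                "length": rp.length,
                "pos1": [starts[0], starts[0] + rp.length],
                "pos2": [starts[1], starts[1] + rp.length],
            }
        )
    # --- editing events (force the reference base, record the plan) --------
    genome_tmp = AnnotatedGenome(
        sequence=NucSequence(plan.genome_id, "".join(arr), circular=True),
        features=[f for f in features],
    )
    edits = _resolve_edits(plan, genome_tmp, canvas)
    # --- IRb = reverse complement of the final IRa --------------------------
    ira_seq = "".join(canvas.arr[ira_start : ira_start + plan.ir_len])
    canvas.arr[irb_start : irb_start + plan.ir_len] = list(
        transform(ira_seq, "reverse_complement")
    )
    # mirrored copies of IR genes
    for f in [f for f in features if f.copy_tag == "A"]:
        exons = [
            _mirror_interval(iv, ira_start, plan.ir_len, irb_start) for iv in f.exons
        ]
        features.append(
            GeneFeature(
                name=f.name,
                kind=f.kind,
                strand="-" if f.strand == "+" else "+",
                exons=exons,
                copy_tag="B",
                functional_group=f.functional_group,
            )
        )
    # --- boundary guards: make the planted IR pair exactly maximal ----------
    _write_boundary_guards(canvas.arr, plan)
    # --- optional planted IR mismatches -------------------------------------
    free = [
        p
        for p in range(irb_start + 100, irb_start + plan.ir_len - 100)
        if not any(s <= _mirror_pos(p, ira_start, plan.ir_len, irb_start) < e
                   for s, e, _ in canvas.claims)
    ]
    mm_positions = sorted(
        rng.choice(free, size=plan.ir_mismatches, replace=False).tolist()
    ) if plan.ir_mismatches else []
    for p in mm_positions:
        old = canvas.arr[p]
        choices = [b for b in "ACGT" if b != old]
        canvas.arr[p] = choices[int(rng.integers(len(choices)))]

    genome = AnnotatedGenome(
        sequence=NucSequence(plan.genome_id, "".join(canvas.arr), circular=True),
        features=features,
    )
    truth = PlastomeTruth(
        regions={r: list(plan.region_interval(r)) for r in ("LSC", "IRa", "SSC", "IRb")},
        ir_identity=1.0 - plan.ir_mismatches / plan.ir_len,
        repeats=planted_repeats,
        edits=edits,
        seed=plan.seed,
    )
    return genome, truth


def _mirror_pos(p, ira_start, ir_len, irb_start):
    return ira_start + ir_len - 1 - (p - irb_start)


def _write_repeat_guards(arr, rng, klass, start1, start2, length):
    """Break the diagonal match at every guard position flanking a planted pair."""
    for t in range(1, GUARD + 1):
        if klass == "forward":
            pairs = [
                (start1 - t, start2 - t),
                (start1 + length - 1 + t, start2 + length - 1 + t),
            ]
        else:  # mirrored alignment for reverse and palindromic
            pairs = [
                (start1 - t, start2 + length - 1 + t),
                (start1 + length - 1 + t, start2 - t),
            ]
        for x, y in pairs:
            required = arr[x] if klass != "palindromic" else _COMP[arr[x]]
            if arr[y] == required:
                choices = [b for b in "ACGT" if b != required]
                arr[y] = choices[int(rng.integers(len(choices)))]


def _write_boundary_guards(arr, plan: PlastomePlan):
    n = plan.total_len
    ira_s, ira_e = plan.region_interval("IRa")
    irb_s, irb_e = plan.region_interval("IRb")
    ssc_s, ssc_e = plan.region_interval("SSC")
    for t in range(3):
        # left of IRa pairs with right of IRb (wraps to the LSC start)
        x, y = ira_s - 1 - t, (irb_e + t) % n
        if arr[x] == _COMP[arr[y]]:
            arr[x] = _pick_nonmatching(arr[x], _COMP[arr[y]])
        # right of IRa (SSC start) pairs with left of IRb (SSC end)
        x, y = ira_e + t, irb_s - 1 - t
        if arr[x] == _COMP[arr[y]]:
            arr[x] = _pick_nonmatching(arr[x], _COMP[arr[y]])


def _pick_nonmatching(current, forbidden):
    for b in "ACGT":
        if b != forbidden and b != current:
            return b
    return "A"


def _resolve_edits(plan, genome, canvas) -> list[PlannedEdit]:
    by_name = {}
    for f in genome.features:
        by_name.setdefault(f.name, f)
    out = []
    used: set[tuple[str, int]] = set()
    for ep in plan.edits:
        feature = by_name.get(ep.gene)
        if feature is None:
            raise PlanError(f"edit references unknown gene {ep.gene!r}")
        cmap = GeneCoordinateMap(genome, feature)
        offsets = [
            i
            for i, (region, _idx, _rel) in enumerate(cmap.kind)
            if region == ep.region
        ]
        if ep.region == "exon":
            offsets = offsets[3:-3]  # keep start/stop codons intact
        else:
            offsets = offsets[2:-2]
        if not offsets:
            raise PlanError(f"gene {ep.gene} has no {ep.region} positions to edit")
        k = min(len(offsets) - 1, int(round(ep.at * (len(offsets) - 1))))
        off = offsets[k]
        while (ep.gene, off) in used:
            k = (k + 7) % len(offsets)
            off = offsets[k]
        used.add((ep.gene, off))
        gpos = cmap.genomic_position(off)
        dna_dnaletter = ep.dna_base.replace("U", "T")
        base_on_genome = (
            dna_dnaletter if feature.strand == "+" else _COMP[dna_dnaletter]
        )
        canvas.arr[gpos] = base_on_genome
        region, gene_pos, intron_idx = cmap.describe(off)
        out.append(
            PlannedEdit(
                gene=ep.gene,
                region=region,
                gene_pos=gene_pos,
                intron_index=intron_idx,
                span_offset=off,
                genome_pos=gpos + 1,
                dna_base=ep.dna_base,
                rna_base=ep.rna_base,
            )
        )
    return out


# ---------------------------------------------------------------------------
# transcripts


def generate_transcripts(
    genome: AnnotatedGenome,
    truth: PlastomeTruth,
    coverage: int = 5,
    edit_fraction: float = 1.0,
    seed: int = 0,
):
    """Per-CDS unspliced transcript copies with planted edits applied.

    Edits are applied to the first ``round(edit_fraction * coverage)`` copies
    of each gene, so the edited fraction at every planted site equals
    ``edit_fraction`` exactly.  Returns (transcripts_by_gene, edits).
    """
    del seed  # transcripts are deterministic given genome+truth
    edits_by_gene: dict[str, list[PlannedEdit]] = {}
    for e in truth.edits:
        edits_by_gene.setdefault(e.gene, []).append(e)
    n_edited = int(round(edit_fraction * coverage))
    out: dict[str, list[NucSequence]] = {}
    seen = set()
    for f in genome.features:
        if f.kind != "CDS" or f.name in seen:
            continue
        seen.add(f.name)
        pre = genomic_span_sequence(genome, f)
        edited = list(pre)
        for e in edits_by_gene.get(f.name, []):
            edited[e.span_offset] = e.rna_base.replace("U", "T")
        edited = "".join(edited)
        copies = []
        for i in range(coverage):
            seq = edited if i < n_edited else pre
            copies.append(NucSequence(id=f"{f.name}_t{i}", bases=seq))
        out[f.name] = copies
    return out, truth.edits


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountPlan:
    n_genes: int = 25
    n_de: int = 5
    baseline_mean: float = 500.0
    log2fc: float = 2.0
    dispersion: float = 0.05
    libraries: tuple = ("leaf", "stem")
    library_size: int = 100_000
    gene_length_range: tuple = (300, 2000)
    seed: int = 1


def generate_counts(plan: CountPlan | None = None, seed: int | None = None):
    """Negative-binomial count table with planted fold changes.

    The first ``n_de`` genes are up-regulated in the first library by
    ``2**log2fc``.  Returns (CountTable, truth) where truth maps DE gene
    names to their planted log2 fold change.
    """
    from .expression import CountTable

    plan = plan or CountPlan()
    if seed is not None:
        plan = replace(plan, seed=seed)
    rng = np.random.default_rng(plan.seed)
    genes = [f"gene{i + 1:03d}" for i in range(plan.n_genes)]
    mu = np.full((plan.n_genes, len(plan.libraries)), plan.baseline_mean)
    truth = {}
    for i in range(plan.n_de):
        mu[i, 0] *= 2.0 ** plan.log2fc
        truth[genes[i]] = plan.log2fc
    if plan.dispersion > 0:
        r = 1.0 / plan.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)
    lengths = rng.integers(*plan.gene_length_range, size=plan.n_genes)
    sizes = np.maximum(counts.sum(axis=0), plan.library_size)
    table = CountTable(
        genes=genes,
        libraries=list(plan.libraries),
        counts=counts,
        gene_lengths=lengths,
        library_sizes=sizes,
    )
    return table, truth


# ---------------------------------------------------------------------------
# contig depths


def generate_contig_depths(
    n_per_class=(30, 40, 30),
    class_depth_means=(2500.0, 200.0, 20.0),
    seed: int = 1,
):
    """Poisson-distributed contig depths around per-class means.

    Returns (records, truth_classes) where records are (id, length, depth)
    tuples ordered chloroplast, mitochondrial, nuclear.
    """
    rng = np.random.default_rng(seed)
    labels = ("chloroplast", "mitochondrial", "nuclear")
    records, truth = [], []
    idx = 0
    for n, mean, label in zip(n_per_class, class_depth_means, labels):
        for _ in range(n):
            idx += 1
            length = int(rng.integers(500, 20000))
            depth = float(rng.poisson(mean))
            records.append((f"contig{idx:04d}", length, depth))
            truth.append(label)
    return records, truth
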