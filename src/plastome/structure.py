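"""Quadripartite plastome structure: IR detection, LSC/SSC/IR partition,
per-region GC and IR-junction gene classification.

A typical angiosperm plastome is a circle LSC -> IRa -> SSC -> IRb where IRb
is the (near-)exact reverse complement of IRa.  The four junctions are named
after the regions they join: ILa/ILb between the IRs and the LSC, ISa/ISb
between the IRs and the SSC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import InvalidStructureError
from .repeats import RepeatParams, find_maximal_repeats
from .seqio import (
    AnnotatedGenome,
    NucSequence,
    gc_fraction,
    interval_contains,
    interval_length,
    interval_within,
)

JUNCTIONS = ("ILa", "ISa", "ISb", "ILb")

CATEGORY_SC = "single-copy-in-SC"
CATEGORY_IR = "duplicated-in-IR"
CATEGORY_SPAN = "junction-spanning"


@dataclass
class IRPair:
    first: tuple[int, int]   # smaller start coordinate
    second: tuple[int, int]
    identity: float


@dataclass
class QuadripartiteMap:
    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    identity: float

    def regions(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}


def detect_inverted_repeats(
    seq: NucSequence, min_len: int = 1000, min_identity: float = 0.99
) -> IRPair | None:
    """Locate the longest disjoint inverted-repeat pair of a circular plastome.

    Seeds on shared k-mers between the sequence and its reverse complement and
    extends without gaps (see :mod:`plastome.repeats` for the hit contract).
    At identity thresholds below 1 a long near-exact pair can absorb a
    mismatch-dense fringe while staying above threshold, so the winning
    candidate is trimmed to its maximum-score core (match +1, mismatch
    -id/(1-id)); interior mismatches stay, boundary overruns are cut.  Ties
    between equally long candidates break on the smaller start coordinate.
    Returns None when nothing passes the thresholds.
    """
    params = RepeatParams(
        min_len=min_len, min_identity=min_identity, require_nonoverlap=True
    )
    hits = find_maximal_repeats(seq, params, klasses=("palindromic",))
    if not hits:
        return None
    best = hits[0]  # already sorted by (-length, pos1)
    pos1, pos2, identity = _trim_to_score_core(seq, best, min_identity)
    if interval_length(pos1, len(seq)) < min_len:
        return None
    return IRPair(first=pos1, second=pos2, identity=identity)


def _trim_to_score_core(seq: NucSequence, hit, min_identity: float):
    """Maximum-score subsegment of a palindromic hit (Kadane on +1/-mu)."""
    from .seqio import reverse_complement

    n = len(seq)
    s1 = seq.region(hit.pos1)
    s2 = reverse_complement(seq.region(hit.pos2))
    if min_identity >= 1.0 or s1 == s2:
        return hit.pos1, hit.pos2, hit.identity
    mu = min_identity / (1.0 - min_identity)
    best_score = cur_score = -1.0
    best = (0, len(s1) - 1)
    cur_start = 0
    for t, (x, y) in enumerate(zip(s1, s2)):
        step = 1.0 if (x == y and x != "N") else -mu
        if cur_score < 0:
            cur_score, cur_start = step, t
        else:
            cur_score += step
        if cur_score > best_score:
            best_score = cur_score
            best = (cur_start, t)
    i, j = best
    length = j - i + 1
    matches = sum(
        1 for x, y in zip(s1[i : j + 1], s2[i : j + 1]) if x == y and x != "N"
    )
    L = len(s1)
    p1s = (hit.pos1[0] + i) % n
    pos1 = (p1s, (p1s + length - 1) % n + 1)
    p2s = (hit.pos2[0] + (L - 1 - j)) % n
    pos2 = (p2s, (p2s + length - 1) % n + 1)
    return pos1, pos2, matches / length


def partition(seq: NucSequence, ir_pair: IRPair) -> QuadripartiteMap:
    """Partition the circle into LSC/IRa/SSC/IRb from a detected IR pair.

    The two single-copy gaps between the IR copies become LSC (the longer)
    and SSC (the shorter); IRa is the IR entered when traversing from the LSC
    start, so the traversal order is LSC -> IRa -> SSC -> IRb.
    """
    n = len(seq)
    p, q = ir_pair.first, ir_pair.second
    occupied = interval_length(p, n) + interval_length(q, n)
    if occupied >= n:
        raise InvalidStructureError("IR copies cover the whole sequence")
    for pos in (p[0], (p[1] - 1) % n):
        if interval_contains(q, pos, n):
            raise InvalidStructureError("IR intervals overlap")
    gap1 = (p[1] % n, q[0])          # between end of first and start of second
    gap2 = (q[1] % n, p[0])          # wraps past the origin back to the first
    len1, len2 = interval_length(gap1, n), interval_length(gap2, n)
    if len1 + len2 + occupied != n:
        raise InvalidStructureError("partition does not cover the genome")
    if len1 > len2:
        lsc, ssc = gap1, gap2
    elif len2 > len1:
        lsc, ssc = gap2, gap1
    else:
        warnings.warn("equal-length single-copy gaps; LSC assigned to smaller start")
        lsc, ssc = sorted([gap1, gap2])
    # IRa is the IR that begins where the LSC ends
    if lsc[1] % n == p[0]:
        ira, irb = p, q
    else:
        ira, irb = q, p
    return QuadripartiteMap(lsc=lsc, ira=ira, ssc=ssc, irb=irb, identity=ir_pair.identity)


def region_gc(genome: AnnotatedGenome, qmap: QuadripartiteMap) -> dict[str, float]:
    """GC fraction per region plus the whole genome.

    The length-weighted mean of the region values equals the whole-genome GC
    (N-free sequences; with Ns the identity holds on the N-excluded counts).
    """
    out = {}
    for name, iv in qmap.regions().items():
        out[name] = gc_fraction(genome.sequence.region(iv))
    out["genome"] = gc_fraction(genome.sequence.bases)
    return out


# ---------------------------------------------------------------------------
# junction reports


@dataclass
class JunctionEntry:
    gene: str
    copy_tag: str | None
    category: str
    distance: int  # bp from the junction point to the nearest edge of the span


@dataclass
class JunctionReport:
    junctions: dict[str, int]                     # junction name -> position
    entries: dict[str, list[JunctionEntry]]
    nearest: dict[str, tuple[str | None, str | None]]
    categories: dict[str, str] = field(default_factory=dict)  # gene -> category


def junction_positions(qmap: QuadripartiteMap, seqlen: int) -> dict[str, int]:
    """Coordinate where the downstream region of each junction begins."""
    return {
        "ILa": qmap.ira[0],   # LSC | IRa
        "ISa": qmap.ssc[0],   # IRa | SSC
        "ISb": qmap.irb[0],   # SSC | IRb
        "ILb": qmap.lsc[0],   # IRb | LSC
    }


def categorize_feature(feature, qmap: QuadripartiteMap, seqlen: int) -> str:
    """duplicated-in-IR / single-copy-in-SC / junction-spanning for one feature."""
    span = feature.span(seqlen)
    for name, iv in qmap.regions().items():
        if interval_within(span, iv, seqlen):
            return CATEGORY_IR if name in ("IRa", "IRb") else CATEGORY_SC
    return CATEGORY_SPAN


def junction_report(
    genome: AnnotatedGenome, qmap: QuadripartiteMap, window: int = 2000
) -> JunctionReport:
    """List features near each junction with their copy category.

    A feature overlapping the +-window around a junction point is reported
    there; its category depends only on containment in the four regions, so a
    feature is junction-spanning iff its span intersects two adjacent regions.
    """
    n = len(genome.sequence)
    positions = junction_positions(qmap, n)
    entries: dict[str, list[JunctionEntry]] = {j: [] for j in positions}
    nearest: dict[str, tuple[str | None, str | None]] = {}
    categories: dict[str, str] = {}
    for f in genome.features:
        categories[f.name] = categorize_feature(f, qmap, n)
    for jname, jpos in positions.items():
        left_best = right_best = None
        dl = dr = n + 1
        for f in genome.features:
            s, e = f.span(n)
            span_len = interval_length((s, e), n)
            # signed distance from junction to span, on the circle
            d_start = (s - jpos) % n          # how far ahead the span starts
            d_end = (jpos - (s + span_len)) % n  # how far behind it ends
            overlaps = interval_contains((s, e), jpos, n) or d_start < window or d_end < window
            if interval_contains((s, e), jpos, n):
                dist = 0
            else:
                dist = min(d_start, d_end)
            if overlaps:
                entries[jname].append(
                    JunctionEntry(
                        gene=f.name,
                        copy_tag=f.copy_tag,
                        category=categories[f.name],
                        distance=dist,
                    )
                )
            if d_end < dl:
                dl, left_best = d_end, f.name
            if d_start < dr:
                dr, right_best = d_start, f.name
        entries[jname].sort(key=lambda x: (x.distance, x.gene))
        nearest[jname] = (left_best, right_best)
    return JunctionReport(
        junctions=positions, entries=entries, nearest=nearest, categories=categories
    )


@dataclass
class GeneFlowEvent:
    gene: str
    from_category: str
    to_category: str


def compare_junctions(report_a: JunctionReport, report_b: JunctionReport):
    """Genes whose copy category changed between two junction reports.

    Antisymmetric: swapping the inputs swaps from/to in every event.
    """
    events = []
    for gene in sorted(set(report_a.categories) & set(report_b.categories)):
        ca, cb = report_a.categories[gene], report_b.categories[gene]
        if ca != cb:
            events.append(GeneFlowEvent(gene=gene, from_category=ca, to_category=cb))
    return events
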