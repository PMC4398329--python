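"""Maximal repeated-pair finder (forward / reverse / palindromic classes).

Repeat classes follow REPuter's vocabulary: the second copy equals the first
(forward), its plain reversal (reverse) or its reverse complement
(palindromic).  Candidates are found by exact shared k-mer seeding between the
sequence and its class transform, then resolved per alignment diagonal.

Hit contract
------------
Comparing S against T = class_transform(S), a *valid segment* on an alignment
diagonal is a contiguous run of paired positions that (i) starts and ends on a
match, (ii) has Hamming identity >= ``min_identity`` (N never matches), and
(iii) is at least ``min_len`` long.  A reported hit is a valid segment that is
not properly contained in another valid segment on the same diagonal.  For
``min_identity = 1`` this reduces to the classical maximal exact repeats.
This match-bounded containment criterion keeps planted repeats recoverable at
their exact coordinates instead of letting hits absorb flanking mismatches.

Circular sequences are scanned on the doubled string; hits are normalised
modulo the length and deduplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    AnnotatedGenome,
    NucSequence,
    interval_contains,
    interval_length,
    interval_within,
    intervals_overlap,
    transform,
)

KLASSES = ("forward", "reverse", "palindromic")
_KLASS_TRANSFORM = {
    "forward": None,
    "reverse": "reverse",
    "palindromic": "reverse_complement",
}

# N encoded so it never matches anything, including another N
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}

# tolerance for the "matches >= min_identity * length" test (float rounding)
IDENTITY_EPS = 1e-9


@dataclass
class RepeatParams:
    min_len: int = 17
    min_identity: float = 0.90
    require_nonoverlap: bool = True
    seed_k: int = 12

    def __post_init__(self):
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if not (0.5 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0.5, 1]")


@dataclass
class RepeatHit:
    klass: str
    length: int
    pos1: tuple[int, int]
    pos2: tuple[int, int]
    identity: float
    seq1: str
    location1: str | None = None
    location2: str | None = None

    def sort_key(self):
        return (KLASSES.index(self.klass), -self.length, self.pos1, self.pos2)


def complete_seed_k(min_len: int, min_identity: float) -> int:
    """Largest seed length that cannot miss any valid segment.

    A valid segment of length L with m mismatches contains an exact run of at
    least ceil((L-m)/(m+1)) matches, and m <= floor(L*(1-identity)).  Seeding
    on exact k-mers with k at or below the minimum of that bound over all
    admissible L therefore guarantees every hit's diagonal is visited.  The
    default ``RepeatParams.seed_k`` trades this guarantee for speed on
    genome-scale input (it still finds every exact repeat >= seed_k and any
    hit containing a seed_k-long exact run).
    """
    if min_identity >= 1.0:
        return min_len
    import math

    horizon = min_len + int(math.ceil(20.0 / (1.0 - min_identity)))
    best = min_len
    for L in range(min_len, horizon + 1):
        m = int(L * (1.0 - min_identity) + IDENTITY_EPS)
        best = min(best, -((L - m) // -(m + 1)))  # ceil division
    return max(best, 1)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(seq), 200, dtype=np.int16)  # N and anything odd -> 200+
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code
    # make every N position unique-ish so N never matches N
    ns = np.nonzero(out == 200)[0]
    out[ns] = 200 + (np.arange(len(ns)) % 1000) * 2 + 1
    return out


def _seed_diagonals(s: str, t: str, k: int, max_occ: int = 200) -> set[int]:
    """Diagonals d = i - j sharing at least one exact k-mer between s and t."""
    index: dict[str, list[int]] = {}
    for j in range(len(t) - k + 1):
        kmer = t[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    diagonals: set[int] = set()
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        occ = index.get(kmer)
        if not occ:
            continue
        if len(occ) > max_occ:
            occ = occ[:max_occ]
        for j in occ:
            diagonals.add(i - j)
    return diagonals


def _maximal_segments(v: np.ndarray, min_len: int, thr: float):
    """Maximal valid segments [a, b] (inclusive) on one diagonal.

    ``v`` is the boolean match vector along the diagonal.  Returns a list of
    (a, b) pairs satisfying the hit contract in the module docstring.
    """
    match_pos = np.nonzero(v)[0]
    if match_pos.size == 0:
        return []
    cum = np.concatenate(([0], np.cumsum(v)))
    # f(t) = cum[t] - thr*t ; segment [a,b] valid iff f(b+1) >= f(a)
    f = cum - thr * np.arange(len(cum))
    g = f[match_pos]                       # f at candidate starts
    pm = np.minimum.accumulate(g)          # non-increasing prefix minima
    fb1 = f[match_pos + 1]                 # f at (end+1) for candidate ends
    # leftmost start index with f(start) <= f(b+1); IDENTITY_EPS guards the
    # matches >= thr*len comparison against float rounding at exact thresholds
    start_idx = np.searchsorted(-pm, -(fb1 + IDENTITY_EPS), side="left")
    starts = match_pos[start_idx]
    lengths = match_pos - starts + 1
    keep = lengths >= min_len
    segs = list(zip(starts[keep].tolist(), match_pos[keep].tolist()))
    # containment filter: scan ends descending, keep strictly-new starts
    segs.sort(key=lambda ab: -ab[1])
    out = []
    best_a = None
    for a, b in segs:
        if best_a is None or a < best_a:
            out.append((a, b))
            best_a = a
    return out


def find_maximal_repeats(
    seq: NucSequence | str,
    params: RepeatParams | None = None,
    klasses=KLASSES,
) -> list[RepeatHit]:
    """Find maximal repeated pairs of the requested classes."""
    params = params or RepeatParams()
    if isinstance(seq, NucSequence):
        bases, circular = seq.bases, seq.circular
    else:
        bases, circular = str(seq).upper(), False
    n = len(bases)
    if n < 2 * params.min_len:
        return []
    scan = bases + bases if circular else bases
    hits: dict[tuple, RepeatHit] = {}
    for klass in klasses:
        tr = _KLASS_TRANSFORM[klass]
        t = scan if tr is None else transform(scan, tr)
        for a, b, d in _diagonal_segments(scan, t, params, klass):
            hit = _segment_to_hit(bases, scan, klass, a, b, d, n, circular, params)
            if hit is not None:
                hits[(hit.klass, hit.pos1, hit.pos2)] = hit
    kept = _drop_contained_images(list(hits.values()), n) if circular else hits.values()
    return sorted(kept, key=RepeatHit.sort_key)


def _circular_diagonal_key(hit: RepeatHit, n: int):
    if hit.klass == "forward":
        return (hit.klass, (hit.pos2[0] - hit.pos1[0]) % n)
    # reverse/palindromic pair mirrored positions: anti-diagonal is constant
    end2 = hit.pos2[1] if hit.pos2[1] > hit.pos2[0] else hit.pos2[1] + n
    return (hit.klass, (hit.pos1[0] + end2 - 1) % n)


def _drop_contained_images(hits: list[RepeatHit], n: int) -> list[RepeatHit]:
    """Remove hits contained in a longer hit on the same circular diagonal.

    Scanning the doubled string sees each circular diagonal through several
    windows, so one long repeat can surface as multiple truncated images.
    """
    groups: dict = {}
    for h in hits:
        groups.setdefault(_circular_diagonal_key(h, n), []).append(h)
    out = []
    for group in groups.values():
        group.sort(key=lambda h: -h.length)
        kept: list[RepeatHit] = []
        for h in group:
            contained = any(
                interval_within(h.pos1, k.pos1, n) and interval_within(h.pos2, k.pos2, n)
                for k in kept
            )
            if not contained:
                kept.append(h)
        out.extend(kept)
    return out


def _diagonal_segments(s: str, t: str, params: RepeatParams, klass: str):
    m = len(s)
    enc_s = _encode(s)
    enc_t = _encode(t)
    for d in sorted(_seed_diagonals(s, t, params.seed_k)):
        if klass == "forward" and d == 0:
            continue  # trivial self-match
        if d >= 0:
            v = enc_s[d:] == enc_t[: m - d]
        else:
            v = enc_s[: m + d] == enc_t[-d:]
        for a, b in _maximal_segments(v, params.min_len, params.min_identity):
            yield a, b, d


def _segment_to_hit(bases, scan, klass, a, b, d, n, circular, params):
    length = b - a + 1
    if length > n:
        warnings.warn("repeat segment longer than the (circular) sequence; skipped")
        return None
    i1 = a + max(d, 0)
    j1 = a + max(-d, 0)
    m = len(scan)
    s_iv = (i1, i1 + length)
    if klass == "forward":
        o_iv = (j1, j1 + length)
    else:  # reverse and palindromic both mirror coordinates
        o_iv = (m - (j1 + length), m - j1)
    pos1, pos2 = sorted([s_iv, o_iv])
    if pos1 == pos2:
        return None  # self-match (e.g. a self-reverse-complement segment)
    if circular:
        if pos1[0] >= n:
            return None  # shifted duplicate of a hit already reported
        pos1 = (pos1[0] % n, (pos1[0] + length - 1) % n + 1)
        pos2 = (pos2[0] % n, (pos2[0] + length - 1) % n + 1)
        pos1, pos2 = sorted([pos1, pos2])
    if params.require_nonoverlap and intervals_overlap(pos1, pos2, n):
        return None
    seq1 = _extract(bases, pos1, n, circular)
    seq2 = _extract(bases, pos2, n, circular)
    ident = _pair_identity(seq1, seq2, klass)
    if ident * length < params.min_identity * length - IDENTITY_EPS:
        return None
    return RepeatHit(
        klass=klass, length=length, pos1=pos1, pos2=pos2, identity=ident, seq1=seq1
    )


def _extract(bases, iv, n, circular):
    s, e = iv
    if e > s:
        return bases[s:e]
    if not circular:
        raise ValueError("wrapping interval on a linear sequence")
    return bases[s:] + bases[:e]


def _pair_identity(seq1: str, seq2: str, klass: str) -> float:
    tr = _KLASS_TRANSFORM[klass]
    other = seq2 if tr is None else transform(seq2, tr)
    matches = sum(
        1 for x, y in zip(seq1, other) if x == y and x != "N"
    )
    return matches / len(seq1)


# ---------------------------------------------------------------------------
# genomic location annotation (Table-3-style)

LOCATION_PRECEDENCE = ("intron", "tRNA", "coding", "IGS")


def locate_position(genome: AnnotatedGenome, pos: int) -> str:
    """Annotation class at one genomic position.

    Returns ``intron:<gene>``, ``tRNA:<gene>``, ``coding:<gene>`` or
    ``IGS:<left>-<right>`` (flanking genes).
    """
    n = len(genome.sequence)
    best = None
    for f in genome.features:
        span = f.span(n)
        if not interval_contains(span, pos, n):
            continue
        in_exon = any(interval_contains(e, pos, n) for e in f.exons)
        if not in_exon:
            cand = ("intron", f.name)
        elif f.kind == "tRNA":
            cand = ("tRNA", f.name)
        elif f.kind == "rRNA":
            cand = ("tRNA", f.name)  # structural RNA; grouped with tRNA tally
        else:
            cand = ("coding", f.name)
        if best is None or LOCATION_PRECEDENCE.index(cand[0]) < LOCATION_PRECEDENCE.index(best[0]):
            best = cand
    if best:
        return f"{best[0]}:{best[1]}"
    left, right = _flanking_genes(genome, pos)
    return f"IGS:{left}-{right}"


def _flanking_genes(genome: AnnotatedGenome, pos: int):
    n = len(genome.sequence)
    left = right = None
    dl = dr = n + 1
    for f in genome.features:
        s, e = f.span(n)
        end = e if e > s else e + n
        d_left = (pos - end) % n
        d_right = (s - pos) % n
        if d_left < dl:
            dl, left = d_left, f.name
        if d_right < dr:
            dr, right = d_right, f.name
    return left or ".", right or "."


def location_kind(location: str) -> str:
    return location.split(":", 1)[0]


def categorize_pair(kind1: str, kind2: str) -> str:
    """Joint category of a repeat from its two copies' location kinds.

    Precedence intron > tRNA > coding > IGS applied to the two copies jointly:
    a repeat counts under the highest-precedence class either copy touches.
    """
    for k in LOCATION_PRECEDENCE:
        if kind1 == k or kind2 == k:
            return k
    raise ValueError(f"unknown location kinds {kind1!r}/{kind2!r}")


@dataclass
class RepeatAnnotation:
    hits: list[RepeatHit]
    tally: dict = field(default_factory=dict)


def annotate_repeat_locations(
    hits: list[RepeatHit], genome: AnnotatedGenome
) -> RepeatAnnotation:
    """Label each copy by midpoint containment and tally joint categories."""
    n = len(genome.sequence)
    tally = {k: 0 for k in LOCATION_PRECEDENCE}
    for h in hits:
        mids = []
        for iv in (h.pos1, h.pos2):
            mid = (iv[0] + interval_length(iv, n) // 2) % n
            mids.append(mid)
        h.location1 = locate_position(genome, mids[0])
        h.location2 = locate_position(genome, mids[1])
        cat = categorize_pair(location_kind(h.location1), location_kind(h.location2))
        tally[cat] += 1
    return RepeatAnnotation(hits=hits, tally=tally)
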