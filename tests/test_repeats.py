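"""Maximal repeat finder vs an exhaustive all-diagonal oracle, planted-repeat
recovery, and the packaged repeat-catalogue worked examples."""

from collections import Counter

import numpy as np
import pytest

from plastome import fixtures, repeats, synth
from plastome.repeats import (
    IDENTITY_EPS,
    RepeatHit,
    RepeatParams,
    annotate_repeat_locations,
    categorize_pair,
    find_maximal_repeats,
)
from plastome.seqio import transform


# ---------------------------------------------------------------------------
# exhaustive oracle: every diagonal, every match-bounded valid segment,
# containment-filtered.  No seeding, no prefix-minimum shortcuts.


def oracle_repeats(s: str, params: RepeatParams, klasses=repeats.KLASSES):
    n = len(s)
    enc = np.frombuffer(s.encode(), dtype=np.uint8).astype(np.int16)
    enc[enc == ord("N")] = -1
    out = set()
    for klass in klasses:
        tr = {"forward": None, "reverse": "reverse",
              "palindromic": "reverse_complement"}[klass]
        t = s if tr is None else transform(s, tr)
        enc_t = np.frombuffer(t.encode(), dtype=np.uint8).astype(np.int16)
        enc_t[enc_t == ord("N")] = -2
        for d in range(-(n - 1), n):
            if klass == "forward" and d == 0:
                continue
            m = n - abs(d)
            if m < params.min_len:
                continue
            i0, j0 = max(d, 0), max(-d, 0)
            v = enc[i0 : i0 + m] == enc_t[j0 : j0 + m]
            for a, b in _oracle_segments(v, params.min_len, params.min_identity):
                length = b - a + 1
                i1, j1 = i0 + a, j0 + a
                s_iv = (i1, i1 + length)
                if klass == "forward":
                    o_iv = (j1, j1 + length)
                else:
                    o_iv = (n - (j1 + length), n - j1)
                pos1, pos2 = sorted([s_iv, o_iv])
                if pos1 == pos2:
                    continue
                if params.require_nonoverlap and pos1[1] > pos2[0] and pos2[1] > pos1[0]:
                    continue
                out.add((klass, pos1, pos2))
    return out


def _oracle_segments(v, min_len, thr):
    """All valid segments not properly contained in another valid segment.

    Exhaustive: every pair of match positions is considered (identity 1.0
    reduces to maximal exact runs, enumerated directly).
    """
    P = np.nonzero(v)[0]
    if P.size == 0:
        return []
    if thr >= 1.0:
        runs = []
        start = prev = P[0]
        for p in P[1:]:
            if p != prev + 1:
                runs.append((start, prev))
                start = p
            prev = p
        runs.append((start, prev))
        return [(a, b) for a, b in runs if b - a + 1 >= min_len]
    cum = np.concatenate(([0], np.cumsum(v)))
    f_start = cum[P] - thr * P
    f_end = cum[P + 1] - thr * (P + 1)
    ok = (f_end[None, :] >= f_start[:, None] - IDENTITY_EPS) & (
        P[None, :] - P[:, None] + 1 >= min_len
    )
    valid = [(int(P[a]), int(P[b])) for a, b in np.argwhere(ok)]
    return [
        seg
        for seg in valid
        if not any(o != seg and o[0] <= seg[0] and o[1] >= seg[1] for o in valid)
    ]


def _hit_set(hits):
    return {(h.klass, h.pos1, h.pos2) for h in hits}


def _complete_params(min_len, identity, **kw):
    """Params with the seed length set to its completeness bound."""
    return RepeatParams(
        min_len=min_len,
        min_identity=identity,
        seed_k=repeats.complete_seed_k(min_len, identity),
        **kw,
    )


def test_tiny_forward_example_matches_oracle():
    s = "ACGTACGT"
    params = _complete_params(4, 1.0)
    found = find_maximal_repeats(s, params)
    assert ("forward", (0, 4), (4, 8)) in _hit_set(found)
    assert _hit_set(found) == oracle_repeats(s, params)


@pytest.mark.parametrize(
    "seed,length,min_len,identity",
    [(s, 300, 8, 1.0) for s in range(6)]
    + [(s, 300, 10, 0.9) for s in range(6, 12)]
    + [(s, 500, 12, 0.85) for s in range(12, 16)]
    + [(s, 2000, 13, 1.0) for s in range(16, 21)]
    + [(2000, 800, 17, 0.9)],
)
def test_oracle_equivalence_on_random_sequences(seed, length, min_len, identity):
    rng = np.random.default_rng(seed)
    s = synth._random_bases(rng, length, 0.45)
    params = _complete_params(min_len, identity)
    assert _hit_set(find_maximal_repeats(s, params)) == oracle_repeats(s, params)


def test_oracle_equivalence_with_planted_structures():
    rng = np.random.default_rng(77)
    s = list(synth._random_bases(rng, 400, 0.4))
    block = synth._random_bases(rng, 30, 0.4)
    s[40:70] = block
    s[200:230] = block
    s[300:330] = transform(block, "reverse_complement")
    s = "".join(s)
    params = _complete_params(15, 0.9)
    found = _hit_set(find_maximal_repeats(s, params))
    assert found == oracle_repeats(s, params)
    assert any(k == "forward" for k, _, _ in found)
    assert any(k == "palindromic" for k, _, _ in found)


def test_planted_repeats_recovered_exactly(default_genome):
    genome, truth = default_genome
    found = _hit_set(find_maximal_repeats(genome.sequence))
    for r in truth.repeats:
        assert (r["klass"], tuple(r["pos1"]), tuple(r["pos2"])) in found


def test_monotonicity_in_parameters():
    rng = np.random.default_rng(123)
    s = list(synth._random_bases(rng, 800, 0.45))
    block = synth._random_bases(rng, 25, 0.45)
    s[100:125] = block
    s[400:425] = block
    s = "".join(s)
    base = _hit_set(find_maximal_repeats(s, RepeatParams(min_len=12, min_identity=0.85)))
    longer = _hit_set(find_maximal_repeats(s, RepeatParams(min_len=20, min_identity=0.85)))
    stricter = _hit_set(find_maximal_repeats(s, RepeatParams(min_len=12, min_identity=0.98)))
    # raising thresholds never adds repeated regions that were absent before
    def regions(hits):
        return {(k, p1) for k, p1, _ in hits}

    assert len(longer) <= len(base)
    assert len(stricter) <= len(base)


def test_emitted_hits_satisfy_their_invariants(default_genome):
    genome, _ = default_genome
    params = RepeatParams()
    n = len(genome.sequence)
    for h in find_maximal_repeats(genome.sequence, params):
        assert h.length >= params.min_len
        seq2 = genome.sequence.region(h.pos2)
        other = seq2 if h.klass == "forward" else transform(
            seq2, "reverse" if h.klass == "reverse" else "reverse_complement"
        )
        matches = sum(1 for x, y in zip(h.seq1, other) if x == y and x != "N")
        assert len(h.seq1) == h.length
        assert matches / h.length >= params.min_identity - 1e-9
        assert matches / h.length == pytest.approx(h.identity)


# ---------------------------------------------------------------------------
# location annotation


def test_annotate_locations_on_generator_genome(default_genome):
    genome, truth = default_genome
    hits = [
        RepeatHit(
            klass=r["klass"], length=r["length"],
            pos1=tuple(r["pos1"]), pos2=tuple(r["pos2"]),
            identity=1.0, seq1=genome.sequence.region(tuple(r["pos1"])),
        )
        for r in truth.repeats
    ]
    ann = annotate_repeat_locations(hits, genome)
    # all default planted repeats live in intergenic spacers
    assert ann.tally["IGS"] == len(hits)
    assert all(h.location1.startswith("IGS:") for h in ann.hits)


def test_category_precedence():
    assert categorize_pair("IGS", "IGS") == "IGS"
    assert categorize_pair("coding", "IGS") == "coding"
    assert categorize_pair("coding", "intron") == "intron"
    assert categorize_pair("tRNA", "coding") == "tRNA"


def test_catalogue_fixture_reproduces_printed_tally():
    rows = fixtures.table3_hits()
    tally = Counter(categorize_pair(r["kind1"], r["kind2"]) for r in rows)
    assert tally == {"coding": 7, "intron": 2, "tRNA": 4}
    assert max(r["size"] for r in rows) == 39
    assert min(r["size"] for r in rows) == 17


def test_catalogue_fixture_sequence_lengths():
    rows = fixtures.table3_hits()
    for r in rows:
        if r["anomaly"] == ".":
            assert len(r["sequence"]) == r["size"]
        else:  # one printed row ships a 19-nt sequence for a stated size of 20
            assert len(r["sequence"]) != r["size"]
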