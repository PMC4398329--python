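"""Quadripartite structure detection, partition, region GC and junctions."""

from dataclasses import replace

import numpy as np
import pytest

from plastome import structure, synth
from plastome.errors import InvalidStructureError
from plastome.seqio import (
    AnnotatedGenome,
    NucSequence,
    interval_length,
    reverse_complement,
)
from plastome.structure import (
    CATEGORY_IR,
    CATEGORY_SC,
    CATEGORY_SPAN,
    IRPair,
    compare_junctions,
    detect_inverted_repeats,
    junction_report,
    partition,
    region_gc,
)
from plastome.synth import PlastomePlan, default_gene_plans


def _random_seq(rng, n, gc=0.38):
    return synth._random_bases(rng, n, gc)


def _constructed_ir_genome(seed, x_len=10_000, y_len=4_000, r_len=2_000):
    """X . R . Y . revcomp(R), with boundary bases forced to break extension."""
    rng = np.random.default_rng(seed)
    x = list(_random_seq(rng, x_len))
    y = list(_random_seq(rng, y_len))
    r = _random_seq(rng, r_len)
    comp = dict(zip("ACGT", "TGCA"))
    # sharpen boundaries: flanking pairs must not complement each other
    for t in range(3):
        if x[-1 - t] == comp[x[t]]:
            x[-1 - t] = next(b for b in "ACGT" if b != comp[x[t]] and b != x[-1 - t])
        if y[t] == comp[y[-1 - t]]:
            y[t] = next(b for b in "ACGT" if b != comp[y[-1 - t]] and b != y[t])
    bases = "".join(x) + r + "".join(y) + reverse_complement(r)
    seq = NucSequence("constructed", bases, circular=True)
    return seq, (x_len, x_len + r_len), (x_len + r_len + y_len, len(bases))


def test_no_ir_in_random_sequence():
    rng = np.random.default_rng(5)
    seq = NucSequence("r", _random_seq(rng, 20_000), circular=True)
    assert detect_inverted_repeats(seq) is None


def test_constructed_ir_found_at_planted_coordinates():
    seq, p, q = _constructed_ir_genome(seed=2)
    ir = detect_inverted_repeats(seq)
    assert ir is not None
    assert (ir.first, ir.second) == (p, q)
    assert ir.identity == 1.0


def test_single_mismatch_ir_still_detected_with_reported_identity():
    seq, p, q = _constructed_ir_genome(seed=3)
    bases = list(seq.bases)
    mid = (p[0] + p[1]) // 2
    bases[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[mid]]
    seq2 = NucSequence("mm", "".join(bases), circular=True)
    ir = detect_inverted_repeats(seq2, min_identity=0.99)
    assert ir is not None
    assert (ir.first, ir.second) == (p, q)
    assert ir.identity == pytest.approx(1 - 1 / (p[1] - p[0]))


def test_partition_assigns_longer_gap_to_lsc():
    seq, p, q = _constructed_ir_genome(seed=4, x_len=10_000, y_len=4_000)
    qmap = partition(seq, detect_inverted_repeats(seq))
    n = len(seq)
    assert interval_length(qmap.lsc, n) == 10_000
    assert interval_length(qmap.ssc, n) == 4_000
    assert interval_length(qmap.ira, n) == interval_length(qmap.irb, n) == 2_000
    total = sum(interval_length(iv, n) for iv in qmap.regions().values())
    assert total == n


def test_partition_equal_gaps_warns_and_uses_smaller_start():
    seq, p, q = _constructed_ir_genome(seed=5, x_len=4_000, y_len=4_000)
    with pytest.warns(UserWarning, match="equal-length"):
        qmap = partition(seq, detect_inverted_repeats(seq))
    assert qmap.lsc[0] <= qmap.ssc[0]


def test_partition_rejects_overlapping_irs():
    seq, _, _ = _constructed_ir_genome(seed=6)
    with pytest.raises(InvalidStructureError):
        partition(seq, IRPair(first=(100, 3000), second=(2000, 6000), identity=1.0))


def test_region_gc_trivial_and_weighted_mean(default_genome):
    # all-G IRs, all-A single-copy regions
    bases = "A" * 1000 + "G" * 500 + "A" * 400 + "G" * 500
    genome = AnnotatedGenome(sequence=NucSequence("t", bases, circular=True))
    qmap = structure.QuadripartiteMap(
        lsc=(0, 1000), ira=(1000, 1500), ssc=(1500, 1900), irb=(1900, 2400),
        identity=1.0,
    )
    gc = region_gc(genome, qmap)
    assert gc["IRa"] == gc["IRb"] == 1.0
    assert gc["LSC"] == gc["SSC"] == 0.0
    # weighted-mean identity on the generator genome
    g, _ = default_genome
    qmap = partition(g.sequence, detect_inverted_repeats(g.sequence))
    gc = region_gc(g, qmap)
    n = len(g.sequence)
    weighted = sum(
        gc[r] * interval_length(iv, n) for r, iv in qmap.regions().items()
    ) / n
    assert weighted == pytest.approx(gc["genome"], abs=1e-9)


def test_generator_region_gc_near_targets(default_genome):
    g, _ = default_genome
    qmap = partition(g.sequence, detect_inverted_repeats(g.sequence))
    gc = region_gc(g, qmap)
    assert abs(gc["LSC"] - 0.36) < 0.02
    assert abs(gc["SSC"] - 0.34) < 0.02
    assert abs(gc["IRa"] - 0.41) < 0.02
    assert gc["IRa"] == pytest.approx(gc["IRb"], abs=1e-9)


def _norm(iv, n):
    return (iv[0] % n, (iv[1] - 1) % n + 1)


@pytest.mark.parametrize("mismatches", [0, 1, 2])
def test_planted_structure_recovery_sweep(mismatches):
    """Boundary recovery on seeded synthetic plastomes, IR 2-8 kb."""
    seeds = range(1, 18) if mismatches == 0 else range(1, 9)
    for seed in seeds:
        rng = np.random.default_rng(seed + 1000 * mismatches)
        plan = PlastomePlan(
            lsc_len=int(rng.integers(9_000, 16_000)),
            ir_len=int(rng.integers(2_000, 8_000)),
            ssc_len=int(rng.integers(3_000, 5_000)),
            genes=[],
            repeats=[],
            edits=[],
            ir_mismatches=mismatches,
            seed=seed,
        )
        genome, truth = synth.generate_plastome(plan)
        n = len(genome.sequence)
        ir = detect_inverted_repeats(genome.sequence)
        assert ir is not None, (seed, mismatches)
        qmap = partition(genome.sequence, ir)
        tol = mismatches  # +-1 bp per planted mismatch
        for name, iv in qmap.regions().items():
            want = _norm(tuple(truth.regions[name]), n)
            got = _norm(iv, n)
            assert abs(got[0] - want[0]) <= tol and abs(got[1] - want[1]) <= tol, (
                seed, mismatches, name, got, want,
            )


# ---------------------------------------------------------------------------
# junctions


@pytest.fixture(scope="module")
def genome_pair():
    """Genome A: ndhA wholly in SSC.  Genome B: ndhA crosses ISa into the IR."""
    g_a, _ = synth.generate_plastome(seed=7)
    genes_b = []
    for gp in default_gene_plans():
        if gp.name == "ndhA":
            gp = replace(gp, offset=-1000)
        if gp.name == "ndhF":
            gp = replace(gp, offset=800)
        genes_b.append(gp)
    g_b, _ = synth.generate_plastome(PlastomePlan(seed=7, genes=genes_b))
    reports = []
    for g in (g_a, g_b):
        qmap = partition(g.sequence, detect_inverted_repeats(g.sequence))
        reports.append(junction_report(g, qmap))
    return reports


def test_feature_categories(default_genome):
    g, _ = default_genome
    qmap = partition(g.sequence, detect_inverted_repeats(g.sequence))
    rep = junction_report(g, qmap)
    assert rep.categories["ndhB"] == CATEGORY_IR      # wholly inside the IRs
    assert rep.categories["ndhA"] == CATEGORY_SC      # wholly inside the SSC
    assert rep.categories["psbA"] == CATEGORY_SC
    # genes near ISa show up in its window with their categories
    isa_genes = {e.gene for e in rep.entries["ISa"]}
    assert "ndhF" in isa_genes


def test_junction_spanning_category(genome_pair):
    rep_a, rep_b = genome_pair
    assert rep_a.categories["ndhA"] == CATEGORY_SC
    assert rep_b.categories["ndhA"] == CATEGORY_SPAN


def test_compare_junctions_reports_gene_flow(genome_pair):
    rep_a, rep_b = genome_pair
    events = compare_junctions(rep_a, rep_b)
    assert len(events) == 1
    (ev,) = events
    assert (ev.gene, ev.from_category, ev.to_category) == (
        "ndhA", CATEGORY_SC, CATEGORY_SPAN,
    )


def test_compare_junctions_identity_and_antisymmetry(genome_pair):
    rep_a, rep_b = genome_pair
    assert compare_junctions(rep_a, rep_a) == []
    forward = compare_junctions(rep_a, rep_b)
    backward = compare_junctions(rep_b, rep_a)
    assert [(e.gene, e.to_category, e.from_category) for e in forward] == [
        (e.gene, e.from_category, e.to_category) for e in backward
    ]


def test_rps19_style_ir_to_lsc_flow():
    """A gene duplicated in the IR in one genome, single-copy in LSC in another."""
    g_a, _ = synth.generate_plastome(seed=9)  # rps19 in LSC
    genes_b = [gp for gp in default_gene_plans() if gp.name != "rps19"]
    genes_b.append(
        synth.GenePlan("rps19", "CDS", "IRa", 5400, "+", [279])
    )
    g_b, _ = synth.generate_plastome(PlastomePlan(seed=9, genes=genes_b))
    reports = []
    for g in (g_a, g_b):
        qmap = partition(g.sequence, detect_inverted_repeats(g.sequence))
        reports.append(junction_report(g, qmap))
    events = compare_junctions(reports[1], reports[0])
    flows = {(e.gene, e.from_category, e.to_category) for e in events}
    assert ("rps19", CATEGORY_IR, CATEGORY_SC) in flows
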