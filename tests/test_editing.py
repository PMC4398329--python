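"""RNA-editing classification, labels, alignment and site calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastome import editing, fixtures, synth
from plastome.editing import (
    EditingSite,
    align_transcript,
    call_editing_for_genome,
    call_editing_sites,
    classify_site,
    format_label,
    parse_label,
    summarize_editing,
)
from plastome.errors import NoAlignmentError


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "codon,pos,base,after,aa1,aa2,syn",
    [
        ("UCA", 2, "U", "UUA", "S", "L", False),
        ("GCC", 3, "U", "GCU", "A", "A", True),
        ("UUU", 1, "C", "CUU", "F", "L", False),
        ("AUG", 2, "C", "ACG", "M", "T", False),
    ],
)
def test_classify_site_examples(codon, pos, base, after, aa1, aa2, syn):
    info = classify_site(codon, pos, base)
    assert info["codon_after"] == after
    assert (info["aa_before"], info["aa_after"]) == (aa1, aa2)
    assert info["synonymous"] is syn


def test_classify_site_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_site("UX A", 1, "U")
    with pytest.raises(ValueError):
        classify_site("UCA", 4, "U")


# ---------------------------------------------------------------------------
# labels


def test_format_label_examples():
    site = EditingSite(gene="rps16", genome_pos=5007, gene_pos=976, region="exon",
                       dna_base="C", rna_base="U", aa_before="L", aa_after="L")
    assert format_label(site) == "rps16eU976LL"
    site = EditingSite(gene="atpA", genome_pos=11006, gene_pos=914, region="exon",
                       dna_base="C", rna_base="U", aa_before="S", aa_after="L")
    assert format_label(site) == "atpAeU914SL"


def test_parse_label_rejects_garbage():
    with pytest.raises(ValueError):
        parse_label("notalabel!")
    with pytest.raises(ValueError):
        parse_label("rps16x976LL")


gene_names = st.sampled_from(
    ["rps16", "atpA", "psbA", "ndhB", "ycf2", "petB", "cemA", "rpl33", "orf42",
     "rpoC1", "trnK-UUU", "clpP", "matK", "rps12", "psbE"]
)


@given(
    gene_names,
    st.sampled_from(["exon", "intron"]),
    st.sampled_from("ACGU"),
    st.integers(min_value=1, max_value=99999),
    st.sampled_from("ACDEFGHIKLMNPQRSTVWY*"),
    st.sampled_from("ACDEFGHIKLMNPQRSTVWY*"),
)
def test_label_round_trip(gene, region, base, pos, aa1, aa2):
    site = EditingSite(gene=gene, genome_pos=1, gene_pos=pos, region=region,
                       dna_base="C", rna_base=base, aa_before=aa1, aa_after=aa2)
    back = parse_label(format_label(site))
    assert (back.gene, back.region, back.rna_base, back.gene_pos,
            back.aa_before, back.aa_after) == (gene, region, base, pos, aa1, aa2)


def test_label_round_trip_many_random_sites():
    rng = np.random.default_rng(42)
    genes = ["rps16", "atpA", "ndhB", "ycf2", "petB", "rpoC1", "psbK"]
    aas = "ACDEFGHIKLMNPQRSTVWY*"
    for _ in range(200):
        site = EditingSite(
            gene=genes[rng.integers(len(genes))],
            genome_pos=1,
            gene_pos=int(rng.integers(1, 5000)),
            region="exon" if rng.integers(2) else "intron",
            dna_base="C",
            rna_base="ACGU"[rng.integers(4)],
            aa_before=aas[rng.integers(len(aas))],
            aa_after=aas[rng.integers(len(aas))],
        )
        back = parse_label(format_label(site))
        assert format_label(back) == format_label(site)


# ---------------------------------------------------------------------------
# alignment


def test_align_identical_sequences_no_mismatch():
    s = "ATG" + "ACGT" * 30 + "TAA"
    assert align_transcript(s, s) == ([], (0, len(s)))


def test_align_single_planted_change():
    rng = np.random.default_rng(3)
    s = synth._random_bases(rng, 1200, 0.4)
    t = list(s)
    t[913] = "T" if s[913] != "T" else "C"  # 1-based position 914
    mismatches, _ = align_transcript(s, "".join(t))
    assert mismatches == [(913, s[913], t[913])]


def test_align_rejects_divergent_pair():
    rng = np.random.default_rng(4)
    a = synth._random_bases(rng, 500, 0.5)
    b = synth._random_bases(rng, 500, 0.5)
    with pytest.raises(NoAlignmentError):
        align_transcript(a, b)


def test_align_handles_offset_transcript():
    rng = np.random.default_rng(5)
    s = synth._random_bases(rng, 900, 0.4)
    mismatches, (lo, hi) = align_transcript(s, s[100:800])
    assert mismatches == [] and (lo, hi) == (100, 800)


# ---------------------------------------------------------------------------
# calling on generated data


def test_clean_recovery_exact(default_genome, default_transcripts):
    genome, _ = default_genome
    by_gene, planted = default_transcripts
    called = call_editing_for_genome(genome, by_gene)
    truth = {(e.gene, e.genome_pos, e.dna_base, e.rna_base) for e in planted}
    got = {(s.gene, s.genome_pos, s.dna_base, s.rna_base) for s in called}
    assert got == truth  # precision = recall = 1
    by_change = summarize_editing(called).by_change
    assert by_change == {"C->U": 6, "U->C": 3, "G->A": 1}
    assert summarize_editing(called).intron == 1


def test_recovery_across_seeds():
    for seed in range(2, 12):
        genome, truth = synth.generate_plastome(seed=seed)
        by_gene, planted = synth.generate_transcripts(genome, truth)
        called = call_editing_for_genome(genome, by_gene)
        want = {(e.gene, e.genome_pos) for e in planted}
        got = {(s.gene, s.genome_pos) for s in called}
        assert got == want, seed


def test_minus_strand_genomic_coordinates(default_genome, default_transcripts):
    genome, _ = default_genome
    by_gene, planted = default_transcripts
    called = call_editing_for_genome(genome, by_gene)
    matk = [s for s in called if s.gene == "matK"]  # minus-strand gene
    assert len(matk) == 2
    planted_matk = sorted(e.genome_pos for e in planted if e.gene == "matK")
    assert sorted(s.genome_pos for s in matk) == planted_matk
    for s in matk:
        # the genomic base is the complement of the edited (gene-strand) base
        genomic = genome.sequence.bases[s.genome_pos - 1]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert comp[genomic] == s.dna_base.replace("U", "T")


def test_subthreshold_fraction_not_called(default_genome):
    genome, truth = default_genome
    by_gene, _ = synth.generate_transcripts(genome, truth, coverage=5,
                                            edit_fraction=0.2)
    called = call_editing_for_genome(genome, by_gene)  # 1/5 < min_fraction 0.5
    assert called == []


def test_tie_at_min_fraction_calls_the_site(default_genome):
    genome, truth = default_genome
    by_gene, planted = synth.generate_transcripts(genome, truth, coverage=4,
                                                  edit_fraction=0.5)
    called = call_editing_for_genome(genome, by_gene)  # 2/4 == min_fraction
    assert {(s.gene, s.genome_pos) for s in called} == {
        (e.gene, e.genome_pos) for e in planted
    }


def test_gene_without_transcripts_warns(default_genome):
    genome, _ = default_genome
    gene = genome.get("psbA")
    with pytest.warns(UserWarning, match="no transcripts"):
        assert call_editing_sites(genome, gene, []) == []


# ---------------------------------------------------------------------------
# summaries


def test_summary_counts_are_consistent(default_genome, default_transcripts):
    genome, _ = default_genome
    by_gene, _ = default_transcripts
    called = call_editing_for_genome(genome, by_gene)
    s = summarize_editing(called)
    assert sum(s.by_change.values()) == s.total
    assert s.exon + s.intron == s.total
    assert sum(s.per_gene.values()) == s.total
    for site in called:
        if site.region == "exon":
            info = classify_site(site.codon_before, site.codon_pos, site.rna_base)
            assert info["synonymous"] == site.synonymous


def test_empty_summary_is_all_zero():
    s = summarize_editing([])
    assert (s.total, s.exon, s.intron, s.max_per_gene) == (0, 0, 0, 0)
    assert s.by_change == {} and s.per_gene == {}


def test_catalogue_fixture_summary_paper_compat():
    sites = fixtures.table4_sites()
    s = summarize_editing(sites, paper_compat=True)
    assert s.total == 43
    assert s.by_change == {"C->U": 36, "U->C": 5, "G->A": 2}
    assert s.intron == 3
    assert s.non_synonymous == 31
    assert s.max_per_gene == 5
    assert set(s.gene_ranking[:2]) == {"ycf2", "rps3"}
    # codon-position bias: second position most edited, then third, then first
    assert s.by_codon_pos[2] > s.by_codon_pos[3] > s.by_codon_pos[1]


def test_catalogue_fixture_summary_default_mode():
    sites = fixtures.table4_sites()
    s = summarize_editing(sites, paper_compat=False)
    # intronic pseudo-codons excluded: 40 exonic sites split 30/10
    assert s.non_synonymous == 30 and s.synonymous == 10
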