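"""SNP effect classification, pool SNP sets, χ² enrichment, summary report."""

import itertools

import numpy as np
import pytest

from domestiscan.annotation_report import (classify_snp_effects,
                                           effects_to_frame, enrichment_chi2,
                                           enrichment_table, pool_snp_sets,
                                           round_half_up, summary_report)
from domestiscan.io_model import GeneModel, GenotypeMatrix, PopulationMap

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def _matrix_at(positions, refs, alts, chrom="chr1"):
    n = len(positions)
    return GenotypeMatrix(
        np.array([chrom] * n, dtype=object), np.array(positions),
        np.array(refs, dtype=object), np.array(alts, dtype=object),
        np.zeros((n, 2), dtype=np.int8), ["a", "b"])


def _reference(seq, chrom="chr1"):
    return {chrom: seq}


def test_codon_third_position_synonymous_and_nonsynonymous():
    """CTG->CTA stays Leu (synonymous); ATG->ATA is Met->Ile (nonsynonymous)."""
    #          pos: 123456789...
    seq = "NNNNCTGATGTAANNNN"         # CDS 5..13: CTG ATG TAA
    gene = GeneModel("g1", "g1.t1", "chr1", "+", cds=[(5, 13)])
    m = _matrix_at([7, 10], ["G", "G"], ["A", "A"])
    effects = classify_snp_effects(m, [gene], _reference(seq))
    assert [e.coding_effect for e in effects] == ["synonymous", "nonsynonymous"]
    assert all(e.category == "CDS" for e in effects)


def test_minus_strand_effect_uses_reverse_complement():
    """A minus-strand gene reads the complement: genomic CAT at 5..7 is coding
    ATG; genomic C->T at pos 7 turns coding ATG->ATA (Met->Ile)."""
    seq = "NNNNCATNNNN"
    gene = GeneModel("g1", "g1.t1", "chr1", "-", cds=[(5, 7)])
    m = _matrix_at([5], ["C"], ["T"])
    (e,) = classify_snp_effects(m, [gene], _reference(seq))
    assert e.coding_effect == "nonsynonymous"


def test_strand_mirror_consistency():
    """A gene mirrored to the opposite strand with reverse-complemented
    sequence yields identical effect calls."""
    rng = np.random.default_rng(9)
    cds_plus = "ATGGCTTTCGGATGCCTATAA"           # 21 bp ORF
    pad = "".join(rng.choice(list("ACGT"), 10))
    seq_plus = pad + cds_plus + pad
    comp = str.maketrans("ACGT", "TGCA")
    seq_minus = seq_plus.translate(comp)[::-1]
    L = len(seq_plus)
    g_plus = GeneModel("g", "g.t", "chr1", "+", cds=[(11, 31)])
    g_minus = GeneModel("g", "g.t", "chr1", "-",
                        cds=[(L - 31 + 1, L - 11 + 1)])
    for pos_plus in range(11, 32):
        ref_p = seq_plus[pos_plus - 1]
        for alt_p in "ACGT":
            if alt_p == ref_p:
                continue
            m_p = _matrix_at([pos_plus], [ref_p], [alt_p])
            (e_p,) = classify_snp_effects(m_p, [g_plus], _reference(seq_plus))
            pos_m = L - pos_plus + 1
            ref_m = ref_p.translate(comp)
            alt_m = alt_p.translate(comp)
            m_m = _matrix_at([pos_m], [ref_m], [alt_m])
            (e_m,) = classify_snp_effects(m_m, [g_minus], _reference(seq_minus))
            assert e_p.coding_effect == e_m.coding_effect, (pos_plus, alt_p)


def test_effects_from_fasta_file_reference(tmp_path):
    """classify_snp_effects works off an indexed FASTA on disk."""
    from domestiscan.annotation_report import open_reference
    from domestiscan.synthetic_data import write_fasta

    seq = "NNNNCTGATGTAANNNN"
    write_fasta({"chr1": seq}, tmp_path / "ref.fa")
    gene = GeneModel("g1", "g1.t1", "chr1", "+", cds=[(5, 13)])
    m = _matrix_at([7, 10], ["G", "G"], ["A", "A"])
    ref = open_reference(tmp_path / "ref.fa")
    effects = classify_snp_effects(m, [gene], ref)
    assert [e.coding_effect for e in effects] == ["synonymous", "nonsynonymous"]


def test_feature_precedence_and_intergenic():
    seq = "A" * 100
    gene = GeneModel("g1", "g1.t1", "chr1", "+",
                     cds=[(21, 35), (51, 65)], utr=[(11, 20)])
    # intron = 36..50; SNP 10 bp upstream of the gene span -> intergenic
    m = _matrix_at([25, 15, 40, 2], ["A"] * 4, ["G"] * 4)
    effects = classify_snp_effects(m, [gene], _reference(seq))
    assert [e.category for e in effects] == ["CDS", "UTR", "intron", "intergenic"]


def test_flagged_gene_feature_only_and_ref_mismatch_skip():
    seq = "A" * 30
    flagged = GeneModel("g1", "g1.t1", "chr1", "+", cds=[(5, 8)])  # length 4
    assert flagged.flagged
    m = _matrix_at([6, 20], ["A", "C"], ["G", "G"])  # site 2 ref mismatch
    effects = classify_snp_effects(m, [flagged], _reference(seq))
    assert len(effects) == 1
    assert effects[0].category == "CDS"
    assert effects[0].coding_effect == "not_applicable"
    df = effects_to_frame(effects)
    assert list(df.columns) == ["site_index", "category", "coding_effect", "gene_id"]


# ---------------------------------------------------------------------------
# Pool SNP sets
# ---------------------------------------------------------------------------

def test_pool_snp_sets_directed_fixed_sets(three_pool_matrix):
    m, pm = three_pool_matrix
    sets = pool_snp_sets(m, pm, min_calls=2)
    # site 0: wild {0,1} polymorphic, landrace {0,0} mono -> lost in domestication
    assert sets.lost_domestication[0]
    # site 2: landrace polymorphic, elite mono -> lost in improvement
    assert sets.lost_improvement[2]
    # site 4 monomorphic everywhere: in no fixed set
    assert not sets.lost_domestication[4] and not sets.lost_improvement[4]
    # site 5 has a missing elite call: elite not classifiable at min_calls=2
    assert not sets.classifiable["elite"][5]


def test_pool_snp_sets_venn_matches_enumeration(three_pool_matrix):
    m, pm = three_pool_matrix
    sets = pool_snp_sets(m, pm, min_calls=2)
    venn = sets.venn_counts()
    # brute force over classifiable sites
    expected = {k: 0 for k in venn}
    keys = [("wild_only", (1, 0, 0)), ("landrace_only", (0, 1, 0)),
            ("elite_only", (0, 0, 1)), ("wild_landrace", (1, 1, 0)),
            ("wild_elite", (1, 0, 1)), ("landrace_elite", (0, 1, 1)),
            ("all_three", (1, 1, 1))]
    for i in range(m.n_sites):
        status = []
        ok = True
        for pool in ("wild", "landrace", "elite"):
            idx = pm.indices(m, pool)
            vals = [c for c in m.calls[i, idx] if c >= 0]
            if len(vals) < 2:
                ok = False
            alleles = set()
            for v in vals:
                alleles |= {0, 1} if v == 1 else {v // 2}
            status.append(1 if len({a for v in vals for a in
                                    ([0, 1] if v == 1 else [v // 2])}) > 1 else 0)
        if not ok:
            continue
        for name, pat in keys:
            if tuple(status) == pat:
                expected[name] += 1
    assert venn == expected
    # inclusion-exclusion: the seven classes partition the classifiable
    # polymorphic-anywhere sites
    total_poly = sum(venn.values())
    base = sets.all_classifiable
    any_poly = (sets.polymorphic["wild"] | sets.polymorphic["landrace"]
                | sets.polymorphic["elite"]) & base
    assert total_poly == int(any_poly.sum())


def test_identical_pools_share_everything():
    calls = [[0, 1, 0, 1, 0, 1], [2, 0, 2, 0, 2, 0], [0, 0, 0, 0, 0, 0]]
    m = make_matrix(calls)
    pm = PopulationMap({"S0": "wild", "S1": "wild", "S2": "landrace",
                        "S3": "landrace", "S4": "elite", "S5": "elite"})
    sets = pool_snp_sets(m, pm)
    venn = sets.venn_counts()
    assert venn["all_three"] == 2
    assert sum(v for k, v in venn.items() if k != "all_three") == 0
    assert not sets.lost_domestication.any() and not sets.lost_improvement.any()


# ---------------------------------------------------------------------------
# Enrichment χ²
# ---------------------------------------------------------------------------

def test_chi2_hand_arithmetic():
    """Table 10/90/190/9810: χ² = N(ad-bc)²/(row·col products) = 33.468."""
    chi2, p = enrichment_chi2(10, 90, 190, 9810)
    assert chi2 == pytest.approx(33.468, abs=5e-3)
    assert p < 1e-6


def test_chi2_proportional_table_is_zero():
    chi2, p = enrichment_chi2(10, 90, 100, 900)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_row_swap_symmetry_and_zero_margin():
    a = enrichment_chi2(10, 90, 190, 9810)
    b = enrichment_chi2(190, 9810, 10, 90)
    assert a[0] == pytest.approx(b[0], rel=1e-12)
    with pytest.raises(ValueError):
        enrichment_chi2(0, 0, 5, 5)
    table = enrichment_table({"ok": (10, 90, 190, 9810), "bad": (0, 0, 5, 5)})
    assert list(table.category) == ["ok"]


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

def test_summary_report_headline_formulas():
    """The printed ratios as pure functions of their inputs."""
    rep = summary_report(
        total_snps=5_102_244, novel_snps=1_299_265,
        fixed_domestication=1_661_945, fixed_improvement=899_865,
        fixed_domestication_cds=94_793, fixed_domestication_nonsyn=66_637,
        improvement_region_bp=14_462_000, domestication_region_bp=13_965_000,
        domestication_genes=928, improvement_genes=1_106,
        annotated_genes=46_430, genome_size=950e6,
    )
    assert rep["novel_snp_pct"] == 25.5
    assert rep["improvement_vs_domestication_fixed_pct"] == 54
    assert rep["fixed_domestication_cds_pct"] == 5.7
    assert rep["fixed_domestication_nonsyn_pct"] == 4.0
    assert rep["improvement_genome_pct"] == 1.52
    assert rep["domestication_gene_pct"] == 2.0
    assert rep["selected_gene_pct"] == 4.38


def test_summary_report_missing_inputs_flagged():
    rep = summary_report(total_snps=100)
    assert rep["novel_snp_pct"] == "unavailable"
    assert rep["selected_gene_pct"] == "unavailable"


def test_round_half_up_matches_printed_convention():
    assert round_half_up(2.345, 2) == 2.35
    assert round_half_up(54.145, 0) == 54
    assert round_half_up(1.515, 2) == 1.52
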