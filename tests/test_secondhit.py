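"""Second-hit evidence layers and verdict integration."""

import numpy as np
import pandas as pd
import pytest

from twohit.config import ThresholdConfig
from twohit.models import (
    CnSegment,
    Consequence,
    EvidenceKind,
    Expectation,
    ExpressionMatrix,
    GeneInterval,
    MethylationTable,
    SomaticEvidence,
    SomaticVariant,
    VariantKey,
)
from twohit.somatic import (
    ExpressionNoData,
    assess_cn_loh,
    chromothripsis_like,
    compute_tmb,
    expression_aberrant,
    find_snv_hit,
    find_sv_hit,
    integrate_verdict,
    methylation_hit,
    nearest_rank_percentile,
    pathway_expansion,
)

CONFIG = ThresholdConfig()
GENE = GeneInterval("RB1", "chr13", 48_000_000, 48_200_000)


def make_somatic(gene="SDHA", vaf=0.4, depth=100, consequence=Consequence.MISSENSE,
                 population_af=None, pos=100, chrom="chr5", is_structural=False,
                 svtype=None, end=None):
    return SomaticVariant(
        case_id="t1",
        key=VariantKey(chrom, pos, "G", "A" if not is_structural else "<DEL>"),
        gene=gene,
        consequence=consequence,
        vaf=vaf,
        depth=depth,
        population_af=population_af,
        is_structural=is_structural,
        svtype=svtype,
        end=end,
    )


# ---------------------------------------------------------------------------
# SNV / SV hits
# ---------------------------------------------------------------------------

def test_qualifying_somatic_snv_detected():
    # a germline SDHA carrier with a somatic missense at VAF 0.4
    (ev,) = find_snv_hit([make_somatic()], "SDHA", CONFIG)
    assert ev.kind is EvidenceKind.SNV_OR_INDEL
    assert ev.vaf == pytest.approx(0.4)


def test_vaf_threshold_strict_at_five_percent():
    at = make_somatic(vaf=0.05)
    above = make_somatic(vaf=0.050001)
    assert find_snv_hit([at], "SDHA", CONFIG) == []
    assert len(find_snv_hit([above], "SDHA", CONFIG)) == 1


def test_no_somatic_variants_in_gene_gives_empty_list():
    assert find_snv_hit([make_somatic(gene="TP53")], "SDHA", CONFIG) == []


def test_synonymous_somatic_variant_not_a_hit():
    v = make_somatic(consequence=Consequence.SYNONYMOUS)
    assert find_snv_hit([v], "SDHA", CONFIG) == []


def test_snv_hits_sorted_by_vaf_descending():
    hits = find_snv_hit(
        [make_somatic(vaf=0.1, pos=1), make_somatic(vaf=0.5, pos=2)],
        "SDHA", CONFIG,
    )
    assert [h.vaf for h in hits] == [0.5, 0.1]


def test_sv_threshold_strict_at_ten_percent():
    sv = make_somatic(chrom="chr13", pos=48_050_000, is_structural=True,
                      svtype="DEL", end=48_100_000, vaf=0.10)
    assert find_sv_hit([sv], GENE, CONFIG) == []
    sv2 = make_somatic(chrom="chr13", pos=48_050_000, is_structural=True,
                       svtype="DEL", end=48_100_000, vaf=0.11)
    (ev,) = find_sv_hit([sv2], GENE, CONFIG)
    assert ev.kind is EvidenceKind.STRUCTURAL_VARIANT


# ---------------------------------------------------------------------------
# Copy number / LOH
# ---------------------------------------------------------------------------

def test_focal_deletion_with_alternative_allele_retained():
    seg = CnSegment("chr13", 47_000_000, 49_000_000, 1.0, True)
    call = assess_cn_loh([seg], GENE, CONFIG, ploidy=2.0,
                         germline_tumor_vaf=0.85)
    assert call.evidence.kind is EvidenceKind.FOCAL_DELETION
    assert call.evidence.retained_allele == "alternative"


def test_copy_neutral_without_imbalance_is_no_evidence():
    seg = CnSegment("chr13", 47_000_000, 49_000_000, 2.0, False)
    call = assess_cn_loh([seg], GENE, CONFIG, ploidy=2.0)
    assert call.evidence is None and call.copy_neutral and not call.no_data


def test_copy_neutral_imbalance_is_loh():
    seg = CnSegment("chr13", 47_000_000, 49_000_000, 2.0, True)
    call = assess_cn_loh([seg], GENE, CONFIG, ploidy=2.0)
    assert call.evidence.kind is EvidenceKind.LOH


def test_forty_megabase_deletion_is_uninformative():
    seg = CnSegment("chr13", 20_000_000, 60_000_000, 1.0, True)
    call = assess_cn_loh([seg], GENE, CONFIG, ploidy=2.0)
    assert call.evidence.kind is EvidenceKind.UNINFORMATIVE_LARGE_DELETION


def test_deletion_relative_to_elevated_ploidy():
    # with tumor ploidy ~3.6, an absolute copy number of 2 still counts as loss
    seg = CnSegment("chr13", 47_000_000, 49_000_000, 2.0, True)
    call = assess_cn_loh([seg], GENE, CONFIG, ploidy=3.6)
    assert call.evidence.kind is EvidenceKind.FOCAL_DELETION


def test_uncovered_gene_is_no_data_not_none():
    seg = CnSegment("chr1", 0, 1_000_000, 1.0, True)
    call = assess_cn_loh([seg], GENE, CONFIG)
    assert call.no_data and call.evidence is None


def test_chromothripsis_switch_counting():
    def alternating(n):
        return [
            CnSegment("chr13", i * 1000, (i + 1) * 1000, 1.0 + (i % 2), False)
            for i in range(n)
        ]

    assert not chromothripsis_like(alternating(1), CONFIG)   # no switches
    assert chromothripsis_like(alternating(15), CONFIG)      # 14 switches
    assert not chromothripsis_like(alternating(10), CONFIG)  # 9 < threshold 10
    assert chromothripsis_like(alternating(11), CONFIG)      # exactly 10


def test_chromothripsis_chromosome_makes_gene_uninformative():
    segs = [
        CnSegment("chr13", 47_000_000 + i * 200_000,
                  47_000_000 + (i + 1) * 200_000, 1.0 + (i % 2), i % 2 == 0)
        for i in range(15)
    ]
    call = assess_cn_loh(segs, GENE, CONFIG)
    assert call.evidence.kind is EvidenceKind.UNINFORMATIVE_CHROMOTHRIPSIS


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _matrix(values, gene="RB1"):
    return ExpressionMatrix(
        pd.DataFrame([values], index=[gene],
                     columns=[f"s{i}" for i in range(len(values))])
    )


def test_cohort_minimum_is_always_low():
    values = list(np.linspace(5, 50, 99)) + [0.5]
    ev = expression_aberrant(_matrix(values), "RB1", "s99", CONFIG)
    assert ev.kind is EvidenceKind.EXPRESSION_LOW


def test_median_of_large_cohort_is_unremarkable():
    values = np.arange(312, dtype=float) + 1
    m = _matrix(list(values))
    assert expression_aberrant(m, "RB1", "s155", CONFIG) is None


def test_fifth_lowest_of_hundred_is_low_sixth_is_not():
    values = list(np.arange(100, dtype=float) + 1)  # distinct 1..100
    m = _matrix(values)
    ev5 = expression_aberrant(m, "RB1", "s4", CONFIG)   # value 5, rank 5
    ev6 = expression_aberrant(m, "RB1", "s5", CONFIG)   # value 6, rank 6
    assert ev5 is not None and ev5.kind is EvidenceKind.EXPRESSION_LOW
    assert ev6 is None


def test_top_tail_flagged_high():
    values = list(np.arange(100, dtype=float) + 1)
    ev = expression_aberrant(_matrix(values), "RB1", "s99", CONFIG)
    assert ev.kind is EvidenceKind.EXPRESSION_HIGH


def test_small_cohort_is_no_data():
    with pytest.raises(ExpressionNoData):
        expression_aberrant(_matrix([1.0] * 10), "RB1", "s0", CONFIG)


def _oracle_tail(values, idx, percent):
    """Sort-based oracle: position of the value among sorted cohort values."""
    import math

    v = values[idx]
    n = len(values)
    k = max(1, math.ceil(percent / 100 * n))
    lo = sorted(values)[k - 1]
    hi = sorted(values, reverse=True)[k - 1]
    if v <= lo:
        return "low"
    if v >= hi:
        return "high"
    return None


def test_percentile_agrees_with_sort_oracle_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(20, 401))
        values = rng.lognormal(2, 1, n).round(4)
        idx = int(rng.integers(n))
        m = _matrix(list(values))
        ev = expression_aberrant(m, "RB1", f"s{idx}", CONFIG)
        got = None if ev is None else (
            "low" if ev.kind is EvidenceKind.EXPRESSION_LOW else "high"
        )
        assert got == _oracle_tail(list(values), idx, 5.0)


def test_nearest_rank_percentile_definition():
    assert nearest_rank_percentile(np.arange(1, 101), 5) == 5.0
    assert nearest_rank_percentile(np.array([7.0]), 5) == 7.0


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def _meth(betas, gene="SDHC", sample="s1", dist=(-500, 0, 500, 900)):
    rows = [
        {"probe": f"p{i}", "gene": gene, "dist_tss": dist[i % len(dist)],
         "beta": b, "sample": sample}
        for i, b in enumerate(betas)
    ]
    return MethylationTable(pd.DataFrame(rows))


def test_hypermethylated_promoter_with_copy_neutral_locus():
    ev, no_data = methylation_hit(_meth([0.8, 0.9, 0.85]), "SDHC", "s1",
                                  CONFIG, copy_neutral=True)
    assert not no_data
    assert ev.kind is EvidenceKind.PROMOTER_HYPERMETHYLATION
    assert ev.biallelic_consistent is True
    assert ev.mean_beta == pytest.approx(0.85)


def test_unmethylated_promoter_is_no_hit():
    ev, no_data = methylation_hit(_meth([0.05, 0.1, 0.08]), "SDHC", "s1", CONFIG)
    assert ev is None and not no_data


def test_two_probes_is_no_data():
    ev, no_data = methylation_hit(_meth([0.8, 0.9]), "SDHC", "s1", CONFIG)
    assert ev is None and no_data


def test_probes_outside_promoter_window_ignored():
    table = _meth([0.9, 0.9, 0.9, 0.9], dist=(-3000, 2000, 1600, -1501))
    ev, no_data = methylation_hit(table, "SDHC", "s1", CONFIG)
    assert no_data  # all probes fall outside TSS +/- 1500


# ---------------------------------------------------------------------------
# Pathway expansion
# ---------------------------------------------------------------------------

def test_pathway_expansion_empty_table():
    assert pathway_expansion("NF1", {"NF1": []}, [], CONFIG) == []


def test_pathway_hit_labelled_and_does_not_claim_gene():
    somatic = [make_somatic(gene="SPRED1", vaf=0.3)]
    (ev,) = pathway_expansion("NF1", {"NF1": ["SPRED1"]}, somatic, CONFIG)
    assert ev.pathway_gene == "SPRED1"
    verdict = integrate_verdict("t1", "NF1", [ev])
    assert not verdict.hit_found  # pathway evidence never upgrades the gene


def test_pathway_gene_absent_warns():
    with pytest.warns(UserWarning, match="interaction table"):
        assert pathway_expansion("WRN", {}, [], CONFIG) == []


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def test_tmb_exact_arithmetic():
    def bulk(n):
        return [make_somatic(vaf=0.3, depth=50, population_af=0.0, pos=i)
                for i in range(n)]

    assert compute_tmb([], CONFIG) == (0.0, False)
    tmb30, high30 = compute_tmb(bulk(30), CONFIG)
    assert tmb30 == pytest.approx(0.01) and not high30
    tmb33k, high33k = compute_tmb(bulk(33_000), CONFIG)
    assert tmb33k == pytest.approx(11.0) and high33k


@pytest.mark.parametrize(
    "depth,vaf,gnomad,counts",
    [
        (10, 0.05, 0.001, True),    # all gates inclusive at the boundary
        (9, 0.3, 0.0, False),       # depth below minimum
        (100, 0.049, 0.0, False),   # VAF below minimum
        (100, 0.3, 0.0011, False),  # population frequency above maximum
        (100, 0.3, None, True),     # missing population AF counts as rare
    ],
)
def test_tmb_gate_boundaries(depth, vaf, gnomad, counts):
    v = make_somatic(vaf=vaf, depth=depth, population_af=gnomad)
    tmb, _ = compute_tmb([v], CONFIG)
    assert (tmb > 0) == counts


def test_tmb_linearity():
    vs = [make_somatic(vaf=0.3, depth=50, population_af=0.0, pos=i)
          for i in range(17)]
    single, _ = compute_tmb(vs, CONFIG)
    double, _ = compute_tmb(vs + [make_somatic(vaf=0.3, depth=50,
                                               population_af=0.0, pos=100 + i)
                                  for i in range(17)], CONFIG)
    assert double == pytest.approx(2 * single)


def test_structural_variants_excluded_from_tmb():
    sv = make_somatic(is_structural=True, svtype="DEL", end=5000, vaf=0.4)
    assert compute_tmb([sv], CONFIG)[0] == 0.0


# ---------------------------------------------------------------------------
# Verdict integration
# ---------------------------------------------------------------------------

def test_focal_deletion_yields_hit():
    ev = SomaticEvidence(EvidenceKind.FOCAL_DELETION, "MLH1", copy_number=1.0)
    v = integrate_verdict("t1", "MLH1", [ev], Expectation.SEMI_EXPECTED)
    assert v.hit_found and v.informative


def test_no_evidence_is_informative_negative():
    v = integrate_verdict("t1", "BRCA1", [])
    assert not v.hit_found and v.informative
    assert v.narrative == "no second hit"


def test_sole_chromothripsis_evidence_is_uninformative():
    ev = SomaticEvidence(EvidenceKind.UNINFORMATIVE_CHROMOTHRIPSIS, "RB1")
    v = integrate_verdict("t1", "RB1", [ev])
    assert not v.hit_found and not v.informative


def test_positive_evidence_overrides_uninformative_cn():
    evs = [
        SomaticEvidence(EvidenceKind.UNINFORMATIVE_LARGE_DELETION, "RB1"),
        SomaticEvidence(EvidenceKind.SNV_OR_INDEL, "RB1", vaf=0.3,
                        detail="snv"),
    ]
    v = integrate_verdict("t1", "RB1", evs)
    assert v.hit_found and v.informative


def test_narrative_priority_order():
    evs = [
        SomaticEvidence(EvidenceKind.EXPRESSION_LOW, "RB1", detail="expr"),
        SomaticEvidence(EvidenceKind.SNV_OR_INDEL, "RB1", vaf=0.3, detail="snv"),
        SomaticEvidence(EvidenceKind.FOCAL_DELETION, "RB1", detail="del"),
    ]
    v = integrate_verdict("t1", "RB1", evs)
    kinds = [e.kind for e in v.evidence]
    assert kinds == [EvidenceKind.SNV_OR_INDEL, EvidenceKind.FOCAL_DELETION,
                     EvidenceKind.EXPRESSION_LOW]
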