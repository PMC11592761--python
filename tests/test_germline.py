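"""Germline screen: gates, exclusion rules, triage, reportability."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from twohit.config import ThresholdConfig
from twohit.germline import (
    apply_exclusion_rules,
    label_expectation,
    prefilter,
    prefilter_status,
    reportability,
    screen_case,
    triage,
)
from twohit.models import (
    Actionability,
    Classification,
    Consequence,
    Expectation,
    GenePanel,
    Genotype,
    Inheritance,
    KnowledgeRow,
    KnowledgeTable,
    ScreenResult,
    ScreenStatus,
)
from twohit.resources import default_knowledge, default_panel

from conftest import make_germline

CONFIG = ThresholdConfig()
PANEL = GenePanel(["CHEK2", "NF1", "RB1", "MUTYH", "SDHA"])


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

def test_off_panel_gene_excluded():
    rec = make_germline(gene="GENE_X")
    assert prefilter_status(rec, PANEL, CONFIG) is ScreenStatus.EXCLUDED_PANEL


def test_noncoding_excluded():
    rec = make_germline(consequence=Consequence.NON_CODING)
    assert prefilter_status(rec, PANEL, CONFIG) is ScreenStatus.EXCLUDED_NONCODING


def test_frequency_gate_is_strict_at_boundary():
    # an allele frequency of exactly 0.01 does NOT survive the < 0.01 gate
    at = make_germline(population_af=0.01)
    below = make_germline(population_af=0.0099)
    assert prefilter_status(at, PANEL, CONFIG) is ScreenStatus.EXCLUDED_FREQUENCY
    assert prefilter_status(below, PANEL, CONFIG) is None


def test_missing_af_survives_frequency_gate():
    rec = make_germline(population_af=None,
                        consequence=Consequence.SPLICE_SITE)
    assert prefilter_status(rec, PANEL, CONFIG) is None


def test_rare_splice_variant_survives():
    rec = make_germline(consequence=Consequence.SPLICE_SITE,
                        population_af=0.0001)
    assert prefilter_status(rec, PANEL, CONFIG) is None


# ---------------------------------------------------------------------------
# Exclusion rules A / B / C
# ---------------------------------------------------------------------------

def test_rule_a_benign_three_submitters():
    rec = make_germline(classification=Classification.BENIGN,
                        benign_submitters=3)
    assert apply_exclusion_rules(rec, CONFIG) is ScreenStatus.EXCLUDED_RULE_A


def test_rule_b_frequent_synonymous():
    rec = make_germline(consequence=Consequence.SYNONYMOUS, local_count=101)
    assert apply_exclusion_rules(rec, CONFIG) is ScreenStatus.EXCLUDED_RULE_B


def test_rule_c_single_submitter_high_local_count():
    rec = make_germline(classification=Classification.LIKELY_BENIGN,
                        benign_submitters=1, local_count=81)
    assert apply_exclusion_rules(rec, CONFIG) is ScreenStatus.EXCLUDED_RULE_C


def test_no_rule_fires_on_moderate_evidence():
    # brute-force evaluation of the three predicates confirms none fires:
    # 2 submitters (not > 2), missense (rule B needs synonymous),
    # local count 50 (not > 80)
    rec = make_germline(classification=Classification.BENIGN,
                        benign_submitters=2, local_count=50)
    assert apply_exclusion_rules(rec, CONFIG) is None


def _oracle_rules(submitters, local_count, consequence, config):
    """Independent brute-force restatement of the three exclusion rules."""
    rule_a = submitters > 2
    rule_b = local_count > 100 and consequence is Consequence.SYNONYMOUS
    rule_c = submitters == 1 and local_count > 80
    for fired, status in [
        (rule_a, ScreenStatus.EXCLUDED_RULE_A),
        (rule_b, ScreenStatus.EXCLUDED_RULE_B),
        (rule_c, ScreenStatus.EXCLUDED_RULE_C),
    ]:
        if fired:
            return status
    return None


@pytest.mark.parametrize(
    "submitters,local_count,consequence",
    list(itertools.product(
        [0, 1, 3],
        [0, 81, 101],
        [Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.NONSENSE],
    )),
)
def test_rule_engine_matches_oracle_on_grid(submitters, local_count, consequence):
    rec = make_germline(
        consequence=consequence,
        classification=(Classification.LIKELY_BENIGN if submitters
                        else Classification.NONE),
        benign_submitters=submitters,
        local_count=local_count,
    )
    assert apply_exclusion_rules(rec, CONFIG) == _oracle_rules(
        submitters, local_count, consequence, CONFIG
    )


# ---------------------------------------------------------------------------
# Monotonicity properties
# ---------------------------------------------------------------------------

record_strategy = st.builds(
    make_germline,
    gene=st.sampled_from(["CHEK2", "NF1", "GENE_X"]),
    consequence=st.sampled_from(list(Consequence)),
    population_af=st.one_of(st.none(), st.floats(0, 0.5)),
    benign_submitters=st.integers(0, 5),
    classification=st.just(Classification.LIKELY_BENIGN),
    local_count=st.integers(0, 200),
)


@settings(max_examples=200, derandomize=True)
@given(st.lists(record_strategy, max_size=20), st.floats(0.0001, 0.01))
def test_lowering_af_threshold_never_grows_surviving_set(records, af_max):
    def survivors(cfg):
        return {
            id(r.record) for r in prefilter(records, PANEL, cfg)
            if not r.status.is_excluded
        }

    loose = ThresholdConfig()
    tight = ThresholdConfig(af_max=af_max)
    assert survivors(tight) <= survivors(loose)


@settings(max_examples=200, derandomize=True)
@given(st.lists(record_strategy, max_size=20), st.integers(2, 6),
       st.integers(80, 300))
def test_raising_rule_thresholds_never_shrinks_surviving_set(
    records, extra_submitters, extra_count
):
    base = ThresholdConfig()
    raised = ThresholdConfig(
        rule_a_min_submitters=base.rule_a_min_submitters + extra_submitters,
        rule_b_min_local_count=base.rule_b_min_local_count + extra_count,
        rule_c_min_local_count=base.rule_c_min_local_count + extra_count,
    )

    def kept(cfg):
        return {id(r) for r in records if apply_exclusion_rules(r, cfg) is None}

    assert kept(base) <= kept(raised)


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

KNOWLEDGE = default_knowledge()


def test_missense_without_cancer_association_is_vus():
    rec = make_germline(consequence=Consequence.MISSENSE, cancer_assoc=False,
                        classification=Classification.PATHOGENIC)
    assert triage(rec, True, KNOWLEDGE) is ScreenStatus.VUS


def test_truncating_with_mechanism_and_phenotype_is_pathogenic():
    # the recurrent CHEK2 frameshift: truncation is the known mechanism
    # and the phenotype is relevant
    rec = make_germline(gene="CHEK2", consequence=Consequence.FRAMESHIFT,
                        classification=Classification.PATHOGENIC,
                        cancer_assoc=True)
    assert triage(rec, True, KNOWLEDGE) is ScreenStatus.PATHOGENIC


def test_nonsense_without_truncation_mechanism_is_vus():
    knowledge = KnowledgeTable([
        KnowledgeRow(gene="MITF", truncation_is_mechanism=False,
                     inheritance=Inheritance.DOMINANT)
    ])
    rec = make_germline(gene="MITF", consequence=Consequence.NONSENSE,
                        classification=Classification.PATHOGENIC)
    assert triage(rec, True, knowledge) is ScreenStatus.VUS


def test_truncating_without_phenotype_association_is_vus():
    rec = make_germline(gene="CHEK2", consequence=Consequence.FRAMESHIFT,
                        classification=Classification.PATHOGENIC)
    assert triage(rec, False, KNOWLEDGE) is ScreenStatus.VUS


def test_synonymous_never_reaches_plp():
    rec = make_germline(consequence=Consequence.SYNONYMOUS,
                        classification=Classification.PATHOGENIC,
                        cancer_assoc=True)
    assert triage(rec, True, KNOWLEDGE) is ScreenStatus.VUS


# ---------------------------------------------------------------------------
# Reportability
# ---------------------------------------------------------------------------

def _plp_result(gene, genotype=Genotype.HET, pos=1000):
    rec = make_germline(gene=gene, consequence=Consequence.NONSENSE,
                        classification=Classification.PATHOGENIC,
                        genotype=genotype, pos=pos)
    return ScreenResult(rec, ScreenStatus.PATHOGENIC)


def test_het_pathogenic_in_dominant_gene_is_reportable():
    (res,) = reportability([_plp_result("NF1")], KNOWLEDGE)
    assert res.reportable
    assert res.inheritance_mode is Inheritance.DOMINANT


def test_single_het_in_recessive_gene_is_carrier_only():
    (res,) = reportability([_plp_result("MUTYH")], KNOWLEDGE)
    assert not res.reportable
    assert res.actionability is Actionability.NONE


def test_homozygous_in_recessive_gene_is_reportable():
    (res,) = reportability([_plp_result("MUTYH", Genotype.HOM)], KNOWLEDGE)
    assert res.reportable and not res.compound_het


def test_two_het_variants_in_recessive_gene_flagged_compound():
    results = reportability(
        [_plp_result("MUTYH", pos=1000), _plp_result("MUTYH", pos=2000)],
        KNOWLEDGE,
    )
    assert all(r.reportable and r.compound_het for r in results)


# ---------------------------------------------------------------------------
# Expectation labels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gene,expected",
    [
        ("NF1", Expectation.EXPECTED),          # known mesenchymal association
        ("CHEK2", Expectation.EXPECTED),        # suggested association
        ("MLH1", Expectation.SEMI_EXPECTED),    # Lynch syndrome
        ("KCNQ1", Expectation.NOT_EXPECTED),    # no known association
    ],
)
def test_expectation_labels(gene, expected):
    assert label_expectation(gene, KNOWLEDGE) is expected


# ---------------------------------------------------------------------------
# Full screen determinism
# ---------------------------------------------------------------------------

def test_screen_is_deterministic():
    records = [
        make_germline(gene="NF1", consequence=Consequence.NONSENSE,
                      classification=Classification.PATHOGENIC,
                      cancer_assoc=True),
        make_germline(gene="CHEK2", population_af=0.02, pos=2000),
        make_germline(gene="GENE_X", pos=3000),
    ]
    a = screen_case(records, default_panel(), KNOWLEDGE)
    b = screen_case(records, default_panel(), KNOWLEDGE)
    assert a == b
    statuses = {r.record.gene: r.status for r in a}
    assert statuses["NF1"] is ScreenStatus.PATHOGENIC
    assert statuses["CHEK2"] is ScreenStatus.EXCLUDED_FREQUENCY
    assert statuses["GENE_X"] is ScreenStatus.EXCLUDED_PANEL
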