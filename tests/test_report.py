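"""Cohort statistics: rates, category table, odds ratios, t-test."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from twohit.errors import ValidationError
from twohit.models import (
    CaseRecord,
    DiagnosisCategory,
    EvidenceKind,
    Expectation,
    SecondHitVerdict,
    SomaticEvidence,
)
from twohit.report import (
    age_comparison,
    category_table,
    detection_rates,
    odds_ratio,
    percent,
    round_half_away,
    second_hit_rate,
)


def _case(cid, finding=False, malignant=True,
          category=DiagnosisCategory.SOFT_TISSUE_SARCOMA_HIGH,
          hit=None, no_tumor=False):
    c = CaseRecord(case_id=cid, diagnosis="x", category=category,
                   malignant=malignant, germline_finding=finding,
                   no_tumor_tissue=no_tumor)
    if hit is not None:
        evidence = (
            (SomaticEvidence(EvidenceKind.SNV_OR_INDEL, "NF1"),) if hit else ()
        )
        c.verdicts = [
            SecondHitVerdict(cid, "NF1", hit, evidence, True,
                             Expectation.EXPECTED, "")
        ]
    return c


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [
    (45.83, 46), (12.5, 13), (4.5, 5), (41.7, 42), (0.4, 0), (-12.5, -13),
])
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


def test_eleven_of_twentyfour_prints_as_46_percent():
    assert percent(11, 24) == 46


# ---------------------------------------------------------------------------
# Detection rates
# ---------------------------------------------------------------------------

def test_cohort_of_ten_with_one_carrier_is_ten_percent():
    cases = [_case(f"c{i}", finding=(i == 0)) for i in range(10)]
    rates = detection_rates(cases)
    assert rates.whole_cohort.numerator == 1
    assert rates.whole_cohort.as_percent == 10


def test_excluding_benign_restricts_both_sides():
    cases = [
        _case("m1", finding=True, malignant=True),
        _case("b1", finding=True, malignant=False),
        _case("m2", malignant=True),
        _case("b2", malignant=False),
    ]
    rates = detection_rates(cases)
    assert (rates.whole_cohort.numerator, rates.whole_cohort.denominator) == (2, 4)
    assert (rates.excluding_benign.numerator,
            rates.excluding_benign.denominator) == (1, 2)


def test_all_benign_cohort_flags_undefined_rate():
    cases = [_case("b1", malignant=False), _case("b2", malignant=False)]
    rates = detection_rates(cases)
    assert not rates.excluding_benign.defined
    with pytest.raises(ValidationError):
        rates.excluding_benign.fraction


def test_empty_cohort_is_an_error():
    with pytest.raises(ValidationError):
        detection_rates([])


# ---------------------------------------------------------------------------
# Category table
# ---------------------------------------------------------------------------

def test_single_case_cohort_is_hundred_percent():
    df = category_table([_case("c1", finding=True,
                               category=DiagnosisCategory.GIST)])
    assert df.loc["GIST", "finding_n"] == 1
    assert df.loc["GIST", "finding_pct"] == 100


def test_count_conservation():
    cases = (
        [_case(f"a{i}", finding=True) for i in range(3)]
        + [_case(f"b{i}", category=DiagnosisCategory.GIST) for i in range(5)]
    )
    df = category_table(cases)
    assert int(df["finding_n"].sum()) == 3
    assert int(df["no_finding_n"].sum()) == 5


def test_missing_category_is_error_listing_case():
    bad = CaseRecord(case_id="c9", diagnosis="mystery lump", category=None)
    with pytest.raises(ValidationError, match="c9"):
        category_table([bad])


# ---------------------------------------------------------------------------
# Second-hit rate
# ---------------------------------------------------------------------------

def test_second_hit_rate_counts_carriers_only():
    cases = [
        _case("c1", finding=True, hit=True),
        _case("c2", finding=True, hit=False),
        _case("c3"),  # non-carrier, ignored
    ]
    summary = second_hit_rate(cases)
    assert (summary.rate.numerator, summary.rate.denominator) == (1, 2)


def test_no_tumor_case_stays_in_denominator_but_flagged():
    cases = [
        _case("c1", finding=True, hit=True),
        _case("c2", finding=True, hit=False, no_tumor=True),
    ]
    summary = second_hit_rate(cases)
    assert summary.rate.denominator == 2
    assert summary.no_tumor_cases == ("c2",)


def test_zero_carriers_is_undefined_and_flagged():
    assert not second_hit_rate([_case("c1")]).rate.defined


def test_all_carriers_with_hits_is_hundred_percent():
    cases = [_case(f"c{i}", finding=True, hit=True) for i in range(4)]
    assert second_hit_rate(cases).rate.as_percent == 100


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

def test_odds_ratio_closed_form():
    assert odds_ratio(1, 2, 3, 4).odds_ratio == pytest.approx(2 / 3, abs=1e-9)
    assert odds_ratio(5, 5, 5, 5).odds_ratio == pytest.approx(1.0)


def test_zero_cell_gets_haldane_correction_and_flag():
    res = odds_ratio(3, 0, 2, 4)
    assert res.corrected
    assert res.odds_ratio == pytest.approx((3.5 * 4.5) / (0.5 * 2.5))  # 12.6


def test_negative_cell_rejected():
    with pytest.raises(ValidationError):
        odds_ratio(-1, 2, 3, 4)


@settings(max_examples=100, derandomize=True)
@given(st.integers(1, 200), st.integers(1, 200), st.integers(1, 200),
       st.integers(1, 200))
def test_odds_ratio_reciprocal_inversion(a, b, c, d):
    assert odds_ratio(a, b, c, d).odds_ratio * odds_ratio(
        b, a, d, c
    ).odds_ratio == pytest.approx(1.0)


def test_confidence_interval_matches_statsmodels():
    # independent route: statsmodels' 2x2 table implementation
    from statsmodels.stats.contingency_tables import Table2x2

    res = odds_ratio(12, 7, 30, 44)
    tab = Table2x2([[12, 7], [30, 44]])
    lo, hi = tab.oddsratio_confint(0.05)
    assert res.odds_ratio == pytest.approx(tab.oddsratio)
    assert res.ci_low == pytest.approx(lo, rel=1e-6)
    assert res.ci_high == pytest.approx(hi, rel=1e-6)


# ---------------------------------------------------------------------------
# Age comparison
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_t_and_unit_p():
    res = age_comparison([1, 2, 3], [1, 2, 3])
    assert res.t_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert not res.significant


def test_t_statistic_matches_pooled_variance_formula():
    g1, g2 = [10.0, 12.0, 14.0], [20.0, 22.0, 24.0]
    res = age_comparison(g1, g2)
    # hand-computed pooled-variance t
    m1, m2 = sum(g1) / 3, sum(g2) / 3
    s2 = (sum((x - m1) ** 2 for x in g1) + sum((x - m2) ** 2 for x in g2)) / 4
    t_manual = (m1 - m2) / math.sqrt(s2 * (1 / 3 + 1 / 3))
    assert res.t_statistic == pytest.approx(t_manual)
    assert res.significant


def test_degenerate_groups_rejected():
    with pytest.raises(ValidationError):
        age_comparison([1.0], [2.0, 3.0])
    with pytest.raises(ValidationError):
        age_comparison([5.0, 5.0], [5.0, 5.0])
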