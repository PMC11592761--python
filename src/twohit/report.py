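"""Cohort-level summaries.

Detection rates (whole cohort and excluding benign tumors), the 8 x 2
diagnosis-category table for carriers versus the rest of the cohort,
second-hit rates overall and by expectation label, odds ratios (carrier
status vs malignancy, carrier status vs sex) with 95% Woolf confidence
intervals, and a Student's t-test on the age distributions.

Percentages are rounded half away from zero to whole percent; all
functions are deterministic so identical inputs yield byte-identical
reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .models import CaseRecord, DiagnosisCategory, Expectation, Sex

CATEGORY_LABELS = {
    DiagnosisCategory.SOFT_TISSUE_SARCOMA_HIGH: "Soft tissue sarcoma, high-grade",
    DiagnosisCategory.SOFT_TISSUE_SARCOMA_LOW: "Soft tissue sarcoma, low-grade",
    DiagnosisCategory.SOFT_TISSUE_BENIGN: "Soft tissue, benign",
    DiagnosisCategory.BONE_SARCOMA_HIGH: "Bone sarcoma, high-grade",
    DiagnosisCategory.BONE_SARCOMA_LOW: "Bone sarcoma, low-grade",
    DiagnosisCategory.BONE_BENIGN: "Bone, benign",
    DiagnosisCategory.GIST: "GIST",
    DiagnosisCategory.GYNAECOLOGICAL_TRACT: "Gynaecological tract",
}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (12.5 -> 13)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent(numerator: int, denominator: int) -> int:
    if denominator == 0:
        raise ValidationError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator)


# ---------------------------------------------------------------------------
# Detection rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rate:
    numerator: int
    denominator: int
    defined: bool = True

    @property
    def fraction(self) -> float:
        if not self.defined:
            raise ValidationError("rate is undefined (zero denominator)")
        return self.numerator / self.denominator

    @property
    def as_percent(self) -> int:
        return percent(self.numerator, self.denominator)

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        return f"{self.numerator}/{self.denominator} ({self.as_percent}%)"


@dataclass(frozen=True)
class DetectionRates:
    whole_cohort: Rate
    excluding_benign: Rate


def detection_rates(cases: Sequence[CaseRecord]) -> DetectionRates:
    """Germline-finding rates for the whole cohort and excluding benign cases."""
    if not cases:
        raise ValidationError("empty cohort")
    carriers = [c for c in cases if c.germline_finding]
    malignant = [c for c in cases if c.malignant]
    malignant_carriers = [c for c in malignant if c.germline_finding]
    whole = Rate(len(carriers), len(cases))
    if malignant:
        excl = Rate(len(malignant_carriers), len(malignant))
    else:
        excl = Rate(0, 0, defined=False)
    return DetectionRates(whole_cohort=whole, excluding_benign=excl)


# ---------------------------------------------------------------------------
# Category table
# ---------------------------------------------------------------------------

def category_table(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """8 x 2 diagnosis-category counts with per-column whole-percent fractions.

    Columns: counts and percentages for the no-germline-finding subcohort
    and the germline-finding subcohort. Every case must carry a category.
    """
    unmapped = [c.case_id for c in cases if c.category is None]
    if unmapped:
        raise ValidationError(f"cases without diagnosis category: {unmapped[:5]}")
    rows = []
    finding = [c for c in cases if c.germline_finding]
    no_finding = [c for c in cases if not c.germline_finding]
    for cat in DiagnosisCategory:
        n_no = sum(1 for c in no_finding if c.category is cat)
        n_yes = sum(1 for c in finding if c.category is cat)
        rows.append(
            {
                "category": CATEGORY_LABELS[cat],
                "no_finding_n": n_no,
                "no_finding_pct": percent(n_no, len(no_finding)) if no_finding else 0,
                "finding_n": n_yes,
                "finding_pct": percent(n_yes, len(finding)) if finding else 0,
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    assert int(df["no_finding_n"].sum()) == len(no_finding)
    assert int(df["finding_n"].sum()) == len(finding)
    return df


# ---------------------------------------------------------------------------
# Second-hit rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondHitSummary:
    rate: Rate
    no_tumor_cases: tuple[str, ...]  # flagged but kept in the denominator
    by_expectation: dict = field(default_factory=dict)


def second_hit_rate(cases: Sequence[CaseRecord]) -> SecondHitSummary:
    """Fraction of carrier cases whose tumor shows a second hit.

    Cases without tumor tissue stay in both numerator-eligible set and
    denominator (they simply cannot contribute a hit) but are flagged.
    """
    carriers = [c for c in cases if c.germline_finding]
    if not carriers:
        return SecondHitSummary(Rate(0, 0, defined=False), ())
    hit_cases = [
        c for c in carriers if any(v.hit_found for v in c.verdicts)
    ]
    by_exp: dict[str, Rate] = {}
    for exp in Expectation:
        group = [
            c for c in carriers
            if any(v.expectation is exp for v in c.verdicts)
        ]
        if group:
            hits = sum(
                1 for c in group
                if any(v.hit_found and v.expectation is exp for v in c.verdicts)
            )
            by_exp[exp.value] = Rate(hits, len(group))
    return SecondHitSummary(
        rate=Rate(len(hit_cases), len(carriers)),
        no_tumor_cases=tuple(
            c.case_id for c in carriers if c.no_tumor_tissue
        ),
        by_expectation=by_exp,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to a zero cell

    def __str__(self) -> str:
        flag = " (0.5 correction)" if self.corrected else ""
        return (
            f"OR {self.odds_ratio:.3g} "
            f"[95% CI {self.ci_low:.3g}-{self.ci_high:.3g}]{flag}"
        )


def odds_ratio(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with a Woolf (log-OR normal) 95% CI.

    Zero cells get the Haldane-Anscombe 0.5 continuity correction (added
    to every cell) and the result is flagged.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency cells must be non-negative")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        corrected=corrected,
    )


@dataclass(frozen=True)
class AgeComparison:
    t_statistic: float
    p_value: float
    significant: bool  # at the 0.05 level


def age_comparison(
    group1: Sequence[float], group2: Sequence[float], equal_var: bool = True
) -> AgeComparison:
    """Two-sample t-test on ages (Student's, equal-variance, by default)."""
    if len(group1) < 2 or len(group2) < 2:
        raise ValidationError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(np.asarray(group1, dtype=float),
                           np.asarray(group2, dtype=float),
                           equal_var=equal_var)
    if math.isnan(t):
        raise ValidationError("degenerate groups (zero pooled variance)")
    return AgeComparison(float(t), float(p), bool(p < 0.05))


# ---------------------------------------------------------------------------
# Whole-cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    detection: DetectionRates
    categories: pd.DataFrame
    second_hits: SecondHitSummary
    or_malignancy: Optional[OddsRatioResult]
    or_sex: Optional[OddsRatioResult]
    age: Optional[AgeComparison]
    n_actionable: int
    n_carriers: int


def cohort_summary(cases: Sequence[CaseRecord],
                   n_actionable: Optional[int] = None) -> CohortSummary:
    """Compute the full set of cohort statistics from annotated cases."""
    carriers = [c for c in cases if c.germline_finding]
    rest = [c for c in cases if not c.germline_finding]

    def cell(group, pred):
        return sum(1 for c in group if pred(c))

    or_mal = or_sex = None
    if carriers and rest:
        or_mal = odds_ratio(
            cell(carriers, lambda c: c.malignant),
            cell(carriers, lambda c: not c.malignant),
            cell(rest, lambda c: c.malignant),
            cell(rest, lambda c: not c.malignant),
        )
        if all(c.sex is not None for c in cases):
            or_sex = odds_ratio(
                cell(carriers, lambda c: c.sex is Sex.FEMALE),
                cell(carriers, lambda c: c.sex is Sex.MALE),
                cell(rest, lambda c: c.sex is Sex.FEMALE),
                cell(rest, lambda c: c.sex is Sex.MALE),
            )
    age = None
    ages1 = [c.age for c in carriers if c.age is not None]
    ages2 = [c.age for c in rest if c.age is not None]
    if len(ages1) >= 2 and len(ages2) >= 2:
        age = age_comparison(ages1, ages2)

    return CohortSummary(
        detection=detection_rates(cases),
        categories=category_table(cases),
        second_hits=second_hit_rate(cases),
        or_malignancy=or_mal,
        or_sex=or_sex,
        age=age,
        n_actionable=n_actionable if n_actionable is not None else 0,
        n_carriers=len(carriers),
    )


def render_text(summary: CohortSummary) -> str:
    """Human-readable cohort report (deterministic)."""
    lines = ["Cohort summary", "=============="]
    lines.append(f"Germline detection, whole cohort: {summary.detection.whole_cohort}")
    lines.append(
        f"Germline detection, excluding benign: {summary.detection.excluding_benign}"
    )
    lines.append(f"Clinically actionable findings: {summary.n_actionable}")
    lines.append(f"Second hits among carriers: {summary.second_hits.rate}")
    for exp, rate in sorted(summary.second_hits.by_expectation.items()):
        lines.append(f"  {exp}: {rate}")
    if summary.second_hits.no_tumor_cases:
        lines.append(
            "  no tumor tissue (kept in denominator): "
            + ", ".join(summary.second_hits.no_tumor_cases)
        )
    if summary.or_malignancy:
        lines.append(f"OR malignancy (carrier vs rest): {summary.or_malignancy}")
    if summary.or_sex:
        lines.append(f"OR female sex (carrier vs rest): {summary.or_sex}")
    if summary.age:
        lines.append(
            f"Age comparison: t = {summary.age.t_statistic:.3f}, "
            f"p = {summary.age.p_value:.3f}"
            + (" (significant)" if summary.age.significant else "")
        )
    lines.append("")
    lines.append(summary.categories.to_string())
    return "\n".join(lines) + "\n"
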