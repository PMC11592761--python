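"""Germline variant screening.

The screen restricts blood variants to a hereditary-cancer gene panel,
applies a population-frequency gate and three benign-evidence exclusion
rules, triages the survivors into VUS / likely pathogenic / pathogenic,
and decides reportability by the gene's inheritance mode:

* frequency gate: gnomAD allele frequency strictly below ``af_max``
  (default 0.01); a missing frequency is treated as 0 (a novel variant is
  by definition rare).
* rule A: benign or likely benign in ClinVar by more than two submitters.
* rule B: more than 100 occurrences in the local assertion database
  (9244 cases) AND synonymous.
* rule C: benign/likely benign by exactly one submitter AND more than 80
  local occurrences.

Rules are evaluated in the fixed order A, B, C and the first rule to fire
is recorded, giving every exclusion a deterministic provenance trace.

Triage deliberately does not re-derive expert ACMG/AMP judgement: missense
variants without a reported cancer-syndrome association and truncating
variants without phenotype relevance (or in genes where truncation is not
the disease mechanism) become VUS; otherwise the pathogenicity assertion
attached to the variant (an overridable input) decides P/LP.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import ThresholdConfig, DEFAULT_CONFIG
from .models import (
    Actionability,
    CaseRecord,
    Classification,
    Consequence,
    Expectation,
    GenePanel,
    GermlineVariantRecord,
    Genotype,
    Inheritance,
    KnowledgeRow,
    KnowledgeTable,
    MesenchymalAssociation,
    ScreenResult,
    ScreenStatus,
)

# ---------------------------------------------------------------------------
# Gates and exclusion rules
# ---------------------------------------------------------------------------

def prefilter_status(
    record: GermlineVariantRecord,
    panel: GenePanel,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> Optional[ScreenStatus]:
    """Panel / coding / frequency gates; None means the record survives.

    A record survives iff its gene is on the panel, its consequence is
    exonic or splicing, and its population AF is strictly below
    ``config.af_max`` (missing AF survives).
    """
    if record.gene not in panel:
        return ScreenStatus.EXCLUDED_PANEL
    if not record.consequence.is_coding:
        return ScreenStatus.EXCLUDED_NONCODING
    if record.af_for_filter >= config.af_max:
        return ScreenStatus.EXCLUDED_FREQUENCY
    return None


def rule_a_fires(record: GermlineVariantRecord, config: ThresholdConfig) -> bool:
    """Benign/likely benign in ClinVar by more than two submitters."""
    return record.clinvar.benign_submitters > config.rule_a_min_submitters


def rule_b_fires(record: GermlineVariantRecord, config: ThresholdConfig) -> bool:
    """> 100 local-database occurrences AND synonymous."""
    return (
        record.local_count > config.rule_b_min_local_count
        and record.consequence is Consequence.SYNONYMOUS
    )


def rule_c_fires(record: GermlineVariantRecord, config: ThresholdConfig) -> bool:
    """Benign/likely benign by exactly one submitter AND > 80 local occurrences."""
    return (
        record.clinvar.benign_submitters == config.rule_c_submitters
        and record.local_count > config.rule_c_min_local_count
    )


def apply_exclusion_rules(
    record: GermlineVariantRecord,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> Optional[ScreenStatus]:
    """Evaluate rules in order A, B, C; return the first that fires, else None."""
    if rule_a_fires(record, config):
        return ScreenStatus.EXCLUDED_RULE_A
    if rule_b_fires(record, config):
        return ScreenStatus.EXCLUDED_RULE_B
    if rule_c_fires(record, config):
        return ScreenStatus.EXCLUDED_RULE_C
    return None


def prefilter(
    records: Iterable[GermlineVariantRecord],
    panel: GenePanel,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[ScreenResult]:
    """Apply the panel/coding/frequency gates to every record.

    Surviving records get a provisional VUS status (triage refines it);
    excluded records carry the gate that fired.
    """
    out = []
    for rec in records:
        status = prefilter_status(rec, panel, config)
        if status is None:
            out.append(ScreenResult(rec, ScreenStatus.VUS,
                                    rule_trace=("panel", "coding", "frequency")))
        else:
            out.append(ScreenResult(rec, status, rule_trace=(status.value,)))
    return out


# ---------------------------------------------------------------------------
# Triage
# ---------------------------------------------------------------------------

def triage(
    record: GermlineVariantRecord,
    phenotype_match: bool,
    knowledge: KnowledgeTable,
) -> ScreenStatus:
    """Classify a filter-surviving variant as VUS / LP / P.

    ``phenotype_match`` states whether the gene's associated syndrome is
    relevant to this patient's phenotype (a per-case clinical input).
    Synonymous variants can never reach P/LP. Otherwise the pathogenicity
    assertion carried by the variant decides, defaulting conservatively
    to VUS.
    """
    row = knowledge.get(record.gene)
    if record.consequence is Consequence.SYNONYMOUS:
        return ScreenStatus.VUS
    if record.consequence is Consequence.MISSENSE:
        if not record.clinvar.has_cancer_syndrome_association:
            return ScreenStatus.VUS
    elif record.consequence.is_truncating:
        if not phenotype_match or not row.truncation_is_mechanism:
            return ScreenStatus.VUS
    if record.clinvar.classification is Classification.PATHOGENIC:
        return ScreenStatus.PATHOGENIC
    if record.clinvar.classification is Classification.LIKELY_PATHOGENIC:
        return ScreenStatus.LIKELY_PATHOGENIC
    return ScreenStatus.VUS


def label_expectation(gene: Optional[str], knowledge: KnowledgeTable) -> Expectation:
    """Second-hit expectation from the gene's mesenchymal-tumor association."""
    assoc = knowledge.get(gene, warn=False).mesenchymal_association
    if assoc in (MesenchymalAssociation.KNOWN, MesenchymalAssociation.SUGGESTED):
        return Expectation.EXPECTED
    if assoc is MesenchymalAssociation.SEMI:
        return Expectation.SEMI_EXPECTED
    return Expectation.NOT_EXPECTED


def _actionability(
    gene: str, row: KnowledgeRow, case: Optional[CaseRecord]
) -> Actionability:
    if case is not None and gene in case.impact_overrides:
        return case.impact_overrides[gene]
    return (
        Actionability.CLINICAL_ACTION
        if row.surveillance_exists
        else Actionability.RISK_FACTOR
    )


# ---------------------------------------------------------------------------
# Reportability by inheritance mode
# ---------------------------------------------------------------------------

def reportability(
    results: Sequence[ScreenResult],
    knowledge: KnowledgeTable,
    case: Optional[CaseRecord] = None,
) -> list[ScreenResult]:
    """Decide per-gene reportability for one case's triaged results.

    Dominant (or unknown-inheritance) genes: any het or hom P/LP variant
    is reportable. Recessive genes: reportable only when homozygous or
    when >= 2 distinct het P/LP variants hit the same gene (flagged as
    potential compound heterozygosity; phasing is not attempted). A single
    het P/LP variant in a recessive gene is a carrier state, not a
    reportable finding.
    """
    plp_by_gene: dict[str, list[ScreenResult]] = defaultdict(list)
    for res in results:
        if res.status.is_reportable_class and res.record.gene:
            plp_by_gene[res.record.gene].append(res)

    out = []
    for res in results:
        if not (res.status.is_reportable_class and res.record.gene):
            out.append(res)
            continue
        gene = res.record.gene
        row = knowledge.get(gene, warn=False)
        siblings = plp_by_gene[gene]
        compound = False
        if row.inheritance is Inheritance.RECESSIVE:
            if res.record.genotype is Genotype.HOM:
                reportable = True
            elif len({s.record.key for s in siblings}) >= 2:
                reportable, compound = True, True
            else:
                reportable = False
        else:  # dominant or unknown
            reportable = True
        out.append(
            replace(
                res,
                reportable=reportable,
                inheritance_mode=row.inheritance,
                actionability=(
                    _actionability(gene, row, case)
                    if reportable
                    else Actionability.NONE
                ),
                expectation=label_expectation(gene, knowledge),
                compound_het=compound,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Whole-case / whole-cohort orchestration
# ---------------------------------------------------------------------------

def screen_case(
    records: Iterable[GermlineVariantRecord],
    panel: GenePanel,
    knowledge: KnowledgeTable,
    case: Optional[CaseRecord] = None,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[ScreenResult]:
    """Run the full screen (gates -> rules -> triage -> reportability)."""
    phenotype_genes = case.phenotype_genes if case is not None else frozenset()
    triaged: list[ScreenResult] = []
    for res in prefilter(records, panel, config):
        if res.status.is_excluded:
            triaged.append(res)
            continue
        rule_status = apply_exclusion_rules(res.record, config)
        if rule_status is not None:
            triaged.append(
                replace(res, status=rule_status,
                        rule_trace=res.rule_trace + (rule_status.value,))
            )
            continue
        gene = res.record.gene
        phenotype_match = (
            gene in phenotype_genes
            if phenotype_genes
            else label_expectation(gene, knowledge) is not Expectation.NOT_EXPECTED
        )
        status = triage(res.record, phenotype_match, knowledge)
        triaged.append(
            replace(res, status=status,
                    rule_trace=res.rule_trace + ("rules_ABC", "triage"))
        )
    return reportability(triaged, knowledge, case)


def reportable_genes(results: Sequence[ScreenResult]) -> dict[str, list[ScreenResult]]:
    """Genes with at least one reportable P/LP variant, with their results."""
    out: dict[str, list[ScreenResult]] = defaultdict(list)
    for res in results:
        if res.reportable and res.record.gene:
            out[res.record.gene].append(res)
    return dict(out)


def screen_cohort(
    records_by_case: Mapping[str, Sequence[GermlineVariantRecord]],
    panel: GenePanel,
    knowledge: KnowledgeTable,
    cases: Optional[Mapping[str, CaseRecord]] = None,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> dict[str, list[ScreenResult]]:
    cases = cases or {}
    return {
        case_id: screen_case(recs, panel, knowledge, cases.get(case_id), config)
        for case_id, recs in records_by_case.items()
    }
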