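"""Somatic second-hit detection.

For each gene carrying a pathogenic/likely-pathogenic germline first hit,
the tumor is searched across evidence layers:

* small variants — protein-altering or splice somatic SNVs/indels in the
  gene with VAF strictly above 5%;
* structural variants — gene-overlapping SV calls with VAF strictly above
  10%;
* copy number / allelic imbalance — gene-overlapping segments classified
  as focal deletion (copy number below the case's ploidy, with allelic
  imbalance) or copy-neutral LOH; chromothripsis-like chromosomes and
  very large deletions are uninformative and withhold evidence rather
  than create it;
* expression — the case's FPKM in the cohort's top or bottom 5th
  percentile (nearest-rank, ties in the tail) for that gene;
* methylation — mean promoter-window beta above the hypermethylation
  threshold, labelled consistent-with-biallelic when the locus is
  copy-neutral.

Tumor mutational burden (TMB) is computed from all quality-passing
somatic small variants (depth >= 10, VAF >= 0.05, gnomAD <= 0.1%)
divided by 3000 Mb; > 10/Mb is TMB-high.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import ThresholdConfig, DEFAULT_CONFIG
from .models import (
    CnSegment,
    EvidenceKind,
    Expectation,
    ExpressionMatrix,
    GeneInterval,
    MethylationTable,
    SecondHitVerdict,
    SomaticEvidence,
    SomaticVariant,
)

NO_DATA = "no_data"


# ---------------------------------------------------------------------------
# Small variants and structural variants
# ---------------------------------------------------------------------------

def find_snv_hit(
    somatic: Iterable[SomaticVariant],
    gene: str,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[SomaticEvidence]:
    """Qualifying somatic small variants in ``gene``, sorted by VAF descending.

    Protein-altering or splice consequences only; VAF strictly above
    ``snv_vaf_min``.
    """
    gene = gene.upper()
    hits = [
        v
        for v in somatic
        if not v.is_structural
        and v.gene == gene
        and v.consequence.is_protein_altering_or_splice
        and v.vaf > config.snv_vaf_min
    ]
    hits.sort(key=lambda v: -v.vaf)
    return [
        SomaticEvidence(
            kind=EvidenceKind.SNV_OR_INDEL,
            gene=gene,
            vaf=v.vaf,
            detail=f"{v.key} {v.consequence.value} VAF {v.vaf:.2f}",
        )
        for v in hits
    ]


def find_sv_hit(
    somatic: Iterable[SomaticVariant],
    gene_interval: GeneInterval,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[SomaticEvidence]:
    """Structural variants overlapping the gene with VAF > ``sv_vaf_min``."""
    hits = []
    for v in somatic:
        if not v.is_structural or v.vaf <= config.sv_vaf_min:
            continue
        sv_end = v.end if v.end is not None else v.key.pos + 1
        if v.key.chrom == gene_interval.chrom and (
            v.key.pos < gene_interval.end and gene_interval.start < sv_end
        ):
            hits.append(
                SomaticEvidence(
                    kind=EvidenceKind.STRUCTURAL_VARIANT,
                    gene=gene_interval.gene,
                    vaf=v.vaf,
                    detail=f"{v.svtype} {v.key.chrom}:{v.key.pos1}-{sv_end} "
                    f"VAF {v.vaf:.2f}",
                )
            )
    hits.sort(key=lambda e: -(e.vaf or 0))
    return hits


# ---------------------------------------------------------------------------
# Copy number / LOH
# ---------------------------------------------------------------------------

def chromothripsis_like(
    segments: Sequence[CnSegment],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> bool:
    """Oscillation heuristic: many copy-number state switches on one chromosome.

    The state of a segment is its rounded total copy number; a switch is a
    change of state between consecutive segments (sorted by start). True
    when the switch count reaches ``chromothripsis_min_switches``.
    """
    segs = sorted(segments, key=lambda s: s.start)
    states = [round(s.total_copy_number) for s in segs]
    switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
    return switches >= config.chromothripsis_min_switches


@dataclass(frozen=True)
class CnCall:
    """Outcome of copy-number / LOH assessment over a gene locus."""

    evidence: Optional[SomaticEvidence]  # None for 'none' and 'no data'
    no_data: bool = False
    copy_neutral: bool = False


def assess_cn_loh(
    segments: Sequence[CnSegment],
    gene_interval: GeneInterval,
    config: ThresholdConfig = DEFAULT_CONFIG,
    ploidy: float = 2.0,
    germline_tumor_vaf: Optional[float] = None,
) -> CnCall:
    """Classify the segment(s) overlapping a gene.

    Copy number below the case ploidy (beyond ``cn_neutral_tolerance``)
    with allelic imbalance is a focal deletion; copy-neutral imbalance is
    LOH. An overlapping segment longer than ``large_deletion_mb`` or a
    chromothripsis-like chromosome is uninformative. When the germline
    variant's allele fraction in the tumor is supplied, a fraction above
    0.5 marks the alternative allele as retained.

    A gene not covered by any segment yields an explicit no-data call.
    """
    overlapping = [
        s for s in segments
        if s.overlaps(gene_interval.chrom, gene_interval.start, gene_interval.end)
    ]
    if not overlapping:
        return CnCall(evidence=None, no_data=True)

    retained = None
    if germline_tumor_vaf is not None:
        retained = "alternative" if germline_tumor_vaf > 0.5 else "reference"

    chrom_segs = [s for s in segments if s.chrom == gene_interval.chrom]
    if chromothripsis_like(chrom_segs, config):
        return CnCall(
            evidence=SomaticEvidence(
                kind=EvidenceKind.UNINFORMATIVE_CHROMOTHRIPSIS,
                gene=gene_interval.gene,
                detail=f"chromothripsis-like profile on {gene_interval.chrom}",
            )
        )

    large_bp = config.large_deletion_mb * 1e6
    seg = min(overlapping, key=lambda s: s.total_copy_number)
    if seg.total_copy_number < ploidy - config.cn_neutral_tolerance and any(
        s.length > large_bp for s in overlapping
    ):
        return CnCall(
            evidence=SomaticEvidence(
                kind=EvidenceKind.UNINFORMATIVE_LARGE_DELETION,
                gene=gene_interval.gene,
                copy_number=seg.total_copy_number,
                detail=f"deleted segment of {seg.length / 1e6:.1f} Mb "
                "treated as non-focal",
            )
        )

    copy_neutral = abs(seg.total_copy_number - ploidy) <= config.cn_neutral_tolerance
    if seg.allelic_imbalance:
        if seg.total_copy_number < ploidy - config.cn_neutral_tolerance:
            return CnCall(
                evidence=SomaticEvidence(
                    kind=EvidenceKind.FOCAL_DELETION,
                    gene=gene_interval.gene,
                    copy_number=seg.total_copy_number,
                    retained_allele=retained,
                    detail=f"CN {seg.total_copy_number:.2f} vs ploidy "
                    f"{ploidy:.2f}, allelic imbalance",
                )
            )
        if copy_neutral:
            return CnCall(
                evidence=SomaticEvidence(
                    kind=EvidenceKind.LOH,
                    gene=gene_interval.gene,
                    copy_number=seg.total_copy_number,
                    retained_allele=retained,
                    detail="copy-neutral allelic imbalance",
                ),
                copy_neutral=True,
            )
    return CnCall(evidence=None, copy_neutral=copy_neutral)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: np.ndarray, percent: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    ordered = np.sort(np.asarray(values))
    n = len(ordered)
    k = max(1, math.ceil(percent / 100.0 * n))
    return float(ordered[k - 1])


class ExpressionNoData(Exception):
    """Raised when the expression cohort is too small to rank against."""


def expression_aberrant(
    matrix: ExpressionMatrix,
    gene: str,
    sample: str,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> Optional[SomaticEvidence]:
    """Flag extreme expression: top or bottom ``expr_tail_percent`` percentile.

    Tail membership is nearest-rank with ties included: a value at or
    below the low cut (resp. at or above the high cut) is aberrant.
    Returns None when unremarkable. A cohort below
    ``min_expression_cohort`` cannot be ranked against and raises
    :class:`ExpressionNoData` (an explicit no-data outcome, not "none").
    """
    if matrix.cohort_size < config.min_expression_cohort:
        raise ExpressionNoData(
            f"cohort of {matrix.cohort_size} below minimum "
            f"{config.min_expression_cohort}"
        )
    values = matrix.values_for_gene(gene)
    v = float(values[sample])
    arr = values.to_numpy(dtype=float)
    low_cut = nearest_rank_percentile(arr, config.expr_tail_percent)
    high_cut = -nearest_rank_percentile(-arr, config.expr_tail_percent)
    # percentile rank of the sample (fraction of cohort at or below it)
    pct_rank = 100.0 * float((arr <= v).sum()) / len(arr)
    if v <= low_cut:
        return SomaticEvidence(
            kind=EvidenceKind.EXPRESSION_LOW, gene=gene, percentile=pct_rank,
            detail=f"FPKM {v:.3g} at percentile {pct_rank:.1f}",
        )
    if v >= high_cut:
        return SomaticEvidence(
            kind=EvidenceKind.EXPRESSION_HIGH, gene=gene, percentile=pct_rank,
            detail=f"FPKM {v:.3g} at percentile {pct_rank:.1f}",
        )
    return None


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def methylation_hit(
    table: MethylationTable,
    gene: str,
    sample: str,
    config: ThresholdConfig = DEFAULT_CONFIG,
    copy_neutral: Optional[bool] = None,
) -> tuple[Optional[SomaticEvidence], bool]:
    """Promoter hypermethylation call: (evidence or None, no_data flag).

    Requires at least ``min_promoter_probes`` probes within the promoter
    window (TSS +/- ``promoter_window_bp``); the call fires when their
    mean beta reaches ``hypermethylation_beta_min``. The hit is labelled
    consistent-with-biallelic only when the locus shows no copy loss.
    """
    probes = table.promoter_probes(gene, sample, config.promoter_window_bp)
    if len(probes) < config.min_promoter_probes:
        return None, True
    mean_beta = float(probes["beta"].mean())
    if mean_beta >= config.hypermethylation_beta_min:
        return (
            SomaticEvidence(
                kind=EvidenceKind.PROMOTER_HYPERMETHYLATION,
                gene=gene,
                mean_beta=mean_beta,
                biallelic_consistent=bool(copy_neutral) if copy_neutral is not None else None,
                detail=f"mean promoter beta {mean_beta:.2f} over {len(probes)} probes",
            ),
            False,
        )
    return None, False


# ---------------------------------------------------------------------------
# Pathway expansion
# ---------------------------------------------------------------------------

def pathway_expansion(
    germline_gene: str,
    interactions: Mapping[str, Sequence[str]],
    somatic: Sequence[SomaticVariant],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> list[SomaticEvidence]:
    """Search associated (pathway / interacting) genes for qualifying SNVs.

    Results are labelled with the pathway gene and never upgrade the
    original gene's hit status.
    """
    gene = germline_gene.upper()
    if gene not in interactions:
        warnings.warn(f"gene {gene} absent from interaction table")
        return []
    out = []
    for partner in interactions[gene]:
        for ev in find_snv_hit(somatic, partner, config):
            out.append(
                SomaticEvidence(
                    kind=ev.kind, gene=gene, vaf=ev.vaf,
                    pathway_gene=partner.upper(),
                    detail=f"pathway gene {partner.upper()}: {ev.detail}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------

def compute_tmb(
    somatic: Iterable[SomaticVariant],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> tuple[float, bool]:
    """Tumor mutational burden per Mb and the TMB-high flag.

    Counts small variants with depth >= ``tmb_min_depth``, VAF >=
    ``tmb_min_af`` and population AF <= ``tmb_max_gnomad`` (missing AF
    counts as 0), divided by ``tmb_genome_mb``. High iff strictly above
    ``tmb_high``.
    """
    n = sum(
        1
        for v in somatic
        if not v.is_structural
        and v.depth >= config.tmb_min_depth
        and v.vaf >= config.tmb_min_af
        and v.af_for_filter <= config.tmb_max_gnomad
    )
    tmb = n / config.tmb_genome_mb
    return tmb, tmb > config.tmb_high


# ---------------------------------------------------------------------------
# Verdict integration
# ---------------------------------------------------------------------------

_NARRATIVE_ORDER = [
    EvidenceKind.SNV_OR_INDEL,
    EvidenceKind.FOCAL_DELETION,
    EvidenceKind.LOH,
    EvidenceKind.STRUCTURAL_VARIANT,
    EvidenceKind.EXPRESSION_LOW,
    EvidenceKind.EXPRESSION_HIGH,
    EvidenceKind.PROMOTER_HYPERMETHYLATION,
    EvidenceKind.UNINFORMATIVE_CHROMOTHRIPSIS,
    EvidenceKind.UNINFORMATIVE_LARGE_DELETION,
]


def integrate_verdict(
    case_id: str,
    gene: str,
    evidence: Sequence[SomaticEvidence],
    expectation: Expectation = Expectation.NOT_EXPECTED,
) -> SecondHitVerdict:
    """Combine per-layer evidence into one per-(case, gene) verdict.

    ``hit_found`` iff any positive (non-pathway) evidence is present.
    A verdict is uninformative only when uninformative copy-number
    findings are the sole evidence. The narrative lists evidence in the
    fixed priority order SNV -> deletion -> LOH -> SV -> expression ->
    methylation.
    """
    own = [e for e in evidence if e.pathway_gene is None]
    positive = [e for e in own if e.kind.is_positive]
    uninformative = [e for e in own if not e.kind.is_positive]
    hit_found = bool(positive)
    informative = hit_found or not uninformative

    ordered = sorted(
        evidence,
        key=lambda e: (_NARRATIVE_ORDER.index(e.kind), e.pathway_gene or ""),
    )
    if hit_found:
        narrative = "; ".join(
            f"{e.kind.value}: {e.detail}" for e in ordered if e.kind.is_positive
        )
    elif not informative:
        narrative = "uninformative: " + "; ".join(e.detail for e in uninformative)
    else:
        narrative = "no second hit"

    return SecondHitVerdict(
        case_id=case_id,
        gene=gene.upper(),
        hit_found=hit_found,
        evidence=tuple(ordered),
        informative=informative,
        expectation=expectation,
        narrative=narrative,
    )


# ---------------------------------------------------------------------------
# Per-case orchestration
# ---------------------------------------------------------------------------

@dataclass
class CaseOmics:
    """The tumor evidence bundle available for one case."""

    somatic: Sequence[SomaticVariant] = ()
    segments: Sequence[CnSegment] = ()
    expression: Optional[ExpressionMatrix] = None
    methylation: Optional[MethylationTable] = None
    sample_id: Optional[str] = None  # column/sample id in cohort tables
    germline_tumor_vaf: Mapping[str, float] | None = None  # gene -> VAF in tumor


def analyze_gene(
    case_id: str,
    gene: str,
    omics: CaseOmics,
    gene_map: Mapping[str, GeneInterval],
    expectation: Expectation = Expectation.NOT_EXPECTED,
    interactions: Optional[Mapping[str, Sequence[str]]] = None,
    config: ThresholdConfig = DEFAULT_CONFIG,
    ploidy: float = 2.0,
) -> SecondHitVerdict:
    """Run every evidence layer for one (case, gene) and integrate."""
    gene = gene.upper()
    evidence: list[SomaticEvidence] = []
    evidence += find_snv_hit(omics.somatic, gene, config)

    copy_neutral: Optional[bool] = None
    interval = gene_map.get(gene)
    if interval is not None:
        evidence += find_sv_hit(omics.somatic, interval, config)
        if omics.segments:
            gvaf = (omics.germline_tumor_vaf or {}).get(gene)
            call = assess_cn_loh(
                omics.segments, interval, config, ploidy=ploidy,
                germline_tumor_vaf=gvaf,
            )
            if call.evidence is not None:
                evidence.append(call.evidence)
            if not call.no_data:
                copy_neutral = call.copy_neutral

    sample = omics.sample_id or case_id
    if (
        omics.expression is not None
        and gene in omics.expression.df.index
        and sample in omics.expression.df.columns
        and omics.expression.cohort_size >= config.min_expression_cohort
    ):
        ev = expression_aberrant(omics.expression, gene, sample, config)
        if ev is not None:
            evidence.append(ev)

    if omics.methylation is not None:
        ev, _no_data = methylation_hit(
            omics.methylation, gene, sample, config, copy_neutral=copy_neutral
        )
        if ev is not None:
            evidence.append(ev)

    verdict = integrate_verdict(case_id, gene, evidence, expectation)

    # pathway expansion only augments the record for hitless, informative cases
    if interactions is not None and not verdict.hit_found:
        pathway_ev = pathway_expansion(gene, interactions, omics.somatic, config)
        if pathway_ev:
            verdict = SecondHitVerdict(
                case_id=verdict.case_id,
                gene=verdict.gene,
                hit_found=verdict.hit_found,
                evidence=verdict.evidence + tuple(pathway_ev),
                informative=verdict.informative,
                expectation=verdict.expectation,
                narrative=verdict.narrative
                + "; pathway-level: "
                + "; ".join(e.detail for e in pathway_ev),
            )
    return verdict
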