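"""Domain types shared across the pipeline.

All genomic intervals are stored internally as 0-based half-open
coordinates; VCF positions (1-based) are converted at the I/O boundary.
The genome build is carried as an opaque label and never verified against
a reference sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ValidationError


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Classification(str, Enum):
    """ClinVar-style summary classification of a variant."""

    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"
    CONFLICTING = "conflicting"
    NONE = "none"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER_EXONIC = "other_exonic"
    NON_CODING = "non_coding"

    @property
    def is_coding(self) -> bool:
        """Exonic or splicing, i.e. survives the coding gate."""
        return self is not Consequence.NON_CODING

    @property
    def is_truncating(self) -> bool:
        """Potentially truncating: nonsense, frameshift or splice site."""
        return self in (
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
            Consequence.SPLICE_SITE,
        )

    @property
    def is_protein_altering_or_splice(self) -> bool:
        return self in (
            Consequence.MISSENSE,
            Consequence.NONSENSE,
            Consequence.FRAMESHIFT,
            Consequence.SPLICE_SITE,
            Consequence.OTHER_EXONIC,
        )


class Genotype(str, Enum):
    HET = "het"
    HOM = "hom"


class ScreenStatus(str, Enum):
    EXCLUDED_PANEL = "excluded_panel"
    EXCLUDED_NONCODING = "excluded_noncoding"
    EXCLUDED_FREQUENCY = "excluded_frequency"
    EXCLUDED_RULE_A = "excluded_rule_A"
    EXCLUDED_RULE_B = "excluded_rule_B"
    EXCLUDED_RULE_C = "excluded_rule_C"
    VUS = "vus"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"

    @property
    def is_excluded(self) -> bool:
        return self.value.startswith("excluded")

    @property
    def is_reportable_class(self) -> bool:
        return self in (ScreenStatus.LIKELY_PATHOGENIC, ScreenStatus.PATHOGENIC)


class Inheritance(str, Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"


class Actionability(str, Enum):
    CLINICAL_ACTION = "clinical_action"
    RISK_FACTOR = "risk_factor"
    NONE = "none"


class Expectation(str, Enum):
    """Whether a somatic second hit is anticipated for a germline-hit gene."""

    EXPECTED = "second_hit_expected"
    SEMI_EXPECTED = "semi_expected"
    NOT_EXPECTED = "second_hit_not_expected"


class MesenchymalAssociation(str, Enum):
    KNOWN = "known"
    SUGGESTED = "suggested"
    SEMI = "semi"
    NONE = "none"


class EvidenceKind(str, Enum):
    SNV_OR_INDEL = "snv_or_indel"
    STRUCTURAL_VARIANT = "structural_variant"
    FOCAL_DELETION = "focal_deletion"
    LOH = "loh"
    EXPRESSION_LOW = "expression_low"
    EXPRESSION_HIGH = "expression_high"
    PROMOTER_HYPERMETHYLATION = "promoter_hypermethylation"
    UNINFORMATIVE_CHROMOTHRIPSIS = "uninformative_chromothripsis"
    UNINFORMATIVE_LARGE_DELETION = "uninformative_large_deletion"

    @property
    def is_positive(self) -> bool:
        """True for evidence kinds that count as a second hit."""
        return self not in (
            EvidenceKind.UNINFORMATIVE_CHROMOTHRIPSIS,
            EvidenceKind.UNINFORMATIVE_LARGE_DELETION,
        )


class DiagnosisCategory(str, Enum):
    SOFT_TISSUE_SARCOMA_HIGH = "soft_tissue_sarcoma_high"
    SOFT_TISSUE_SARCOMA_LOW = "soft_tissue_sarcoma_low"
    SOFT_TISSUE_BENIGN = "soft_tissue_benign"
    BONE_SARCOMA_HIGH = "bone_sarcoma_high"
    BONE_SARCOMA_LOW = "bone_sarcoma_low"
    BONE_BENIGN = "bone_benign"
    GIST = "gist"
    GYNAECOLOGICAL_TRACT = "gynaecological_tract"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


# ---------------------------------------------------------------------------
# Variant-level records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a small variant. ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    build: str = "unknown"

    @property
    def pos1(self) -> int:
        """1-based position as printed in VCF."""
        return self.pos + 1

    def __str__(self) -> str:  # chrom:pos1 ref>alt, the human-facing form
        return f"{self.chrom}:{self.pos1}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ClinVarAssertion:
    """Summary of ClinVar submissions for one variant.

    ``benign_submitters`` counts submitters asserting benign or likely
    benign; a classification of ``none`` (no ClinVar entry) implies zero.
    """

    classification: Classification = Classification.NONE
    benign_submitters: int = 0
    has_cancer_syndrome_association: bool = False

    def __post_init__(self) -> None:
        if self.benign_submitters < 0:
            raise ValidationError("benign_submitters must be >= 0")
        if self.classification is Classification.NONE and self.benign_submitters != 0:
            raise ValidationError(
                "classification 'none' implies zero benign submitters"
            )


@dataclass(frozen=True)
class LocalDbCount:
    """Occurrence count of a variant in the local assertion database."""

    key: VariantKey
    occurrence_count: int
    database_size: int = 9244

    def __post_init__(self) -> None:
        if not (0 <= self.occurrence_count <= 2 * self.database_size):
            raise ValidationError(
                f"occurrence_count {self.occurrence_count} outside "
                f"[0, {2 * self.database_size}] for {self.key}"
            )


@dataclass(frozen=True)
class GermlineVariantRecord:
    """One annotated small variant observed in blood."""

    case_id: str
    key: VariantKey
    gene: Optional[str]
    consequence: Consequence
    genotype: Genotype
    population_af: Optional[float]  # missing stored as None, compared as 0
    clinvar: ClinVarAssertion = field(default_factory=ClinVarAssertion)
    local_count: int = 0

    @property
    def af_for_filter(self) -> float:
        """Population AF as used by the frequency gate (missing -> 0)."""
        return 0.0 if self.population_af is None else self.population_af


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic small variant or structural variant call in the tumor."""

    case_id: str
    key: VariantKey
    gene: Optional[str]
    consequence: Consequence
    vaf: float
    depth: int
    population_af: Optional[float] = None
    filter_pass: bool = True
    is_structural: bool = False
    svtype: Optional[str] = None
    end: Optional[int] = None  # 0-based half-open end for SVs

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"VAF {self.vaf} outside [0, 1] for {self.key}")

    @property
    def af_for_filter(self) -> float:
        return 0.0 if self.population_af is None else self.population_af


# ---------------------------------------------------------------------------
# Intervals and segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnSegment:
    """A copy-number / allelic-imbalance segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    total_copy_number: float
    allelic_imbalance: bool
    minor_allele_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.total_copy_number < 0:
            raise ValidationError("total_copy_number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def validate_segments(segments: Iterable[CnSegment]) -> None:
    """Check per-chromosome non-overlap (after sorting)."""
    by_chrom: dict[str, list[CnSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------

class GenePanel:
    """A hereditary-cancer gene panel: a set of symbols plus a version label.

    Symbols are upper-cased on construction; membership tests are
    case-sensitive after that normalization.
    """

    def __init__(self, genes: Iterable[str], version_label: str = "unversioned"):
        normalized = [g.strip().upper() for g in genes if g and g.strip()]
        if not normalized:
            raise ValidationError("gene panel must be non-empty")
        if len(set(normalized)) < len(normalized):
            dupes = sorted({g for g in normalized if normalized.count(g) > 1})
            warnings.warn(f"duplicate panel symbols deduplicated: {dupes}")
        self.genes: frozenset[str] = frozenset(normalized)
        self.version_label = version_label

    def __contains__(self, gene: Optional[str]) -> bool:
        if gene is None:
            return False
        return gene.strip().upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:
        return f"GenePanel({len(self.genes)} genes, {self.version_label!r})"


class ExpressionMatrix:
    """Cohort FPKM matrix, genes x samples."""

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if (df.values < 0).any():
            raise ValidationError("FPKM values must be >= 0")
        df = df.copy()
        df.index.name = "gene"
        self.df = df

    @property
    def cohort_size(self) -> int:
        return self.df.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def values_for_gene(self, gene: str) -> pd.Series:
        return self.df.loc[gene]


class MethylationTable:
    """Long-format methylation probe table.

    Columns: probe, gene, dist_tss (signed bp to TSS), beta in [0, 1],
    sample.
    """

    COLUMNS = ("probe", "gene", "dist_tss", "beta", "sample")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"methylation table missing columns: {missing}")
        bad = df.index[(df["beta"] < 0) | (df["beta"] > 1)]
        if len(bad):
            raise ValidationError(
                f"beta outside [0, 1] at row(s) {list(bad[:5])}"
            )
        self.df = df.reset_index(drop=True)

    def promoter_probes(
        self, gene: str, sample: str, window_bp: int
    ) -> pd.DataFrame:
        d = self.df
        m = (
            (d["gene"] == gene)
            & (d["sample"] == sample)
            & (d["dist_tss"].abs() <= window_bp)
        )
        return d[m]


@dataclass(frozen=True)
class KnowledgeRow:
    """Per-gene clinical knowledge driving triage and expectation labels."""

    gene: str
    syndrome: str = "unknown"
    inheritance: Inheritance = Inheritance.UNKNOWN
    truncation_is_mechanism: bool = False
    mesenchymal_association: MesenchymalAssociation = MesenchymalAssociation.NONE
    surveillance_exists: bool = False


DEFAULT_KNOWLEDGE_ROW = KnowledgeRow(gene="__default__")


class KnowledgeTable:
    """Gene -> syndrome knowledge; unknown genes fall back to a default row."""

    def __init__(self, rows: Iterable[KnowledgeRow]):
        self.rows: dict[str, KnowledgeRow] = {r.gene.upper(): r for r in rows}

    def get(self, gene: Optional[str], warn: bool = True) -> KnowledgeRow:
        if gene is not None and gene.upper() in self.rows:
            return self.rows[gene.upper()]
        if warn:
            warnings.warn(f"gene {gene!r} absent from knowledge table; using default")
        return DEFAULT_KNOWLEDGE_ROW

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.rows

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Screening / second-hit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Per-variant outcome of the germline screen."""

    record: GermlineVariantRecord
    status: ScreenStatus
    inheritance_mode: Inheritance = Inheritance.UNKNOWN
    reportable: bool = False
    actionability: Actionability = Actionability.NONE
    expectation: Expectation = Expectation.NOT_EXPECTED
    rule_trace: tuple[str, ...] = ()
    compound_het: bool = False

    def __post_init__(self) -> None:
        if self.reportable and not self.status.is_reportable_class:
            raise ValidationError("reportable requires a P/LP status")


@dataclass(frozen=True)
class SomaticEvidence:
    """One tumor observation usable as (or withholding) a second hit."""

    kind: EvidenceKind
    gene: str
    vaf: Optional[float] = None
    copy_number: Optional[float] = None
    percentile: Optional[float] = None
    mean_beta: Optional[float] = None
    retained_allele: Optional[str] = None  # "alternative" | "reference"
    biallelic_consistent: Optional[bool] = None
    pathway_gene: Optional[str] = None  # set when found via pathway expansion
    detail: str = ""


@dataclass(frozen=True)
class SecondHitVerdict:
    """Integrated per-(case, gene) second-hit conclusion."""

    case_id: str
    gene: str
    hit_found: bool
    evidence: tuple[SomaticEvidence, ...]
    informative: bool
    expectation: Expectation
    narrative: str

    def __post_init__(self) -> None:
        if self.hit_found and not self.evidence:
            raise ValidationError("hit_found requires non-empty evidence")
        if not self.informative and self.hit_found:
            raise ValidationError("uninformative verdicts cannot carry a hit")


# ---------------------------------------------------------------------------
# Case metadata
# ---------------------------------------------------------------------------

@dataclass
class CaseRecord:
    """One patient: identifiers, diagnosis, clinical metadata, evidence."""

    case_id: str
    diagnosis: str
    category: Optional[DiagnosisCategory] = None
    malignant: bool = True
    sex: Optional[Sex] = None
    age: Optional[float] = None
    radiotherapy: bool = False
    chemotherapy: bool = False
    ploidy: float = 2.0
    # genes whose associated syndrome matches this patient's phenotype
    phenotype_genes: frozenset[str] = frozenset()
    # manual clinical decision overriding the per-gene actionability default
    impact_overrides: Mapping[str, Actionability] = field(default_factory=dict)
    no_tumor_tissue: bool = False
    germline_finding: bool = False
    verdicts: list[SecondHitVerdict] = field(default_factory=list)
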