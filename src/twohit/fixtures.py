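"""Study fixtures: the 24 carrier cases and the cohort category table.

The per-case table (24 patients with a potentially disease-causing
germline variant) is encoded verbatim: diagnosis, gene, transcript, HGVS
notation, clinical impact, syndrome-criteria flag and the second-hit
description. From it the module derives machine-readable inputs that
exercise the real pipeline code paths:

* germline variant records (synthetic coordinates on the package's
  miniature gene map — the patients' true coordinates are not public);
* per-case tumor evidence bundles (somatic variants / copy-number
  segments) constructed so the second-hit engine reproduces the printed
  second-hit column. These bundles are reconstructions sufficient to
  reproduce the printed verdicts, not the patients' data.

The 312-case cohort reconstruction adds 288 background cases matching
the published category table (column sums 288 and 24). The published
material states 63 benign tumors overall and 3 of the 24 carriers are
benign, so 60 background cases must be benign; the explicitly benign
background categories sum to 45 and the remaining 15 are placed in the
gynaecological-tract category as benign uterine leiomyomas (synthetic
assignment — the publication does not break malignancy down by
category).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import ThresholdConfig, DEFAULT_CONFIG
from .models import (
    Actionability,
    CaseRecord,
    Classification,
    ClinVarAssertion,
    CnSegment,
    Consequence,
    DiagnosisCategory,
    GermlineVariantRecord,
    Genotype,
    ScreenResult,
    SecondHitVerdict,
    VariantKey,
)
from .germline import label_expectation, screen_case
from .resources import default_gene_map, default_knowledge, default_panel
from .somatic import CaseOmics, analyze_gene
from .models import SomaticVariant

_C = DiagnosisCategory
_ACT = Actionability.CLINICAL_ACTION
_RISK = Actionability.RISK_FACTOR


@dataclass(frozen=True)
class CarrierCaseRow:
    """One printed carrier case, plus derived machine-readable fields."""

    case_no: int
    diagnosis: str
    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str
    clinical_impact: Actionability
    pedigree: str
    prior_treatment: str
    comorbidity: str
    syndrome_known: bool
    fulfils_criteria: bool
    second_hit: str          # printed description
    # derived (not printed): consequence class, category, malignancy,
    # machine-readable second-hit kind
    consequence: Consequence
    category: DiagnosisCategory
    malignant: bool
    second_hit_kind: str     # "snv" | "deletion" | "none" | "na"
    somatic_consequence: Optional[Consequence] = None
    somatic_hgvs: str = ""


_MIS = Consequence.MISSENSE
_NON = Consequence.NONSENSE
_FS = Consequence.FRAMESHIFT
_SPL = Consequence.SPLICE_SITE

CARRIER_CASES: tuple[CarrierCaseRow, ...] = (
    CarrierCaseRow(40, "Leiomyoma", "BRCA1", "NM_007294", "c.406del",
              "p.Arg136AspfsTer27", _ACT, "No known cancer", "No", "OvC 55 y",
              True, True, "No second hit",
              _FS, _C.GYNAECOLOGICAL_TRACT, False, "none"),
    CarrierCaseRow(52, "Osteosarcoma, parosteal", "FLCN", "NM_144606", "c.779+1G>T",
              "", _ACT, "No known cancer", "No", "No",
              False, False, "No second hit",
              _SPL, _C.BONE_SARCOMA_LOW, True, "none"),
    CarrierCaseRow(62, "GIST", "SDHAF2", "NM_017841", "c.37-1G>C",
              "", _RISK, "No known cancer", "No", "HT",
              False, False, "No second hit",
              _SPL, _C.GIST, True, "none"),
    CarrierCaseRow(63, "GIST, wild-type", "SDHA", "NM_004168", "c.223C>T",
              "p.Arg75Ter", _ACT, "No known cancer", "No", "DCMP, dementia",
              False, False,
              "SNV: SDHA, NM_004168, c.896G>A, p.Gly299Asp",
              _NON, _C.GIST, True, "snv", _MIS, "c.896G>A p.Gly299Asp"),
    CarrierCaseRow(67, "Angiosarcoma", "ATM", "NM_000051", "c.7570G>C",
              "p.Ala2524Pro", _RISK, "No known cancer", "No", "HT",
              False, False,
              "SNV: ATM, NM_000051, c.5188C>T, p.Arg1730Ter",
              _MIS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "snv", _NON,
              "c.5188C>T p.Arg1730Ter"),
    CarrierCaseRow(76, "Pleomorphic liposarcoma", "MLH1", "NM_000249", "c.546-2A>G",
              "", _ACT, "No known cancer", "No", "CRC 52 y, kidney failure, HT",
              False, False, "Deletion MLH1",
              _SPL, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "deletion"),
    CarrierCaseRow(95, "Liposarcoma, dedifferentiated", "CHEK2", "NM_001005735",
              "c.1229del", "p.Thr410MetfsTer15", _ACT, "No known cancer",
              "RT, chemo breast", "BrC 65, HT",
              False, False, "No second hit",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "none"),
    CarrierCaseRow(101, "Leiomyosarcoma", "RB1", "NM_000321", "c.1981C>T",
              "p.Arg661Trp", _ACT,
              "Brother's son suspected RB 4y, mother UtC 50y.", "No", "No",
              False, False, "Deletion RB1",
              _MIS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "deletion"),
    CarrierCaseRow(111, "Leiomyosarcoma", "RB1", "NM_000321", "c.184C>T",
              "p.Gln62Ter", _ACT, "No known cancer", "RT OS",
              "RB bilateral 6 months, OS legs multiple during childhood, "
              "endometriosis",
              True, True, "Deletion RB1",
              _NON, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "deletion"),
    CarrierCaseRow(115, "Adenosarcoma, sarcomatous overgrowth", "CDC73",
              "NM_024529", "c.664C>T", "p.Arg222Ter", _ACT,
              "Mother and sister LuC", "No", "Hypothyreosis, lung embolus",
              False, False,
              "SNV: CDC73, NM_024529, c.25C>T, p.Arg9Ter",
              _NON, _C.GYNAECOLOGICAL_TRACT, True, "snv", _NON,
              "c.25C>T p.Arg9Ter"),
    CarrierCaseRow(139, "Radiation-induced sarcoma", "MSH6", "NM_000179",
              "c.2851_2858del", "p.Leu951IlefsTer12", _ACT,
              "Mother OvC, son testis cancer, daughter BC, daughter CxC",
              "RT, chemo breast", "BrC 44 y, UtC 48 y",
              True, True, "No verified second hit",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "none"),
    CarrierCaseRow(144, "GIST", "MITF", "NM_198159", "c.1255G>A", "p.Glu419Lys",
              _RISK, "No known cancer", "No", "UtC 75",
              False, False, "No second hit",
              _MIS, _C.GIST, True, "none"),
    CarrierCaseRow(168, "MPNST", "NF1", "NM_000267", "c.1721+3A>C", "", _ACT,
              "Sister brain tumor", "No", "GIST small intestine",
              True, True,
              "SNV: NF1, NM_000267, c.565A>T, p.Lys189Ter",
              _SPL, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "snv", _NON,
              "c.565A>T p.Lys189Ter"),
    CarrierCaseRow(207, "DFSP, fibrosarcoma", "EXT1", "NM_000127", "c.1018C>T",
              "p.Arg340Cys", _RISK, "No known cancer", "No", "No",
              False, False, "No second hit",
              _MIS, _C.SOFT_TISSUE_SARCOMA_LOW, True, "none"),
    CarrierCaseRow(208, "Leiomyosarcoma", "TP53", "NM_001126112", "c.503del",
              "p.His168ProfsTer2", _ACT, "No known cancer", "Interferone",
              "OS 16 y, LMS 35 y",
              False, True, "Deletion TP53",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "deletion"),
    CarrierCaseRow(231, "Liposarcoma (DDLPS)", "ATR", "NM_001184", "c.6836dup",
              "p.Asn2279LysfsTer4", _RISK, "No known cancer", "No", "No",
              False, False, "No second hit",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "none"),
    CarrierCaseRow(265, "Leiomyoma", "MRE11", "NM_005591", "c.1090C>T",
              "p.Arg364Ter", _RISK, "No known cancer", "No", "No",
              False, False, "No second hit",
              _NON, _C.GYNAECOLOGICAL_TRACT, False, "none"),
    CarrierCaseRow(295, "Secondary peripheral chondrosarcoma", "EXT2", "NM_000401",
              "c.441C>G", "p.Tyr147Ter", _ACT, "No known cancer", "No", "CHS",
              True, True, "Deletion EXT2",
              _NON, _C.BONE_SARCOMA_LOW, True, "deletion"),
    CarrierCaseRow(306, "MPNST", "NF1", "NM_000267", "c.4974_4977del",
              "p.Tyr1659ThrfsTer17", _ACT, "No known cancer", "RT brain",
              "Intracranial sarcoma 23 y, Scwannoma 24 y, Cafe-au-lait spots",
              True, True,
              "SNV: NF1, NM_000267, c.365_371del, p.His122LeufsTer41",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "snv", _FS,
              "c.365_371del p.His122LeufsTer41"),
    CarrierCaseRow(311, "Synovial chondromatosis", "CHEK2", "NM_001005735",
              "c.1229del", "p.Thr410MetfsTer15", _ACT, "Sister breast cancer",
              "RT, chemo breast, Tamoxifene", "BrC 59 y",
              False, True, "No second hit",
              _FS, _C.SOFT_TISSUE_BENIGN, False, "none"),
    CarrierCaseRow(329, "Low-grade parosteal OS", "CHEK2", "NM_001005735",
              "c.1229del", "p.Thr410MetfsTer15", _RISK, "No known cancer",
              "No", "No",
              False, False, "No second hit",
              _FS, _C.BONE_SARCOMA_LOW, True, "none"),
    CarrierCaseRow(339, "Soft tissue sarcoma paravertebral", "MSH6", "NM_000179",
              "c.3261del", "p.Phe1088SerfsTer2", _ACT,
              "Sister OvC, mother BC 59y + UrC 59y + CRC 67y + UtC 53y, "
              "maternal grandmother UtC", "Chemo", "CRC 54 y",
              True, True, "NA",
              _FS, _C.SOFT_TISSUE_SARCOMA_HIGH, True, "na"),
    CarrierCaseRow(353, "Leiomyosarcoma", "DDX41", "NM_016222", "c.415_418dup",
              "p.Asp140GlyfsTer2", _RISK, "Father CRC", "RT, chemo kidney",
              "Wilm's tumor kidney and lung, cholecystectomy, myoma",
              False, False, "No second hit",
              _FS, _C.GYNAECOLOGICAL_TRACT, True, "none"),
    CarrierCaseRow(364, "GIST, wild-type", "NF1", "NM_000267", "c.6792C>A",
              "p.Tyr2264Ter", _ACT,
              "Son molecularly verified NF1, no known cancer.", "No",
              "Cafe-au-lait spots",
              True, True,
              "SNV: NF1, NM_000267, c.3723_3730dup, p.Val1244GlufsTer25",
              _NON, _C.GIST, True, "snv", _FS,
              "c.3723_3730dup p.Val1244GlufsTer25"),
)


def carrier_table_fixture() -> tuple[CarrierCaseRow, ...]:
    """The 24 printed carrier cases."""
    assert len(CARRIER_CASES) == 24
    return CARRIER_CASES


# ---------------------------------------------------------------------------
# Published diagnosis-category counts (verbatim)
# ---------------------------------------------------------------------------

_CATEGORY_COUNTS = [
    # label, no-finding n, no-finding %, finding n, finding %
    ("Soft tissue sarcoma, high-grade", 120, 42, 11, 46),
    ("Soft tissue sarcoma, low-grade", 33, 11, 1, 4),
    ("Soft tissue, benign", 40, 14, 1, 4),
    ("Bone sarcoma, high-grade", 13, 5, 0, 0),
    ("Bone sarcoma, low-grade", 7, 2, 3, 13),
    ("Bone, benign", 5, 2, 0, 0),
    ("GIST", 36, 13, 4, 17),
    ("Gynaecological tract", 34, 12, 4, 17),
]


def category_counts_fixture() -> pd.DataFrame:
    """The printed 8 x 2 category count table (column sums 288 and 24)."""
    df = pd.DataFrame(
        _CATEGORY_COUNTS,
        columns=["category", "no_finding_n", "no_finding_pct",
                 "finding_n", "finding_pct"],
    ).set_index("category")
    assert int(df["no_finding_n"].sum()) == 288
    assert int(df["finding_n"].sum()) == 24
    return df


_CATEGORY_BY_LABEL = {
    "Soft tissue sarcoma, high-grade": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "Soft tissue sarcoma, low-grade": _C.SOFT_TISSUE_SARCOMA_LOW,
    "Soft tissue, benign": _C.SOFT_TISSUE_BENIGN,
    "Bone sarcoma, high-grade": _C.BONE_SARCOMA_HIGH,
    "Bone sarcoma, low-grade": _C.BONE_SARCOMA_LOW,
    "Bone, benign": _C.BONE_BENIGN,
    "GIST": _C.GIST,
    "Gynaecological tract": _C.GYNAECOLOGICAL_TRACT,
}

_BENIGN_CATEGORIES = {_C.SOFT_TISSUE_BENIGN, _C.BONE_BENIGN}
# benign uterine leiomyomas among the gynaecological-tract background cases
# (synthetic reconstruction; see module docstring)
_N_BENIGN_GYN_BACKGROUND = 15


# ---------------------------------------------------------------------------
# Machine-readable carrier cases and evidence bundles
# ---------------------------------------------------------------------------

def _germline_record(row: CarrierCaseRow) -> GermlineVariantRecord:
    """Carrier germline variant on synthetic coordinates (gene start + 500)."""
    interval = default_gene_map()[row.gene]
    return GermlineVariantRecord(
        case_id=str(row.case_no),
        key=VariantKey(interval.chrom, interval.start + 500, "C", "T",
                       build="synthetic-mini"),
        gene=row.gene,
        consequence=row.consequence,
        genotype=Genotype.HET,
        population_af=None,
        clinvar=ClinVarAssertion(
            classification=Classification.PATHOGENIC,
            benign_submitters=0,
            has_cancer_syndrome_association=True,
        ),
        local_count=0,
    )


def fixture_germline_records() -> dict[str, list[GermlineVariantRecord]]:
    """Per-case germline records for the 24 carriers."""
    return {str(r.case_no): [_germline_record(r)] for r in CARRIER_CASES}


def fixture_case_record(row: CarrierCaseRow) -> CaseRecord:
    overrides = {}
    # one printed impact differs from the gene's surveillance default:
    # the third c.1229del carrier lacked the family criteria for follow-up
    if row.case_no == 329:
        overrides["CHEK2"] = Actionability.RISK_FACTOR
    return CaseRecord(
        case_id=str(row.case_no),
        diagnosis=row.diagnosis,
        category=row.category,
        malignant=row.malignant,
        radiotherapy="RT" in row.prior_treatment,
        chemotherapy="chemo" in row.prior_treatment.lower(),
        phenotype_genes=frozenset({row.gene}),
        impact_overrides=overrides,
        no_tumor_tissue=(row.second_hit_kind == "na"),
        germline_finding=True,
    )


def fixture_omics(row: CarrierCaseRow) -> CaseOmics:
    """Tumor evidence bundle reproducing the printed second-hit column.

    SNV hits become qualifying somatic variants (VAF 0.40, depth 100);
    deletions become a gene-overlapping segment at copy number 1 with
    allelic imbalance (the germline allele fraction in the tumor is set
    high, marking retention of the alternative allele); hitless cases get
    a copy-neutral segment so the copy-number layer is informative; the
    no-tumor-tissue case gets an empty bundle. The unverified-second-hit
    case carries a candidate below the VAF threshold, which the engine
    must reject.
    """
    gene_map = default_gene_map()
    interval = gene_map[row.gene]
    case_id = str(row.case_no)
    somatic: list[SomaticVariant] = []
    segments: list[CnSegment] = []
    germline_tumor_vaf: dict[str, float] = {}

    if row.second_hit_kind == "na":
        return CaseOmics()

    if row.second_hit_kind == "snv":
        somatic.append(
            SomaticVariant(
                case_id=case_id,
                key=VariantKey(interval.chrom, interval.start + 1000, "G", "A",
                               build="synthetic-mini"),
                gene=row.gene,
                consequence=row.somatic_consequence or Consequence.NONSENSE,
                vaf=0.40,
                depth=100,
                population_af=None,
            )
        )
        segments.append(
            CnSegment(interval.chrom, interval.start - 1_000_000,
                      interval.end + 1_000_000, 2.0, False)
        )
    elif row.second_hit_kind == "deletion":
        segments.append(
            CnSegment(interval.chrom, interval.start - 1_000_000,
                      interval.end + 1_000_000, 1.0, True)
        )
        germline_tumor_vaf[row.gene] = 0.85
    else:  # "none": copy-neutral locus, no qualifying somatic events
        segments.append(
            CnSegment(interval.chrom, interval.start - 1_000_000,
                      interval.end + 1_000_000, 2.0, False)
        )
        if row.case_no == 139:  # candidate below the 5% VAF threshold
            somatic.append(
                SomaticVariant(
                    case_id=case_id,
                    key=VariantKey(interval.chrom, interval.start + 1200,
                                   "A", "G", build="synthetic-mini"),
                    gene=row.gene,
                    consequence=Consequence.MISSENSE,
                    vaf=0.04,
                    depth=80,
                    population_af=None,
                )
            )
    return CaseOmics(
        somatic=somatic,
        segments=segments,
        germline_tumor_vaf=germline_tumor_vaf or None,
    )


# ---------------------------------------------------------------------------
# Full pipeline over the fixtures
# ---------------------------------------------------------------------------

def run_fixture_screen(
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> dict[str, list[ScreenResult]]:
    """Run the germline screen on all 24 carrier cases."""
    panel = default_panel()
    knowledge = default_knowledge()
    out = {}
    for row in CARRIER_CASES:
        case = fixture_case_record(row)
        out[case.case_id] = screen_case(
            [_germline_record(row)], panel, knowledge, case, config
        )
    return out


def run_fixture_secondhit(
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> dict[str, SecondHitVerdict]:
    """Run the second-hit engine on every carrier's evidence bundle."""
    gene_map = default_gene_map()
    knowledge = default_knowledge()
    out = {}
    for row in CARRIER_CASES:
        omics = fixture_omics(row)
        verdict = analyze_gene(
            case_id=str(row.case_no),
            gene=row.gene,
            omics=omics,
            gene_map=gene_map,
            expectation=label_expectation(row.gene, knowledge),
            config=config,
        )
        out[str(row.case_no)] = verdict
    return out


def fixture_cohort() -> list[CaseRecord]:
    """The reconstructed 312-case cohort: 24 carriers + 288 background cases.

    Background cases follow the published category counts; benignity is
    assigned so the cohort holds 63 benign tumors in total (45 in the
    explicitly benign categories, 15 benign uterine leiomyomas in the
    gynaecological-tract category, plus the 3 benign carriers).
    """
    verdicts = run_fixture_secondhit()
    cases = []
    for row in CARRIER_CASES:
        case = fixture_case_record(row)
        case.verdicts = [verdicts[case.case_id]]
        cases.append(case)
    i = 0
    for label, n_no, _pct, _n_yes, _pct2 in _CATEGORY_COUNTS:
        cat = _CATEGORY_BY_LABEL[label]
        n_benign_gyn = (
            _N_BENIGN_GYN_BACKGROUND if cat is _C.GYNAECOLOGICAL_TRACT else 0
        )
        for j in range(n_no):
            benign = cat in _BENIGN_CATEGORIES or j < n_benign_gyn
            cases.append(
                CaseRecord(
                    case_id=f"bg{i:03d}",
                    diagnosis=label,
                    category=cat,
                    malignant=not benign,
                    germline_finding=False,
                )
            )
            i += 1
    assert len(cases) == 312
    assert sum(1 for c in cases if not c.malignant) == 63
    return cases
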