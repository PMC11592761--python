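"""Built-in reference tables.

The published 787-gene panel composition is not public, so the package
ships a documented stand-in panel (hereditary-cancer genes relevant to
mesenchymal tumors plus common panel genes) and accepts any user list.
The knowledge table encodes per-gene syndrome, inheritance mode, whether
truncation is the disease mechanism, the strength of the gene's
association with mesenchymal tumors (driving the second-hit expectation
label), and whether a surveillance programme exists (driving the default
actionability). The miniature gene map places panel genes on a synthetic
desk-scale genome; no real reference coordinates are shipped.
"""

from __future__ import annotations

from .models import (
    DiagnosisCategory,
    GeneInterval,
    GenePanel,
    Inheritance,
    KnowledgeRow,
    KnowledgeTable,
    MesenchymalAssociation,
)

_DOM = Inheritance.DOMINANT
_REC = Inheritance.RECESSIVE
_KNOWN = MesenchymalAssociation.KNOWN
_SUGG = MesenchymalAssociation.SUGGESTED
_SEMI = MesenchymalAssociation.SEMI
_NONE = MesenchymalAssociation.NONE

# gene, syndrome, inheritance, truncation_is_mechanism, mesenchymal, surveillance
_KNOWLEDGE = [
    ("NF1", "Neurofibromatosis type 1", _DOM, True, _KNOWN, True),
    ("RB1", "Hereditary retinoblastoma", _DOM, True, _KNOWN, True),
    ("TP53", "Heritable TP53-related cancer syndrome", _DOM, True, _KNOWN, True),
    ("EXT1", "Multiple osteochondromas", _DOM, True, _KNOWN, False),
    ("EXT2", "Multiple osteochondromas", _DOM, True, _KNOWN, True),
    ("SDHA", "Hereditary PGL/GIST (SDH-deficient)", _DOM, True, _KNOWN, True),
    ("SDHB", "Hereditary PGL/GIST (SDH-deficient)", _DOM, True, _KNOWN, True),
    ("SDHC", "Hereditary PGL/GIST (SDH-deficient)", _DOM, True, _KNOWN, True),
    ("SDHD", "Hereditary PGL/GIST (SDH-deficient)", _DOM, True, _KNOWN, True),
    ("SDHAF2", "Hereditary paraganglioma", _DOM, True, _KNOWN, False),
    ("CHEK2", "CHEK2-related cancer risk", _DOM, True, _SUGG, True),
    ("MLH1", "Lynch syndrome", _DOM, True, _SEMI, True),
    ("MSH2", "Lynch syndrome", _DOM, True, _SEMI, True),
    ("MSH6", "Lynch syndrome", _DOM, True, _SEMI, True),
    ("PMS2", "Lynch syndrome", _DOM, True, _SEMI, True),
    ("BRCA1", "Hereditary breast/ovarian cancer", _DOM, True, _NONE, True),
    ("BRCA2", "Hereditary breast/ovarian cancer", _DOM, True, _NONE, True),
    ("FLCN", "Birt-Hogg-Dube syndrome", _DOM, True, _NONE, True),
    ("CDC73", "Hyperparathyroid-jaw tumor syndrome", _DOM, True, _NONE, True),
    ("ATM", "ATM-related cancer risk", _DOM, True, _NONE, False),
    ("ATR", "ATR-related risk (suggested)", _DOM, True, _NONE, False),
    ("MRE11", "MRE11-related risk (suggested)", _DOM, True, _NONE, False),
    ("BRIP1", "BRIP1-related ovarian cancer risk", _DOM, True, _NONE, False),
    ("DDX41", "DDX41-related myeloid neoplasia", _DOM, True, _NONE, False),
    ("MITF", "MITF-related melanoma/RCC risk", _DOM, False, _NONE, False),
    ("KCNQ1", "Long QT syndrome 1", _DOM, True, _NONE, False),
    ("POLG", "POLG-related mitochondrial disease", _REC, False, _NONE, False),
    ("MUTYH", "MUTYH-associated polyposis", _REC, True, _NONE, True),
    ("PALB2", "PALB2-related breast cancer", _DOM, True, _NONE, True),
    ("APC", "Familial adenomatous polyposis", _DOM, True, _SUGG, True),
    ("PTEN", "PTEN hamartoma tumor syndrome", _DOM, True, _SUGG, True),
    ("VHL", "Von Hippel-Lindau syndrome", _DOM, True, _NONE, True),
    ("CDKN2A", "Familial melanoma", _DOM, True, _NONE, True),
    ("NBN", "NBN-related cancer risk", _DOM, True, _NONE, False),
    ("RECQL4", "Rothmund-Thomson syndrome", _REC, True, _KNOWN, False),
    ("WRN", "Werner syndrome", _REC, True, _KNOWN, False),
    ("DICER1", "DICER1 tumor predisposition", _DOM, True, _KNOWN, True),
    ("SMARCB1", "Rhabdoid tumor predisposition", _DOM, True, _KNOWN, True),
    ("SMARCA4", "Rhabdoid tumor predisposition 2", _DOM, True, _KNOWN, True),
    ("FH", "HLRCC (leiomyomatosis and RCC)", _DOM, True, _KNOWN, True),
    ("STK11", "Peutz-Jeghers syndrome", _DOM, True, _NONE, True),
    ("PTCH1", "Gorlin syndrome", _DOM, True, _NONE, True),
    ("TSC1", "Tuberous sclerosis 1", _DOM, True, _SUGG, True),
    ("TSC2", "Tuberous sclerosis 2", _DOM, True, _SUGG, True),
    ("KIT", "Familial GIST", _DOM, False, _KNOWN, True),
    ("PDGFRA", "Familial GIST", _DOM, False, _KNOWN, True),
]


def default_knowledge() -> KnowledgeTable:
    return KnowledgeTable(
        KnowledgeRow(
            gene=g, syndrome=s, inheritance=inh, truncation_is_mechanism=trunc,
            mesenchymal_association=assoc, surveillance_exists=surv,
        )
        for g, s, inh, trunc, assoc, surv in _KNOWLEDGE
    )


def default_panel() -> GenePanel:
    """Stand-in hereditary-cancer panel (the study's full list is not public)."""
    return GenePanel((row[0] for row in _KNOWLEDGE),
                     version_label="twohit-standin-1.0")


# synthetic desk-scale genome: genes laid out deterministically on 12
# miniature chromosomes, 100 kb per gene, 500 kb spacing
_GENE_LENGTH = 100_000
_GENE_SPACING = 500_000
_N_CHROMS = 12
CHROM_LENGTH = 30_000_000


def default_gene_map() -> dict[str, GeneInterval]:
    out = {}
    for i, (gene, *_rest) in enumerate(_KNOWLEDGE):
        chrom = f"chr{i % _N_CHROMS + 1}"
        start = 1_000_000 + (i // _N_CHROMS) * _GENE_SPACING
        out[gene] = GeneInterval(gene, chrom, start, start + _GENE_LENGTH)
    return out


# ---------------------------------------------------------------------------
# Diagnosis-text -> category mapping (editable; unmapped text is an error)
# ---------------------------------------------------------------------------

_C = DiagnosisCategory
DIAGNOSIS_CATEGORIES: dict[str, DiagnosisCategory] = {
    # high-grade soft tissue sarcoma
    "leiomyosarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "angiosarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "pleomorphic liposarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "liposarcoma, dedifferentiated": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "liposarcoma (ddlps)": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "mpnst": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "radiation-induced sarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "soft tissue sarcoma paravertebral": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "undifferentiated pleomorphic sarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "soft tissue sarcoma, high-grade": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "synovial sarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    "myxofibrosarcoma": _C.SOFT_TISSUE_SARCOMA_HIGH,
    # low-grade soft tissue sarcoma
    "dfsp, fibrosarcoma": _C.SOFT_TISSUE_SARCOMA_LOW,
    "dfsp": _C.SOFT_TISSUE_SARCOMA_LOW,
    "soft tissue sarcoma, low-grade": _C.SOFT_TISSUE_SARCOMA_LOW,
    "myxoid liposarcoma, low-grade": _C.SOFT_TISSUE_SARCOMA_LOW,
    # benign soft tissue
    "synovial chondromatosis": _C.SOFT_TISSUE_BENIGN,
    "lipoma": _C.SOFT_TISSUE_BENIGN,
    "fibromatosis": _C.SOFT_TISSUE_BENIGN,
    "soft tissue, benign": _C.SOFT_TISSUE_BENIGN,
    "schwannoma": _C.SOFT_TISSUE_BENIGN,
    # bone sarcoma, high-grade
    "osteosarcoma": _C.BONE_SARCOMA_HIGH,
    "ewing sarcoma": _C.BONE_SARCOMA_HIGH,
    "bone sarcoma, high-grade": _C.BONE_SARCOMA_HIGH,
    # bone sarcoma, low-grade
    "osteosarcoma, parosteal": _C.BONE_SARCOMA_LOW,
    "low-grade parosteal os": _C.BONE_SARCOMA_LOW,
    "secondary peripheral chondrosarcoma": _C.BONE_SARCOMA_LOW,
    "chondrosarcoma, low-grade": _C.BONE_SARCOMA_LOW,
    "bone sarcoma, low-grade": _C.BONE_SARCOMA_LOW,
    # benign bone
    "osteochondroma": _C.BONE_BENIGN,
    "enchondroma": _C.BONE_BENIGN,
    "bone, benign": _C.BONE_BENIGN,
    # GIST
    "gist": _C.GIST,
    "gist, wild-type": _C.GIST,
    # gynaecological tract
    "leiomyoma": _C.GYNAECOLOGICAL_TRACT,
    "uterine leiomyoma": _C.GYNAECOLOGICAL_TRACT,
    "adenosarcoma, sarcomatous overgrowth": _C.GYNAECOLOGICAL_TRACT,
    "uterine leiomyosarcoma": _C.GYNAECOLOGICAL_TRACT,
    "gynaecological tract": _C.GYNAECOLOGICAL_TRACT,
}


def map_diagnosis(text: str) -> DiagnosisCategory:
    """Look up the diagnosis category for free-text; unmapped text raises."""
    from .errors import ValidationError

    key = text.strip().lower()
    if key not in DIAGNOSIS_CATEGORIES:
        raise ValidationError(f"unmapped diagnosis text: {text!r}")
    return DIAGNOSIS_CATEGORIES[key]


def default_interactions() -> dict[str, list[str]]:
    """A minimal pathway / protein-interaction table for second-hit expansion."""
    return {
        "NF1": ["SPRED1", "RAS", "KRAS"],
        "TP53": ["MDM2", "CDKN2A"],
        "RB1": ["CDK4", "CCND1", "CDKN2A"],
        "MLH1": ["PMS2", "MSH2", "MSH6"],
        "MSH6": ["MSH2", "MLH1", "PMS2"],
        "SDHA": ["SDHB", "SDHC", "SDHD", "SDHAF2"],
        "BRCA1": ["BARD1", "BRIP1", "PALB2"],
        "CHEK2": ["ATM", "TP53"],
        "ATM": ["CHEK2", "MRE11", "NBN"],
        "KCNQ1": ["CTNNB1"],
    }
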