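"""Synthetic paired tumor/normal cohort generation.

The generator emulates the screening study's conditions on a miniature
synthetic genome: ~312 cases of which ~8% carry a planted pathogenic
germline first hit in a hereditary-cancer panel gene, with a planted
somatic second hit in a configurable fraction of carriers (default
11/24), drawn from five evidence classes (somatic SNV at VAF 0.3, focal
deletion, copy-neutral LOH, expression at the cohort minimum, promoter
methylation at beta 0.9). Every case additionally receives benign decoy
variants designed to be removed by each filter gate and exclusion rule
(common allele frequency, multi-submitter benign ClinVar entries,
high-count synonymous variants, single-submitter likely-benign variants
with high local counts, off-panel and non-coding variants).

Truth is recorded per plant so recovery can be scored exactly. The same
seed reproduces the cohort byte-for-byte, on disk and in memory.

What this emulates — and what it does not: the generator reproduces the
*decision surface* of the pipeline (annotations, VAFs, copy-number
states, expression ranks, promoter betas), not sequencing physics. There
are no reads, no mapping artefacts, no subclonal structure, and
background expression/methylation for unplanted carrier genes is pinned
to unremarkable values so that planted truth is the only signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import io_formats
from .errors import ValidationError
from .models import (
    CaseRecord,
    Classification,
    ClinVarAssertion,
    CnSegment,
    Consequence,
    DiagnosisCategory,
    ExpressionMatrix,
    GenePanel,
    GermlineVariantRecord,
    Genotype,
    KnowledgeTable,
    MethylationTable,
    Sex,
    SomaticVariant,
    VariantKey,
)
from .resources import default_gene_map, default_knowledge, default_panel
from .somatic import CaseOmics

BUILD = "synthetic-mini"

EVIDENCE_CLASSES = (
    "snv", "focal_deletion", "loh", "expression_low",
    "promoter_hypermethylation",
)

# genes eligible for planted first hits: dominant, truncation-mechanism
_CARRIER_GENES = (
    "NF1", "RB1", "TP53", "EXT2", "SDHA", "MLH1", "MSH6", "CHEK2",
    "BRCA1", "CDC73", "ATM", "FLCN",
)

_CATEGORY_WEIGHTS = {
    DiagnosisCategory.SOFT_TISSUE_SARCOMA_HIGH: 131,
    DiagnosisCategory.SOFT_TISSUE_SARCOMA_LOW: 34,
    DiagnosisCategory.SOFT_TISSUE_BENIGN: 41,
    DiagnosisCategory.BONE_SARCOMA_HIGH: 13,
    DiagnosisCategory.BONE_SARCOMA_LOW: 10,
    DiagnosisCategory.BONE_BENIGN: 5,
    DiagnosisCategory.GIST: 40,
    DiagnosisCategory.GYNAECOLOGICAL_TRACT: 38,
}

_BENIGN_CATEGORIES = {
    DiagnosisCategory.SOFT_TISSUE_BENIGN,
    DiagnosisCategory.BONE_BENIGN,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generation parameters; defaults are the study's conditions."""

    n_cases: int = 312
    carrier_fraction: float = 0.08
    second_hit_fraction: float = 11 / 24
    evidence_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    decoys_per_case: int = 6
    background_somatic_mean: float = 30.0  # passengers passing TMB gates
    expr_log_mu_mean: float = 1.5          # per-gene log-FPKM location
    expr_log_mu_sd: float = 1.0
    expr_log_sigma: float = 0.5            # within-gene log-FPKM spread
    meth_beta_a: float = 2.0               # baseline promoter Beta params
    meth_beta_b: float = 20.0
    meth_planted_beta: float = 0.9
    probes_per_promoter: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValidationError("n_cases must be >= 2")
        for name in ("carrier_fraction", "second_hit_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if len(self.evidence_mix) != len(EVIDENCE_CLASSES):
            raise ValidationError(
                f"evidence_mix needs {len(EVIDENCE_CLASSES)} weights"
            )
        if abs(sum(self.evidence_mix) - 1.0) > 1e-9:
            raise ValidationError("evidence_mix must sum to 1")


@dataclass
class Cohort:
    """An in-memory synthetic cohort plus its ground truth."""

    config: SimConfig
    cases: list[CaseRecord]
    germline: dict[str, list[GermlineVariantRecord]]
    omics: dict[str, CaseOmics]
    expression: ExpressionMatrix
    methylation: MethylationTable
    panel: GenePanel
    knowledge: KnowledgeTable
    gene_map: dict = field(default_factory=dict)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _decoy_records(case_id: str, rng: np.random.Generator) -> list[GermlineVariantRecord]:
    """Benign decoys: one per filter gate / exclusion rule."""
    gm = default_gene_map()
    host = gm["BRCA2"]  # panel gene not used for planted first hits
    mk = lambda off, **kw: GermlineVariantRecord(  # noqa: E731
        case_id=case_id,
        key=VariantKey(host.chrom, host.start + off, "A", "G", BUILD),
        genotype=Genotype.HET,
        **kw,
    )
    return [
        # common variant: fails the AF < 0.01 gate
        mk(10, gene="BRCA2", consequence=Consequence.MISSENSE,
           population_af=float(rng.uniform(0.01, 0.3))),
        # rule A: benign by more than two submitters
        mk(20, gene="BRCA2", consequence=Consequence.MISSENSE,
           population_af=0.001,
           clinvar=ClinVarAssertion(Classification.BENIGN, 3, False)),
        # rule B: synonymous with a high local-database count
        mk(30, gene="BRCA2", consequence=Consequence.SYNONYMOUS,
           population_af=0.001, local_count=int(rng.integers(101, 400))),
        # rule C: single benign submitter, local count above 80
        mk(40, gene="BRCA2", consequence=Consequence.MISSENSE,
           population_af=0.001, local_count=int(rng.integers(81, 100)),
           clinvar=ClinVarAssertion(Classification.LIKELY_BENIGN, 1, False)),
        # off-panel gene
        mk(50, gene="OFFPANEL1", consequence=Consequence.MISSENSE,
           population_af=None),
        # non-coding variant in a panel gene
        mk(60, gene="BRCA2", consequence=Consequence.NON_CODING,
           population_af=None),
    ]


_DECOY_CLASSES = ("frequency", "rule_A", "rule_B", "rule_C", "panel", "noncoding")


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate a deterministic synthetic cohort with recorded truth."""
    rng = np.random.default_rng(config.seed)
    gene_map = default_gene_map()
    panel = default_panel()
    knowledge = default_knowledge()
    categories = list(_CATEGORY_WEIGHTS)
    cat_p = np.array(list(_CATEGORY_WEIGHTS.values()), dtype=float)
    cat_p /= cat_p.sum()

    cases: list[CaseRecord] = []
    germline: dict[str, list[GermlineVariantRecord]] = {}
    omics_somatic: dict[str, list[SomaticVariant]] = {}
    omics_segments: dict[str, list[CnSegment]] = {}
    truth_rows = []
    expr_plants: list[tuple[str, str]] = []   # (gene, sample)
    meth_plants: list[tuple[str, str]] = []
    carrier_genes_by_case: dict[str, str] = {}

    for i in range(config.n_cases):
        case_id = f"S{i:03d}"
        category = categories[int(rng.choice(len(categories), p=cat_p))]
        sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
        age = float(np.clip(rng.normal(58, 16), 18, 92).round(1))
        is_carrier = bool(rng.random() < config.carrier_fraction)

        records = _decoy_records(case_id, rng)
        somatic: list[SomaticVariant] = []
        segments: list[CnSegment] = []
        germline_tumor_vaf: dict[str, float] = {}
        planted_class = ""
        gene = ""

        if is_carrier:
            gene = _CARRIER_GENES[int(rng.integers(len(_CARRIER_GENES)))]
            interval = gene_map[gene]
            records.append(
                GermlineVariantRecord(
                    case_id=case_id,
                    key=VariantKey(interval.chrom, interval.start + 500,
                                   "C", "T", BUILD),
                    gene=gene,
                    consequence=Consequence.NONSENSE,
                    genotype=Genotype.HET,
                    population_af=None,
                    clinvar=ClinVarAssertion(
                        Classification.PATHOGENIC, 0, True
                    ),
                )
            )
            carrier_genes_by_case[case_id] = gene
            has_second_hit = bool(rng.random() < config.second_hit_fraction)
            if has_second_hit:
                planted_class = EVIDENCE_CLASSES[
                    int(rng.choice(len(EVIDENCE_CLASSES),
                                   p=np.asarray(config.evidence_mix)))
                ]
            # copy-number state over the carrier gene by planted class
            if planted_class == "focal_deletion":
                segments.append(
                    CnSegment(interval.chrom, interval.start - 500_000,
                              interval.end + 500_000, 1.0, True)
                )
                germline_tumor_vaf[gene] = 0.85
            elif planted_class == "loh":
                segments.append(
                    CnSegment(interval.chrom, interval.start - 500_000,
                              interval.end + 500_000, 2.0, True)
                )
                germline_tumor_vaf[gene] = 0.9
            else:
                segments.append(
                    CnSegment(interval.chrom, interval.start - 500_000,
                              interval.end + 500_000, 2.0, False)
                )
            if planted_class == "snv":
                somatic.append(
                    SomaticVariant(
                        case_id=case_id,
                        key=VariantKey(interval.chrom, interval.start + 1000,
                                       "G", "A", BUILD),
                        gene=gene,
                        consequence=Consequence.NONSENSE,
                        vaf=0.3,
                        depth=100,
                    )
                )
            elif planted_class == "expression_low":
                expr_plants.append((gene, case_id))
            elif planted_class == "promoter_hypermethylation":
                meth_plants.append((gene, case_id))

        # intergenic somatic passengers (drive TMB, never map to a gene)
        n_bg = int(rng.poisson(config.background_somatic_mean))
        for j in range(n_bg):
            chrom = f"chr{int(rng.integers(1, 13))}"
            pos = int(rng.integers(20_000_000, 29_000_000))
            somatic.append(
                SomaticVariant(
                    case_id=case_id,
                    key=VariantKey(chrom, pos, "A", "T", BUILD),
                    gene=None,
                    consequence=Consequence.NON_CODING,
                    vaf=round(float(rng.uniform(0.1, 0.6)), 3),
                    depth=int(rng.integers(40, 120)),
                    population_af=0.0,
                )
            )

        cases.append(
            CaseRecord(
                case_id=case_id,
                diagnosis=category.value.replace("_", " "),
                category=category,
                malignant=category not in _BENIGN_CATEGORIES,
                sex=sex,
                age=age,
                phenotype_genes=frozenset({gene}) if gene else frozenset(),
                germline_finding=False,  # set by the screen, not the truth
            )
        )
        germline[case_id] = records
        omics_somatic[case_id] = somatic
        omics_segments[case_id] = segments
        truth_rows.append(
            {
                "case_id": case_id,
                "carrier": is_carrier,
                "gene": gene,
                "second_hit_class": planted_class,
                "decoy_classes": ",".join(_DECOY_CLASSES),
                "germline_tumor_vaf": ";".join(
                    f"{g}:{v}" for g, v in germline_tumor_vaf.items()
                ),
            }
        )

    sample_ids = [c.case_id for c in cases]

    # expression matrix over all panel genes
    genes = sorted(panel.genes)
    mu = rng.normal(config.expr_log_mu_mean, config.expr_log_mu_sd, len(genes))
    values = np.exp(
        rng.normal(mu[:, None], config.expr_log_sigma,
                   (len(genes), len(sample_ids)))
    ).round(4)
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    # planted low expression: the exact cohort minimum (zero FPKM)
    for gene, sample in expr_plants:
        df.loc[gene, sample] = 0.0
    # unplanted carrier genes are pinned to the per-gene median so that
    # random tail membership cannot masquerade as a second hit
    for case_id, gene in carrier_genes_by_case.items():
        if (gene, case_id) not in expr_plants:
            df.loc[gene, case_id] = float(df.loc[gene].median())
    expression = ExpressionMatrix(df)

    # methylation: promoter probes for carrier genes across all samples
    meth_genes = sorted(set(carrier_genes_by_case.values())) or ["NF1"]
    meth_plant_set = set(meth_plants)
    rows = []
    offsets = np.linspace(-1200, 1200, config.probes_per_promoter).astype(int)
    for gene in meth_genes:
        for k, off in enumerate(offsets):
            probe = f"{gene}_p{k}"
            betas = rng.beta(config.meth_beta_a, config.meth_beta_b,
                             len(sample_ids))
            betas = np.minimum(betas, 0.5).round(4)  # baseline stays unmethylated
            for sample, beta in zip(sample_ids, betas):
                rows.append(
                    {
                        "probe": probe,
                        "gene": gene,
                        "dist_tss": int(off),
                        "beta": (
                            config.meth_planted_beta
                            if (gene, sample) in meth_plant_set
                            else float(beta)
                        ),
                        "sample": sample,
                    }
                )
    methylation = MethylationTable(pd.DataFrame(rows))

    omics = {}
    truth = pd.DataFrame(truth_rows)
    for row in truth_rows:
        case_id = row["case_id"]
        gvaf = {}
        if row["germline_tumor_vaf"]:
            for part in row["germline_tumor_vaf"].split(";"):
                g, v = part.split(":")
                gvaf[g] = float(v)
        omics[case_id] = CaseOmics(
            somatic=omics_somatic[case_id],
            segments=omics_segments[case_id],
            expression=expression,
            methylation=methylation,
            sample_id=case_id,
            germline_tumor_vaf=gvaf or None,
        )

    return Cohort(
        config=config,
        cases=cases,
        germline=germline,
        omics=omics,
        expression=expression,
        methylation=methylation,
        panel=panel,
        knowledge=knowledge,
        gene_map=gene_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the cohort in the documented on-disk layout.

    ``out_dir/``: panel.tsv, knowledge.tsv, gene_map.tsv, cases.tsv,
    expression.tsv, methylation.tsv, truth.tsv, germline/<case>.vcf,
    somatic/<case>.vcf, segments/<case>.tsv.
    """
    out = Path(out_dir)
    (out / "germline").mkdir(parents=True, exist_ok=True)
    (out / "somatic").mkdir(exist_ok=True)
    (out / "segments").mkdir(exist_ok=True)

    io_formats.write_panel(out / "panel.tsv", cohort.panel)
    io_formats.write_knowledge(out / "knowledge.tsv", cohort.knowledge)
    io_formats.write_gene_map(out / "gene_map.tsv", cohort.gene_map)
    io_formats.write_cases(out / "cases.tsv", cohort.cases)
    io_formats.write_expression(out / "expression.tsv", cohort.expression)
    io_formats.write_methylation(out / "methylation.tsv", cohort.methylation)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    for case in cohort.cases:
        cid = case.case_id
        io_formats.write_germline_vcf(
            out / "germline" / f"{cid}.vcf", cohort.germline[cid], cid
        )
        io_formats.write_somatic_vcf(
            out / "somatic" / f"{cid}.vcf", list(cohort.omics[cid].somatic), cid
        )
        io_formats.write_segments(
            out / "segments" / f"{cid}.tsv", list(cohort.omics[cid].segments)
        )
    return out
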