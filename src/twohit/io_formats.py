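"""Readers and writers for every external representation the pipeline touches.

Conventions
-----------
* VCF 4.2 for small variants and (via SVTYPE/END) structural variants,
  parsed with :mod:`pysam`. Positions are converted to the internal
  0-based half-open convention on read and back to 1-based on write.
* Segment, expression, methylation, panel, knowledge, ClinVar-style,
  local-count and case-metadata tables are TSV with documented headers;
  segment coordinates are BED-like (already 0-based half-open).
* Annotations (gene, consequence class, gnomAD AF, ClinVar summary, local
  counts) may arrive embedded as INFO keys or as side tables joined on the
  variant key; side tables win on conflict.

INFO dialect (key names configurable through :class:`VcfDialect`):
``GENE`` gene symbol, ``CSQ`` consequence class, ``GNOMAD_AF`` population
allele frequency, ``CLNSIG`` summary classification, ``CLNBLB`` count of
benign/likely-benign submitters, ``CLNCA`` flag for a reported cancer
syndrome association, ``LOCALN`` local-database occurrence count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .errors import ConfigurationError, ParseError, ValidationError
from .models import (
    Actionability,
    CaseRecord,
    Classification,
    ClinVarAssertion,
    CnSegment,
    Consequence,
    DiagnosisCategory,
    ExpressionMatrix,
    GeneInterval,
    GenePanel,
    GermlineVariantRecord,
    Genotype,
    Inheritance,
    KnowledgeRow,
    KnowledgeTable,
    LocalDbCount,
    MesenchymalAssociation,
    Sex,
    SomaticVariant,
    VariantKey,
    validate_segments,
)

VCF_VERSION_LINE = "##fileformat=VCFv4.2"


@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO/FORMAT keys carrying annotations."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    population_af: str = "GNOMAD_AF"
    clinvar_sig: str = "CLNSIG"
    clinvar_benign_submitters: str = "CLNBLB"
    clinvar_cancer_assoc: str = "CLNCA"
    local_count: str = "LOCALN"


DEFAULT_DIALECT = VcfDialect()


def _scalar(value):
    """pysam returns INFO values as tuples for Number=A/.; unwrap singletons."""
    if isinstance(value, tuple):
        return value[0] if value else None
    return value


def _info_get(rec, key, default=None):
    """INFO lookup tolerant of keys not declared in the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _open_vcf(path: str | Path) -> pysam.VariantFile:
    try:
        return pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc


def _require_info_keys(vcf: pysam.VariantFile, keys: Sequence[str], path) -> None:
    declared = set(vcf.header.info.keys())
    missing = [k for k in keys if k not in declared]
    if missing:
        raise ConfigurationError(
            f"{path}: required INFO key(s) {missing} not declared in header; "
            "configure the dialect or supply side tables"
        )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_germline_vcf(
    path: str | Path,
    panel: Optional[GenePanel] = None,
    dialect: VcfDialect = DEFAULT_DIALECT,
    build: str = "unknown",
    case_id: Optional[str] = None,
) -> list[GermlineVariantRecord]:
    """Read a single-sample germline VCF into annotated records.

    One record is emitted per ALT allele; genotype is classified het/hom
    from the sample GT. ``panel`` is accepted for interface symmetry; no
    panel filtering happens here (the screen assigns excluded_panel
    statuses itself). Records lacking a gene annotation carry gene=None.
    """
    with _open_vcf(path) as vcf:
        _require_info_keys(vcf, [dialect.gene, dialect.consequence], path)
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ParseError(f"{path}: expected exactly one sample, got {samples}")
        cid = case_id or samples[0]
        records: list[GermlineVariantRecord] = []
        for rec in vcf:
            gt = rec.samples[0].get("GT") or ()
            for i, alt in enumerate(rec.alts or (), start=1):
                called = [a for a in gt if a is not None]
                if called and all(a == i for a in called) and len(called) > 1:
                    genotype = Genotype.HOM
                else:
                    genotype = Genotype.HET
                records.append(
                    GermlineVariantRecord(
                        case_id=cid,
                        key=VariantKey(rec.chrom, rec.pos - 1, rec.ref, alt, build),
                        gene=_parse_gene(rec, dialect),
                        consequence=_parse_consequence(rec, dialect, path),
                        genotype=genotype,
                        population_af=_parse_float_info(rec, dialect.population_af),
                        clinvar=_parse_clinvar_info(rec, dialect),
                        local_count=int(_scalar(_info_get(rec, dialect.local_count, 0)) or 0),
                    )
                )
    return records


def _parse_gene(rec, dialect: VcfDialect) -> Optional[str]:
    gene = _scalar(_info_get(rec, dialect.gene))
    return gene.upper() if gene else None


def _parse_consequence(rec, dialect: VcfDialect, path) -> Consequence:
    raw = _scalar(_info_get(rec, dialect.consequence))
    if raw is None:
        return Consequence.NON_CODING
    try:
        return Consequence(str(raw))
    except ValueError as exc:
        raise ParseError(
            f"{path} {rec.chrom}:{rec.pos}: unknown consequence class {raw!r}"
        ) from exc


def _parse_float_info(rec, key: str) -> Optional[float]:
    value = _scalar(_info_get(rec, key))
    if value is None:
        return None
    # htslib stores Float INFO as 32-bit; renormalize to 6 significant
    # digits so written values round-trip exactly
    return float(f"{float(value):.6g}")


def _parse_clinvar_info(rec, dialect: VcfDialect) -> ClinVarAssertion:
    sig = _scalar(_info_get(rec, dialect.clinvar_sig))
    if sig is None:
        return ClinVarAssertion()
    return ClinVarAssertion(
        classification=Classification(str(sig)),
        benign_submitters=int(
            _scalar(_info_get(rec, dialect.clinvar_benign_submitters, 0)) or 0
        ),
        has_cancer_syndrome_association=bool(
            _info_get(rec, dialect.clinvar_cancer_assoc, False)
        ),
    )


def read_somatic_vcf(
    path: str | Path,
    dialect: VcfDialect = DEFAULT_DIALECT,
    build: str = "unknown",
    case_id: Optional[str] = None,
) -> list[SomaticVariant]:
    """Read a somatic VCF; every record carries a VAF in [0, 1] and a depth.

    VAF derivation: FORMAT AD (alt / (ref + alt)) when present, else the
    INFO AF field; neither derivable is a parse error identifying the
    record. Records with an SVTYPE INFO key are structural variants and
    use END for their span.
    """
    with _open_vcf(path) as vcf:
        samples = list(vcf.header.samples)
        cid = case_id or (samples[0] if samples else Path(path).stem)
        out: list[SomaticVariant] = []
        for rec in vcf:
            svtype = _info_get(rec, "SVTYPE")
            for i, alt in enumerate(rec.alts or (), start=1):
                vaf, depth = _derive_vaf_depth(rec, i, path)
                out.append(
                    SomaticVariant(
                        case_id=cid,
                        key=VariantKey(rec.chrom, rec.pos - 1, rec.ref, alt, build),
                        gene=_parse_gene(rec, dialect),
                        consequence=_parse_consequence(rec, dialect, path),
                        vaf=vaf,
                        depth=depth,
                        population_af=_parse_float_info(rec, dialect.population_af),
                        filter_pass=(not rec.filter.keys())
                        or ("PASS" in rec.filter.keys()),
                        is_structural=svtype is not None,
                        svtype=str(svtype) if svtype is not None else None,
                        end=int(rec.stop) if svtype is not None else None,
                    )
                )
    return out


def _derive_vaf_depth(rec, alt_index: int, path) -> tuple[float, int]:
    where = f"{path} {rec.chrom}:{rec.pos} {rec.ref}>{(rec.alts or ('?',))[alt_index - 1]}"
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        if ad is not None and len(ad) > alt_index and ad[0] is not None:
            total = sum(a for a in ad if a is not None)
            if total <= 0:
                raise ParseError(f"{where}: AD present but zero total depth")
            depth = sample.get("DP") or total
            return ad[alt_index] / total, int(depth)
        af = sample.get("AF")
        if af is not None:
            af_val = af[alt_index - 1] if isinstance(af, tuple) else af
            depth = sample.get("DP") or _scalar(_info_get(rec, "DP")) or 0
            return float(af_val), int(depth)
    af = _info_get(rec, "AF")
    if af is not None:
        depth = _scalar(_info_get(rec, "DP")) or 0
        af_val = _scalar(af)
        return float(af_val), int(depth)
    raise ParseError(f"{where}: VAF underivable (no AD or AF)")


# ---------------------------------------------------------------------------
# VCF writing (synthetic cohorts, round-trips)
# ---------------------------------------------------------------------------

_GERMLINE_HEADER_EXTRA = [
    '##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID={csq},Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID={af},Number=1,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID={sig},Number=1,Type=String,Description="ClinVar summary classification">',
    '##INFO=<ID={blb},Number=1,Type=Integer,Description="Benign/likely-benign submitter count">',
    '##INFO=<ID={ca},Number=0,Type=Flag,Description="Cancer syndrome association reported">',
    '##INFO=<ID={loc},Number=1,Type=Integer,Description="Local database occurrence count">',
]


def _header_lines(contigs: Iterable[str], dialect: VcfDialect, somatic: bool) -> list[str]:
    lines = [VCF_VERSION_LINE]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        line.format(
            gene=dialect.gene,
            csq=dialect.consequence,
            af=dialect.population_af,
            sig=dialect.clinvar_sig,
            blb=dialect.clinvar_benign_submitters,
            ca=dialect.clinvar_cancer_assoc,
            loc=dialect.local_count,
        )
        for line in _GERMLINE_HEADER_EXTRA
    ]
    if somatic:
        lines += [
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
            '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end (1-based inclusive)">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        ]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    return lines


def write_germline_vcf(
    path: str | Path,
    records: Sequence[GermlineVariantRecord],
    sample_id: str,
    dialect: VcfDialect = DEFAULT_DIALECT,
) -> None:
    contigs = sorted({r.key.chrom for r in records})
    lines = _header_lines(contigs, dialect, somatic=False)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for r in sorted(records, key=lambda r: (r.key.chrom, r.key.pos, r.key.alt)):
        info = [f"{dialect.consequence}={r.consequence.value}"]
        if r.gene:
            info.insert(0, f"{dialect.gene}={r.gene}")
        if r.population_af is not None:
            info.append(f"{dialect.population_af}={r.population_af:.6g}")
        if r.clinvar.classification is not Classification.NONE:
            info.append(f"{dialect.clinvar_sig}={r.clinvar.classification.value}")
            info.append(
                f"{dialect.clinvar_benign_submitters}={r.clinvar.benign_submitters}"
            )
            if r.clinvar.has_cancer_syndrome_association:
                info.append(dialect.clinvar_cancer_assoc)
        if r.local_count:
            info.append(f"{dialect.local_count}={r.local_count}")
        gt = "1/1" if r.genotype is Genotype.HOM else "0/1"
        lines.append(
            f"{r.key.chrom}\t{r.key.pos1}\t.\t{r.key.ref}\t{r.key.alt}\t.\tPASS\t"
            + ";".join(info)
            + f"\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_somatic_vcf(
    path: str | Path,
    variants: Sequence[SomaticVariant],
    sample_id: str,
    dialect: VcfDialect = DEFAULT_DIALECT,
) -> None:
    contigs = sorted({v.key.chrom for v in variants})
    lines = _header_lines(contigs, dialect, somatic=True)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for v in sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.alt)):
        info = [f"{dialect.consequence}={v.consequence.value}"]
        if v.gene:
            info.insert(0, f"{dialect.gene}={v.gene}")
        if v.population_af is not None:
            info.append(f"{dialect.population_af}={v.population_af:.6g}")
        if v.is_structural:
            info.append(f"SVTYPE={v.svtype}")
            if v.end is not None:
                info.append(f"END={v.end}")  # internal half-open end == 1-based inclusive
        alt_reads = round(v.vaf * v.depth)
        ref_reads = max(v.depth - alt_reads, 0)
        filt = "PASS" if v.filter_pass else "fail"
        lines.append(
            f"{v.key.chrom}\t{v.key.pos1}\t.\t{v.key.ref}\t{v.key.alt}\t.\t{filt}\t"
            + ";".join(info)
            + f"\tGT:AD:DP:AF\t0/1:{ref_reads},{alt_reads}:{v.depth}:{v.vaf:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def read_segments(path: str | Path) -> list[CnSegment]:
    """Read BED-like copy-number segments (0-based half-open coordinates)."""
    df = _read_tsv(path, ["chrom", "start", "end", "total_copy_number",
                          "allelic_imbalance"])
    segments = []
    for i, row in df.iterrows():
        try:
            maf = row.get("minor_allele_fraction")
            segments.append(
                CnSegment(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    total_copy_number=float(row["total_copy_number"]),
                    allelic_imbalance=_parse_bool(row["allelic_imbalance"]),
                    minor_allele_fraction=None if pd.isna(maf) else float(maf),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    validate_segments(segments)
    return segments


def write_segments(path: str | Path, segments: Sequence[CnSegment]) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "total_copy_number": s.total_copy_number,
            "allelic_imbalance": s.allelic_imbalance,
            "minor_allele_fraction": s.minor_allele_fraction,
        }
        for s in segments
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "total_copy_number",
                 "allelic_imbalance", "minor_allele_fraction"],
    ).to_csv(path, sep="\t", index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValidationError(f"cannot interpret boolean value {value!r}")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Genes x samples FPKM matrix; first column 'gene', remaining samples."""
    df = _read_tsv(path, ["gene"]).set_index("gene")
    try:
        return ExpressionMatrix(df.astype(float))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="gene")


def read_methylation(path: str | Path):
    from .models import MethylationTable

    df = _read_tsv(path, list(MethylationTable.COLUMNS))
    try:
        return MethylationTable(df)
    except ValidationError as exc:
        bad = df.index[(df["beta"] < 0) | (df["beta"] > 1)]
        rows = [int(i) + 1 for i in bad[:5]]
        raise ValidationError(f"{path} row(s) {rows}: {exc}") from exc


def write_methylation(path: str | Path, table) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> GenePanel:
    """One symbol per line; an optional '#version=<label>' comment line."""
    version = "unversioned"
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#version="):
                version = line.split("=", 1)[1]
            continue
        genes.append(line)
    return GenePanel(genes, version_label=version)


def write_panel(path: str | Path, panel: GenePanel) -> None:
    lines = [f"#version={panel.version_label}"] + sorted(panel.genes)
    Path(path).write_text("\n".join(lines) + "\n")


def read_knowledge(path: str | Path) -> KnowledgeTable:
    df = _read_tsv(
        path,
        ["gene", "syndrome", "inheritance", "truncation_is_mechanism",
         "mesenchymal_association", "surveillance_exists"],
    )
    rows = [
        KnowledgeRow(
            gene=str(r["gene"]).upper(),
            syndrome=str(r["syndrome"]),
            inheritance=Inheritance(str(r["inheritance"])),
            truncation_is_mechanism=_parse_bool(r["truncation_is_mechanism"]),
            mesenchymal_association=MesenchymalAssociation(
                str(r["mesenchymal_association"])
            ),
            surveillance_exists=_parse_bool(r["surveillance_exists"]),
        )
        for _, r in df.iterrows()
    ]
    return KnowledgeTable(rows)


def write_knowledge(path: str | Path, table: KnowledgeTable) -> None:
    rows = [
        {
            "gene": r.gene,
            "syndrome": r.syndrome,
            "inheritance": r.inheritance.value,
            "truncation_is_mechanism": r.truncation_is_mechanism,
            "mesenchymal_association": r.mesenchymal_association.value,
            "surveillance_exists": r.surveillance_exists,
        }
        for r in table.rows.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clinvar_table(
    path: str | Path, build: str = "unknown"
) -> dict[VariantKey, ClinVarAssertion]:
    """Side table of ClinVar summaries, POS 1-based as in VCF."""
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "classification",
                          "benign_submitters", "cancer_association"])
    out = {}
    for i, r in df.iterrows():
        try:
            key = VariantKey(str(r["chrom"]), int(r["pos"]) - 1, str(r["ref"]),
                             str(r["alt"]), build)
            out[key] = ClinVarAssertion(
                classification=Classification(str(r["classification"])),
                benign_submitters=int(r["benign_submitters"]),
                has_cancer_syndrome_association=_parse_bool(r["cancer_association"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    return out


def write_clinvar_table(
    path: str | Path, table: Mapping[VariantKey, ClinVarAssertion]
) -> None:
    rows = [
        {
            "chrom": k.chrom,
            "pos": k.pos1,
            "ref": k.ref,
            "alt": k.alt,
            "classification": v.classification.value,
            "benign_submitters": v.benign_submitters,
            "cancer_association": v.has_cancer_syndrome_association,
        }
        for k, v in table.items()
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "classification",
                 "benign_submitters", "cancer_association"],
    ).to_csv(path, sep="\t", index=False)


def read_local_db(path: str | Path, build: str = "unknown") -> dict[VariantKey, LocalDbCount]:
    df = _read_tsv(path, ["chrom", "pos", "ref", "alt", "occurrence_count",
                          "database_size"])
    out = {}
    for i, r in df.iterrows():
        try:
            key = VariantKey(str(r["chrom"]), int(r["pos"]) - 1, str(r["ref"]),
                             str(r["alt"]), build)
            out[key] = LocalDbCount(key, int(r["occurrence_count"]),
                                    int(r["database_size"]))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    return out


def write_local_db(path: str | Path, table: Mapping[VariantKey, LocalDbCount]) -> None:
    rows = [
        {
            "chrom": k.chrom,
            "pos": k.pos1,
            "ref": k.ref,
            "alt": k.alt,
            "occurrence_count": v.occurrence_count,
            "database_size": v.database_size,
        }
        for k, v in table.items()
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "occurrence_count", "database_size"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> dict[str, GeneInterval]:
    df = _read_tsv(path, ["gene", "chrom", "start", "end"])
    out = {}
    for i, r in df.iterrows():
        try:
            gi = GeneInterval(str(r["gene"]).upper(), str(r["chrom"]),
                              int(r["start"]), int(r["end"]))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
        out[gi.gene] = gi
    return out


def write_gene_map(path: str | Path, gene_map: Mapping[str, GeneInterval]) -> None:
    rows = [
        {"gene": g.gene, "chrom": g.chrom, "start": g.start, "end": g.end}
        for g in gene_map.values()
    ]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path: str | Path) -> dict[str, list[str]]:
    """Gene -> associated genes (pathway / protein interaction partners)."""
    df = _read_tsv(path, ["gene", "associated_genes"])
    out: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        partners = str(r["associated_genes"]).strip()
        out[str(r["gene"]).upper()] = (
            [] if not partners or partners.lower() == "nan"
            else [p.strip().upper() for p in partners.split(",") if p.strip()]
        )
    return out


def write_interactions(path: str | Path, interactions: Mapping[str, list[str]]) -> None:
    rows = [
        {"gene": g, "associated_genes": ",".join(partners)}
        for g, partners in interactions.items()
    ]
    pd.DataFrame(rows, columns=["gene", "associated_genes"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Case metadata
# ---------------------------------------------------------------------------

CASE_COLUMNS = [
    "case_id", "diagnosis", "category", "malignant", "sex", "age",
    "radiotherapy", "chemotherapy", "ploidy", "phenotype_genes",
    "impact_overrides", "no_tumor_tissue",
]


def read_cases(path: str | Path) -> list[CaseRecord]:
    df = _read_tsv(path, CASE_COLUMNS)
    cases = []
    for i, r in df.iterrows():
        try:
            overrides = {}
            raw = r["impact_overrides"]
            if not pd.isna(raw) and str(raw).strip():
                for part in str(raw).split(";"):
                    gene, impact = part.split(":")
                    overrides[gene.strip().upper()] = Actionability(impact.strip())
            phen = r["phenotype_genes"]
            phen_genes = (
                frozenset()
                if pd.isna(phen) or not str(phen).strip()
                else frozenset(g.strip().upper() for g in str(phen).split(","))
            )
            cases.append(
                CaseRecord(
                    case_id=str(r["case_id"]),
                    diagnosis=str(r["diagnosis"]),
                    category=(
                        None if pd.isna(r["category"]) or not str(r["category"]).strip()
                        else DiagnosisCategory(str(r["category"]))
                    ),
                    malignant=_parse_bool(r["malignant"]),
                    sex=None if pd.isna(r["sex"]) else Sex(str(r["sex"])),
                    age=None if pd.isna(r["age"]) else float(r["age"]),
                    radiotherapy=_parse_bool(r["radiotherapy"]),
                    chemotherapy=_parse_bool(r["chemotherapy"]),
                    ploidy=float(r["ploidy"]),
                    phenotype_genes=phen_genes,
                    impact_overrides=overrides,
                    no_tumor_tissue=_parse_bool(r["no_tumor_tissue"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path} row {i + 1}: {exc}") from exc
    return cases


def write_cases(path: str | Path, cases: Sequence[CaseRecord]) -> None:
    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "diagnosis": c.diagnosis,
                "category": c.category.value if c.category else "",
                "malignant": c.malignant,
                "sex": c.sex.value if c.sex else "",
                "age": c.age if c.age is not None else "",
                "radiotherapy": c.radiotherapy,
                "chemotherapy": c.chemotherapy,
                "ploidy": c.ploidy,
                "phenotype_genes": ",".join(sorted(c.phenotype_genes)),
                "impact_overrides": ";".join(
                    f"{g}:{a.value}" for g, a in sorted(c.impact_overrides.items())
                ),
                "no_tumor_tissue": c.no_tumor_tissue,
            }
        )
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Side-table joins
# ---------------------------------------------------------------------------

def _join_key(key: VariantKey) -> tuple[str, int, str, str]:
    # build label is opaque and may legitimately differ between sources
    return (key.chrom, key.pos, key.ref, key.alt)


def apply_annotation_tables(
    records: Sequence[GermlineVariantRecord],
    clinvar: Optional[Mapping[VariantKey, ClinVarAssertion]] = None,
    local_db: Optional[Mapping[VariantKey, LocalDbCount]] = None,
) -> list[GermlineVariantRecord]:
    """Overlay side-table annotations; side tables win over embedded INFO."""
    from dataclasses import replace

    cv = {_join_key(k): v for k, v in (clinvar or {}).items()}
    ldb = {_join_key(k): v for k, v in (local_db or {}).items()}
    out = []
    for rec in records:
        jk = _join_key(rec.key)
        changes = {}
        if jk in cv:
            changes["clinvar"] = cv[jk]
        if jk in ldb:
            changes["local_count"] = ldb[jk].occurrence_count
        out.append(replace(rec, **changes) if changes else rec)
    return out
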