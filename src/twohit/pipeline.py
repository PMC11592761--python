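"""End-to-end orchestration: screen -> second hit -> report.

A run consumes a cohort directory in the documented layout (see
:func:`twohit.simulate.write_cohort`), executes the stages in order,
fails fast on validation errors, and writes a results directory with a
run manifest (tool version, config hash, input digests, per-stage record
counts). Re-running on identical inputs reproduces identical result
digests; only the manifest timestamp differs.

Missing optional inputs (expression matrix, methylation table,
interaction table) degrade the corresponding evidence layer to "no
data" with a warning instead of failing the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
import pandas as pd
import yaml

from . import __version__, io_formats
from .config import ThresholdConfig, DEFAULT_CONFIG
from .errors import ValidationError
from .germline import label_expectation, reportable_genes, screen_case
from .models import ScreenResult, SecondHitVerdict
from .report import cohort_summary, render_text
from .somatic import CaseOmics, analyze_gene, compute_tmb


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_digests: dict
    output_digests: dict
    stage_counts: dict
    timestamp: str
    degraded: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: ThresholdConfig) -> str:
    canon = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _screen_result_dict(res: ScreenResult) -> dict:
    r = res.record
    return {
        "case_id": r.case_id,
        "variant": str(r.key),
        "gene": r.gene,
        "consequence": r.consequence.value,
        "genotype": r.genotype.value,
        "population_af": r.population_af,
        "status": res.status.value,
        "reportable": res.reportable,
        "inheritance_mode": res.inheritance_mode.value,
        "actionability": res.actionability.value,
        "expectation": res.expectation.value,
        "compound_het": res.compound_het,
        "rule_trace": list(res.rule_trace),
    }


def _verdict_dict(v: SecondHitVerdict) -> dict:
    return {
        "case_id": v.case_id,
        "gene": v.gene,
        "hit_found": v.hit_found,
        "informative": v.informative,
        "expectation": v.expectation.value,
        "narrative": v.narrative,
        "evidence": [
            {
                "kind": e.kind.value,
                "gene": e.gene,
                "vaf": e.vaf,
                "copy_number": e.copy_number,
                "percentile": e.percentile,
                "mean_beta": e.mean_beta,
                "pathway_gene": e.pathway_gene,
                "detail": e.detail,
            }
            for e in v.evidence
        ],
    }


def run_all(
    cohort_dir: str | Path,
    out_dir: str | Path,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> RunManifest:
    """Execute screen, second-hit and report stages over a cohort directory."""
    cohort = Path(cohort_dir)
    out = Path(out_dir)
    required = ["panel.tsv", "knowledge.tsv", "gene_map.tsv", "cases.tsv"]
    missing = [f for f in required if not (cohort / f).exists()]
    if missing or not (cohort / "germline").is_dir():
        raise ValidationError(
            f"cohort directory {cohort} is missing required inputs: "
            f"{missing + ([] if (cohort / 'germline').is_dir() else ['germline/'])}"
        )
    out.mkdir(parents=True, exist_ok=True)

    panel = io_formats.read_panel(cohort / "panel.tsv")
    knowledge = io_formats.read_knowledge(cohort / "knowledge.tsv")
    gene_map = io_formats.read_gene_map(cohort / "gene_map.tsv")
    cases = {c.case_id: c for c in io_formats.read_cases(cohort / "cases.tsv")}

    clinvar = (
        io_formats.read_clinvar_table(cohort / "clinvar.tsv")
        if (cohort / "clinvar.tsv").exists() else None
    )
    local_db = (
        io_formats.read_local_db(cohort / "localdb.tsv")
        if (cohort / "localdb.tsv").exists() else None
    )

    degraded = False
    expression = None
    if (cohort / "expression.tsv").exists():
        expression = io_formats.read_expression(cohort / "expression.tsv")
    else:
        degraded = True
        warnings.warn("no expression matrix; expression layer degraded to no-data")
    methylation = None
    if (cohort / "methylation.tsv").exists():
        methylation = io_formats.read_methylation(cohort / "methylation.tsv")
    else:
        degraded = True
        warnings.warn("no methylation table; methylation layer degraded to no-data")
    interactions = (
        io_formats.read_interactions(cohort / "interactions.tsv")
        if (cohort / "interactions.tsv").exists() else None
    )

    input_digests = {
        str(p.relative_to(cohort)): _sha256(p)
        for p in sorted(cohort.rglob("*")) if p.is_file()
    }

    # ---- stage 1: germline screen -------------------------------------
    screen_rows = []
    screen_json: dict[str, list[dict]] = {}
    results_by_case: dict[str, list[ScreenResult]] = {}
    for vcf_path in sorted((cohort / "germline").glob("*.vcf")):
        case_id = vcf_path.stem
        records = io_formats.read_germline_vcf(vcf_path, panel, case_id=case_id)
        records = io_formats.apply_annotation_tables(records, clinvar, local_db)
        results = screen_case(records, panel, knowledge,
                              cases.get(case_id), config)
        results_by_case[case_id] = results
        screen_json[case_id] = [_screen_result_dict(r) for r in results]
        screen_rows += screen_json[case_id]
        if case_id in cases:
            cases[case_id].germline_finding = any(r.reportable for r in results)
    if not results_by_case:
        raise ValidationError(f"no germline VCFs found under {cohort}/germline")

    screen_tsv = out / "screen_results.tsv"
    pd.DataFrame(screen_rows).assign(
        rule_trace=lambda d: d["rule_trace"].map("|".join)
    ).to_csv(screen_tsv, sep="\t", index=False)
    (out / "screen.json").write_text(
        json.dumps(screen_json, indent=2, sort_keys=True)
    )

    # ---- stage 2: somatic second hits ---------------------------------
    verdicts_json: dict[str, list[dict]] = {}
    tmb_rows = []
    evidence_rows = []
    n_verdicts = 0
    for case_id, results in sorted(results_by_case.items()):
        genes = reportable_genes(results)
        if not genes:
            continue
        somatic_path = cohort / "somatic" / f"{case_id}.vcf"
        segments_path = cohort / "segments" / f"{case_id}.tsv"
        somatic = (
            io_formats.read_somatic_vcf(somatic_path, case_id=case_id)
            if somatic_path.exists() else []
        )
        segments = (
            io_formats.read_segments(segments_path)
            if segments_path.exists() else []
        )
        case = cases.get(case_id)
        omics = CaseOmics(
            somatic=somatic,
            segments=segments,
            expression=expression,
            methylation=methylation,
            sample_id=case_id,
        )
        tmb, tmb_high = compute_tmb(somatic, config)
        tmb_rows.append({"case_id": case_id, "tmb_per_mb": round(tmb, 6),
                         "tmb_high": tmb_high})
        case_verdicts = []
        for gene in sorted(genes):
            verdict = analyze_gene(
                case_id=case_id,
                gene=gene,
                omics=omics,
                gene_map=gene_map,
                expectation=label_expectation(gene, knowledge),
                interactions=interactions,
                config=config,
                ploidy=case.ploidy if case else 2.0,
            )
            case_verdicts.append(verdict)
            n_verdicts += 1
            for e in verdict.evidence:
                evidence_rows.append(
                    {"case_id": case_id, "gene": gene, "kind": e.kind.value,
                     "detail": e.detail}
                )
        verdicts_json[case_id] = [_verdict_dict(v) for v in case_verdicts]
        if case is not None:
            case.verdicts = case_verdicts

    (out / "verdicts.json").write_text(
        json.dumps(verdicts_json, indent=2, sort_keys=True)
    )
    pd.DataFrame(
        evidence_rows, columns=["case_id", "gene", "kind", "detail"]
    ).to_csv(out / "evidence.tsv", sep="\t", index=False)
    pd.DataFrame(
        tmb_rows, columns=["case_id", "tmb_per_mb", "tmb_high"]
    ).to_csv(out / "tmb.tsv", sep="\t", index=False)

    # ---- stage 3: cohort report ---------------------------------------
    case_list = list(cases.values())
    n_actionable = sum(
        1
        for results in results_by_case.values()
        for gene_results in reportable_genes(results).values()
        if any(r.actionability.value == "clinical_action" for r in gene_results)
    )
    summary = cohort_summary(case_list, n_actionable=n_actionable)
    (out / "report.txt").write_text(render_text(summary))
    summary.categories.to_csv(out / "category_table.tsv", sep="\t")
    summary_json = {
        "detection_whole": {
            "numerator": summary.detection.whole_cohort.numerator,
            "denominator": summary.detection.whole_cohort.denominator,
        },
        "detection_excluding_benign": {
            "numerator": summary.detection.excluding_benign.numerator,
            "denominator": summary.detection.excluding_benign.denominator,
        },
        "n_actionable": summary.n_actionable,
        "second_hit": {
            "numerator": summary.second_hits.rate.numerator,
            "denominator": summary.second_hits.rate.denominator,
        }
        if summary.second_hits.rate.defined
        else None,
    }
    (out / "summary.json").write_text(
        json.dumps(summary_json, indent=2, sort_keys=True)
    )

    output_digests = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
        and p.name != "manifest.json"
    }
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash(config),
        input_digests=input_digests,
        output_digests=output_digests,
        stage_counts={
            "cases_screened": len(results_by_case),
            "variants_screened": len(screen_rows),
            "carriers": sum(
                1 for r in results_by_case.values()
                if any(x.reportable for x in r)
            ),
            "verdicts": n_verdicts,
        },
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        degraded=degraded,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
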