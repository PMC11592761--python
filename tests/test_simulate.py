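"""Synthetic cohort generator: determinism, decoys, end-to-end recovery."""

from pathlib import Path

import pytest

from twohit.errors import ValidationError
from twohit.germline import label_expectation, reportable_genes, screen_case
from twohit.models import ScreenStatus
from twohit.simulate import EVIDENCE_CLASSES, SimConfig, generate_cohort, write_cohort
from twohit.somatic import analyze_gene


def _dir_identical(a: Path, b: Path) -> bool:
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    if files_a != files_b:
        return False
    return all((a / f).read_bytes() == (b / f).read_bytes() for f in files_a)


def test_same_seed_reproduces_identical_files(tmp_path):
    cfg = SimConfig(n_cases=50, carrier_fraction=0.1, seed=7)
    write_cohort(generate_cohort(cfg), tmp_path / "a")
    write_cohort(generate_cohort(cfg), tmp_path / "b")
    assert _dir_identical(tmp_path / "a", tmp_path / "b")


def test_different_seed_changes_cohort(tmp_path):
    a = generate_cohort(SimConfig(n_cases=50, seed=1))
    b = generate_cohort(SimConfig(n_cases=50, seed=2))
    assert not a.truth.equals(b.truth)


def test_zero_carrier_fraction_yields_no_reportable_cases():
    cohort = generate_cohort(SimConfig(n_cases=40, carrier_fraction=0.0, seed=5))
    assert not cohort.truth.carrier.any()
    for case in cohort.cases:
        results = screen_case(cohort.germline[case.case_id], cohort.panel,
                              cohort.knowledge, case)
        assert not reportable_genes(results)


def test_invalid_config_rejected():
    with pytest.raises(ValidationError):
        SimConfig(second_hit_fraction=1.5)
    with pytest.raises(ValidationError):
        SimConfig(n_cases=1)
    with pytest.raises(ValidationError):
        SimConfig(evidence_mix=(0.5, 0.5, 0.5, 0.5, 0.5))


def test_every_decoy_class_is_exercised():
    cohort = generate_cohort(SimConfig(n_cases=30, seed=11))
    statuses = set()
    for case in cohort.cases:
        for res in screen_case(cohort.germline[case.case_id], cohort.panel,
                               cohort.knowledge, case):
            statuses.add(res.status)
    assert {
        ScreenStatus.EXCLUDED_FREQUENCY,
        ScreenStatus.EXCLUDED_RULE_A,
        ScreenStatus.EXCLUDED_RULE_B,
        ScreenStatus.EXCLUDED_RULE_C,
        ScreenStatus.EXCLUDED_PANEL,
        ScreenStatus.EXCLUDED_NONCODING,
    } <= statuses


def test_carrier_count_tracks_configured_fraction():
    # across seeds the screened carrier count stays within the binomial
    # 99% interval around carrier_fraction * n
    from scipy import stats

    n, p = 312, 0.08
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    for seed in range(5):
        cohort = generate_cohort(SimConfig(n_cases=n, seed=seed))
        carriers = int(cohort.truth.carrier.sum())
        assert lo <= carriers <= hi


def test_planted_hits_recovered_and_null_genes_clean():
    """Every planted second hit of every class is found; unplanted carrier
    genes yield no hit; non-carriers yield nothing reportable."""
    classes_seen = set()
    for seed in (3, 4, 5):
        cohort = generate_cohort(SimConfig(n_cases=80, carrier_fraction=0.3,
                                           second_hit_fraction=0.6, seed=seed))
        cases = {c.case_id: c for c in cohort.cases}
        for _, row in cohort.truth.iterrows():
            results = screen_case(cohort.germline[row.case_id], cohort.panel,
                                  cohort.knowledge, cases[row.case_id])
            genes = reportable_genes(results)
            if not row.carrier:
                assert not genes
                continue
            assert row.gene in genes
            verdict = analyze_gene(
                row.case_id, row.gene, cohort.omics[row.case_id],
                cohort.gene_map,
                label_expectation(row.gene, cohort.knowledge),
            )
            if row.second_hit_class:
                assert verdict.hit_found, (row.case_id, row.second_hit_class)
                classes_seen.add(row.second_hit_class)
            else:
                assert not verdict.hit_found, (row.case_id, verdict.narrative)
    assert classes_seen == set(EVIDENCE_CLASSES)
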