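"""Threshold configuration.

Every numeric cut-off used by the pipeline lives in one versioned,
serializable object so a run can be reproduced from its config file alone.
Defaults are the screening study's operating points: gnomAD AF < 0.01 for
germline rarity, somatic VAF > 5% (SNV/indel) and > 10% (SV), TMB gates of
depth >= 10 / VAF >= 0.05 / gnomAD <= 0.1% over 3000 Mb with > 10/Mb
called high, and top/bottom 5th percentile for aberrant expression.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

CONFIG_VERSION = "1.0"


@dataclass(frozen=True)
class ThresholdConfig:
    # germline frequency gate (strict <)
    af_max: float = 0.01
    # exclusion rules
    rule_a_min_submitters: int = 2      # fires when benign submitters > 2
    rule_b_min_local_count: int = 100   # fires when local count > 100 AND synonymous
    rule_c_submitters: int = 1          # fires when submitters == 1 ...
    rule_c_min_local_count: int = 80    # ... AND local count > 80
    # somatic VAF gates (strict >)
    snv_vaf_min: float = 0.05
    sv_vaf_min: float = 0.10
    # expression outlier tail, percent
    expr_tail_percent: float = 5.0
    min_expression_cohort: int = 20
    # TMB
    tmb_min_depth: int = 10
    tmb_min_af: float = 0.05
    tmb_max_gnomad: float = 0.001
    tmb_genome_mb: float = 3000.0
    tmb_high: float = 10.0
    # methylation
    hypermethylation_beta_min: float = 0.6
    promoter_window_bp: int = 1500
    min_promoter_probes: int = 3
    # copy-number interpretation
    large_deletion_mb: float = 25.0
    chromothripsis_min_switches: int = 10
    cn_neutral_tolerance: float = 0.25  # |CN - ploidy| within this is copy-neutral
    version: str = CONFIG_VERSION

    def __post_init__(self) -> None:
        positive = (
            "af_max snv_vaf_min sv_vaf_min expr_tail_percent tmb_genome_mb "
            "tmb_high hypermethylation_beta_min large_deletion_mb "
            "cn_neutral_tolerance"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.expr_tail_percent < 50):
            raise ValidationError("expr_tail_percent must be in (0, 50)")
        for name in ("tmb_min_depth", "min_promoter_probes",
                     "chromothripsis_min_switches", "min_expression_cohort"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = ThresholdConfig()
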