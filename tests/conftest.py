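import warnings

import pytest

from twohit.config import ThresholdConfig
from twohit.models import (
    ClinVarAssertion,
    Classification,
    Consequence,
    GermlineVariantRecord,
    Genotype,
    VariantKey,
)


@pytest.fixture(autouse=True)
def _quiet_knowledge_warnings():
    """Default-row fallbacks are expected in tests; keep output readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*absent from knowledge table.*")
        warnings.filterwarnings("ignore", message=".*absent from interaction table.*")
        yield


@pytest.fixture
def config():
    return ThresholdConfig()


def make_germline(
    gene="CHEK2",
    consequence=Consequence.MISSENSE,
    population_af=None,
    classification=Classification.NONE,
    benign_submitters=0,
    cancer_assoc=False,
    local_count=0,
    genotype=Genotype.HET,
    case_id="case1",
    pos=1000,
    chrom="chr1",
):
    """Convenience constructor for annotated germline records."""
    return GermlineVariantRecord(
        case_id=case_id,
        key=VariantKey(chrom, pos, "C", "T"),
        gene=gene,
        consequence=consequence,
        genotype=genotype,
        population_af=population_af,
        clinvar=ClinVarAssertion(
            classification=classification,
            benign_submitters=benign_submitters,
            has_cancer_syndrome_association=cancer_assoc,
        ),
        local_count=local_count,
    )
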