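"""Screen a handful of annotated germline variants against the panel.

Builds four blood variants — a rare pathogenic NF1 nonsense variant, a
common CHEK2 missense variant, a multi-submitter-benign variant and a
frequent synonymous variant — and runs the full screen: panel/coding/
frequency gates, exclusion rules A-C, triage, reportability.
"""

from twohit.models import (
    Classification,
    ClinVarAssertion,
    Consequence,
    GermlineVariantRecord,
    Genotype,
    VariantKey,
)
from twohit.germline import screen_case
from twohit.resources import default_gene_map, default_knowledge, default_panel


def variant(gene, consequence, pos_offset=500, **kw):
    interval = default_gene_map()[gene]
    clinvar = ClinVarAssertion(
        classification=kw.pop("classification", Classification.NONE),
        benign_submitters=kw.pop("benign_submitters", 0),
        has_cancer_syndrome_association=kw.pop("cancer_assoc", False),
    )
    return GermlineVariantRecord(
        case_id="demo", gene=gene, consequence=consequence,
        key=VariantKey(interval.chrom, interval.start + pos_offset, "C", "T"),
        genotype=Genotype.HET, clinvar=clinvar,
        population_af=kw.pop("population_af", None),
        local_count=kw.pop("local_count", 0),
    )


records = [
    # rare truncating NF1 variant, asserted pathogenic: survives and reports
    variant("NF1", Consequence.NONSENSE,
            classification=Classification.PATHOGENIC, cancer_assoc=True),
    # CHEK2 missense at 2% population frequency: fails the AF < 0.01 gate
    variant("CHEK2", Consequence.MISSENSE, population_af=0.02),
    # benign by three ClinVar submitters: removed by rule A
    variant("BRCA1", Consequence.MISSENSE, population_af=0.001,
            classification=Classification.BENIGN, benign_submitters=3),
    # synonymous variant seen 150 times in the local database: rule B
    variant("TP53", Consequence.SYNONYMOUS, population_af=0.001,
            local_count=150),
]

results = screen_case(records, default_panel(), default_knowledge())
for res in results:
    flag = " REPORTABLE" if res.reportable else ""
    print(f"{res.record.gene:7s} {res.record.consequence.value:10s} "
          f"-> {res.status.value}{flag}")

# Expected output: NF1 ends 'pathogenic REPORTABLE'; the others show which
# gate or exclusion rule removed them (frequency, rule A, rule B).
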