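"""Search a tumor for a second hit against a germline-hit gene.

Constructs tumor evidence for an RB1 germline carrier: a copy-number
segment deleting the RB1 locus with allelic imbalance, plus the germline
variant's allele fraction in the tumor (high, i.e. the pathogenic allele
is retained). The engine classifies the deletion, notes the retained
allele, and integrates a per-(case, gene) verdict.
"""

from twohit.models import CnSegment
from twohit.germline import label_expectation
from twohit.resources import default_gene_map, default_knowledge
from twohit.somatic import CaseOmics, analyze_gene, compute_tmb

gene_map = default_gene_map()
rb1 = gene_map["RB1"]

omics = CaseOmics(
    segments=[
        # 2 Mb segment spanning RB1 at copy number 1 with allelic imbalance
        CnSegment(rb1.chrom, rb1.start - 1_000_000, rb1.end + 1_000_000,
                  total_copy_number=1.0, allelic_imbalance=True),
    ],
    germline_tumor_vaf={"RB1": 0.85},  # pathogenic allele retained
)

verdict = analyze_gene(
    case_id="demo", gene="RB1", omics=omics, gene_map=gene_map,
    expectation=label_expectation("RB1", default_knowledge()),
)
print("hit found:   ", verdict.hit_found)
print("informative: ", verdict.informative)
print("expectation: ", verdict.expectation.value)
print("narrative:   ", verdict.narrative)

tmb, high = compute_tmb(omics.somatic)
print(f"TMB: {tmb}/Mb (high: {high})")

# Expected: hit found True via a focal deletion with the alternative
# allele retained — biallelic RB1 inactivation, second hit expected.
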