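# twohit

Germline cancer-predisposition screening with somatic second-hit
detection for paired tumor/normal multi-omics.

## The problem

Mesenchymal tumors (sarcomas, GISTs and their benign mimics) are rare,
and most appear sporadic. When whole-genome sequencing of blood and
tumor is available for the same patient, a germline pathogenic variant
in a hereditary-cancer gene can be interpreted *in the light of the
tumor*: under the Knudson two-hit model, a causative germline first hit
should be accompanied by a somatic second hit inactivating the
remaining allele — a somatic SNV, a focal deletion, loss of
heterozygosity, silencing by promoter hypermethylation, or aberrant
expression. A germline finding without any second hit is more likely an
incidental carrier state.

`twohit` implements that reasoning as a tested, configurable pipeline
for clinical-genomics analysts and method developers:

1. **Germline screen** — restrict blood variants to a gene panel, keep
   coding (exonic/splicing) variants with population allele frequency
   < 0.01 (missing frequency counts as rare), then exclude variants that
   are (A) benign/likely benign in ClinVar by more than two submitters,
   (B) seen > 100 times in a local assertion database *and* synonymous,
   or (C) benign/likely benign by exactly one submitter *and* seen > 80
   times locally. Survivors are triaged to VUS / likely pathogenic /
   pathogenic (missense without a reported cancer-syndrome association,
   and truncating variants without phenotype relevance or in genes where
   truncation is not the disease mechanism, stay VUS). Reportability
   follows inheritance mode: het suffices for dominant genes; recessive
   genes need homozygosity or two distinct het P/LP variants (flagged as
   unphased potential compound heterozygosity).
2. **Second-hit search** — for each reportable gene, the tumor is
   searched layer by layer: protein-altering/splice somatic variants
   with VAF > 5%, structural variants with VAF > 10%, gene-overlapping
   copy-number segments (copy number below the case ploidy with allelic
   imbalance → focal deletion; copy-neutral imbalance → LOH;
   chromothripsis-like chromosomes and > 25 Mb deletions are
   *uninformative* rather than evidence), cohort expression outliers
   (top/bottom 5th percentile, nearest-rank with ties), and promoter
   hypermethylation (mean beta ≥ 0.6 over ≥ 3 probes within TSS ±
   1500 bp, "consistent with biallelic" when the locus is copy-neutral).
   Tumor mutational burden is the count of somatic variants with depth
   ≥ 10, VAF ≥ 0.05 and gnomAD ≤ 0.1%, divided by 3000 Mb (> 10/Mb is
   TMB-high). Genes without a same-gene hit can be expanded to pathway /
   interaction partners; pathway evidence never upgrades the gene's own
   verdict.
3. **Cohort report** — detection rates (whole cohort and excluding
   benign tumors), an 8 × 2 diagnosis-category table, second-hit rates
   by expectation label, odds ratios with Woolf 95% CIs
   (Haldane–Anscombe correction on zero cells), and a Student's t-test
   on age distributions.

A fully synthetic cohort generator (`twohit.simulate`) plants germline
first hits, second hits of every evidence class, and benign decoys on a
miniature genome with a recorded truth table, so the whole pipeline is
testable without any patient data. `twohit.fixtures` encodes a published
24-carrier case table and its cohort category table for exact count
reproduction.

## Worked example

```python
from twohit.models import CnSegment
from twohit.germline import label_expectation
from twohit.resources import default_gene_map, default_knowledge
from twohit.somatic import CaseOmics, analyze_gene

gene_map = default_gene_map()
rb1 = gene_map["RB1"]
omics = CaseOmics(
    segments=[CnSegment(rb1.chrom, rb1.start - 1_000_000,
                        rb1.end + 1_000_000, 1.0, True)],
    germline_tumor_vaf={"RB1": 0.85},
)
verdict = analyze_gene("demo", "RB1", omics, gene_map,
                       label_expectation("RB1", default_knowledge()))
print(verdict.hit_found, "|", verdict.narrative)
```

prints

```
True | focal_deletion: CN 1.00 vs ploidy 2.00, allelic imbalance
```

i.e. the RB1 locus sits in a one-copy segment with allelic imbalance —
a focal deletion — and the high tumor allele fraction of the germline
variant (0.85) means the pathogenic allele was retained: biallelic RB1
inactivation. More narrative scripts live in `examples/` (germline
screen, second-hit layers, simulate-and-run, cohort report); each
prints the numbers it computes and what they mean.

There is also a thin CLI:

```bash
twohit simulate --seed 1 --n-cases 60 --out-dir cohort/
twohit run-all --cohort-dir cohort/ --out-dir results/
twohit report --results-dir results/
```

## Layout

```
src/twohit/      io_formats, germline, somatic, report, simulate,
                 fixtures, pipeline, cli, config, models, resources
tests/           unit + property + acceptance suites
examples/        narrative scripts, one per capability
docs/methods.md  models, thresholds, design choices, limitations
```
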