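# Methods

## Scope and model

`twohit` operationalizes paired germline–somatic interpretation for
mesenchymal-tumor cohorts. The underlying model is Knudson's two-hit
hypothesis for tumor suppressor genes: a heterozygous pathogenic
germline variant ("first hit") is causally linked to the tumor when the
tumor shows inactivation of the remaining allele ("second hit"). The
pipeline takes *called and annotated* variants as input — alignment,
variant calling and consequence annotation are upstream concerns — and
is deterministic end to end: all randomness lives in the synthetic
cohort generator.

## Germline screen

Variants are gated in a fixed order, and the first gate or rule to fire
is recorded per variant, giving every exclusion an auditable provenance
trace:

1. **Panel gate** — gene must be on the configured panel. Symbols are
   upper-cased once; membership is exact after that. The published
   787-gene panel behind this design is not public, so the package
   ships a documented ~46-gene stand-in (`twohit.resources`) and
   accepts any list.
2. **Coding gate** — exonic or splicing consequences only.
3. **Frequency gate** — population allele frequency strictly < `af_max`
   (default 0.01). A missing frequency is treated as 0: absence from
   population databases is evidence of rarity, which is the gate's
   intent.
4. **Exclusion rules**, evaluated A → B → C with first-hit attribution
   (the rules are alternatives; the fixed order exists for deterministic
   provenance, not precedence of meaning):
   - A: benign/likely-benign ClinVar submitter count > 2;
   - B: local-database occurrence count > 100 **and** synonymous;
   - C: submitter count exactly 1 **and** local count > 80.
   All `>` thresholds are strict, matching their stated inequalities.
   Rules A and C key on the benign-submitter count alone: the count
   field *is* "reported benign/likely benign by N submitters", so no
   separate classification check is applied. Rule C is implemented
   literally ("only one submitter" = exactly 1); whether two submitters
   with a high local count should also exclude is left to rule A's
   threshold.

**Triage.** The pipeline deliberately does not re-derive expert
ACMG/AMP judgement. Missense variants without a reported
cancer-syndrome association are VUS. Truncating variants (nonsense,
frameshift, splice site) are VUS when the gene's syndrome is not
relevant to the patient's phenotype or when truncation is not the
gene's known disease mechanism (a per-gene flag in the knowledge
table). Everything else takes its P/LP status from the pathogenicity
assertion attached to the variant — an overridable input representing
the expert assessment. Synonymous variants that survive rule B are
retained through triage but always classified VUS; they cannot become
P/LP under these rules, so excluding them earlier would only change
bookkeeping.

Phenotype relevance is a per-(case, gene) boolean supplied with the
case metadata (`phenotype_genes`). When absent, the screen falls back
to "the gene has any mesenchymal-tumor association in the knowledge
table", which is the right default for a mesenchymal-tumor cohort but
deliberately coarse — real phenotype matching is a clinical judgement.

**Reportability.** Dominant (and unknown-inheritance) genes report on
any het or hom P/LP variant. Recessive genes report only on
homozygosity or on ≥ 2 distinct het P/LP variants in the same gene,
flagged as *potential* compound heterozygosity: short-read phasing is
out of scope, and the flag preserves that honesty. A single het P/LP
variant in a recessive gene is a carrier state.

**Actionability.** The per-gene `surveillance_exists` flag provides the
default (clinical action vs risk factor); a per-(case, gene) override
in the case metadata represents the manual genotype-plus-phenotype
decision, which cannot be purely gene-level (the same recurrent CHEK2
frameshift is actionable for a carrier with a breast-cancer history and
a risk factor for one without).

**Expectation labels.** Genes with a known or suggested
mesenchymal-tumor association are labelled "second hit expected"; Lynch
syndrome genes are "semi-expected"; all others "second hit not
expected". The label annotates verdicts and stratifies cohort
statistics; it never influences detection.

## Second-hit evidence layers

All thresholds live in `ThresholdConfig`; defaults below.

| parameter | default | meaning |
|---|---|---|
| `snv_vaf_min` | 0.05 | somatic SNV/indel VAF, strict > |
| `sv_vaf_min` | 0.10 | structural-variant VAF, strict > |
| `expr_tail_percent` | 5 | expression outlier tail (each side) |
| `min_expression_cohort` | 20 | below this, expression is "no data" |
| `tmb_min_depth` / `tmb_min_af` / `tmb_max_gnomad` | 10 / 0.05 / 0.001 | TMB quality gates, inclusive |
| `tmb_genome_mb` / `tmb_high` | 3000 / 10 | TMB denominator and high cut (strict >) |
| `hypermethylation_beta_min` | 0.6 | mean promoter beta for a call |
| `promoter_window_bp` / `min_promoter_probes` | 1500 / 3 | promoter definition around the TSS |
| `large_deletion_mb` | 25 | larger deleted segments are uninformative |
| `chromothripsis_min_switches` | 10 | copy-state switches per chromosome |
| `cn_neutral_tolerance` | 0.25 | |CN − ploidy| treated as copy-neutral |

Notes on the choices that were genuinely open:

- **Expression percentile** uses the nearest-rank definition (the
  ⌈p/100·n⌉-th order statistic) with ties included in the tail. At
  cohort sizes around 300 the interpolation scheme is immaterial, but
  it must be fixed for determinism; nearest-rank is the simplest
  definition that makes "the cohort minimum is always in the tail" an
  exact property. Ranking is cohort-wide by default (a histology
  stratification can be done by subsetting the matrix before the call).
- **Chromothripsis-like** has no universal definition; the package uses
  an oscillation heuristic — ≥ 10 switches of rounded copy-number state
  along one chromosome. The flag can only *withhold* evidence (the
  locus becomes uninformative), never create it, so the heuristic's
  looseness is conservative.
- **Large deletions** (> 25 Mb overlap with a deleted state) are
  likewise uninformative: an arm-level loss says little about targeted
  inactivation of one gene. The cut is explicit and configurable.
- **Focal deletion vs LOH** is judged against the *case ploidy*
  (metadata, default 2.0), not against absolute copy number 2: in a
  near-tetraploid tumor, CN 2 with allelic imbalance is a loss. When
  the germline variant's allele fraction in the tumor is supplied, a
  fraction > 0.5 records that the alternative (pathogenic) allele was
  retained — the expected signature of a true second hit.
- **Hypermethylation** requires ≥ 3 probes within TSS ± 1500 bp and
  mean beta ≥ 0.6; the call is labelled consistent-with-biallelic only
  when the locus shows no copy loss, since hypermethylation plus
  deletion is already explained by two DNA-level hits.
- **VAF thresholds are strict** (> 5%, > 10%); the "5% for deletions"
  is read as small indels — copy-number deletions have no VAF.
- **TMB gates are inclusive** (depth ≥ 10 reads "minimal read depth
  10") and a missing population frequency counts as rare.

**Integration.** A per-(case, gene) verdict is positive iff any
positive-evidence layer fired; pathway-expansion findings are labelled
with the partner gene and never upgrade the verdict. A verdict is
*uninformative* only when uninformative copy-number findings are the
sole evidence. Narratives list evidence in a fixed priority order
(SNV → deletion → LOH → SV → expression → methylation) so reports are
byte-reproducible.

## Cohort statistics

Detection rates are reported with explicit numerators/denominators;
the benign-excluded rate restricts both sides to malignant cases.
Percentages round half away from zero to whole percent (so 11/24 →
46%, 12.5% → 13%), matching the reporting style of the category table
this package reproduces. Cases without tumor tissue stay in the
second-hit denominator but are flagged. Odds ratios use the closed form
(a·d)/(b·c) with a Woolf log-OR normal 95% CI; zero cells get the
Haldane–Anscombe 0.5 correction and a flag (cross-checked against
statsmodels in the test suite). The age comparison is the
equal-variance Student's t-test (a Welch option exists but is off by
default). No multiple-testing correction is applied; none is defined
for this descriptive set.

## Synthetic cohorts

`SimConfig` defaults encode the study conditions: 312 cases, carrier
probability 0.08 per case (Bernoulli), second-hit probability 11/24
among carriers, equal mix over the five plantable evidence classes
(SNV at VAF 0.3, focal deletion, copy-neutral LOH, expression pinned to
the cohort minimum, promoter beta 0.9). Every case receives six decoys
— one per gate/rule (common-frequency, rule A, rule B, rule C,
off-panel, non-coding) — so the whole filter funnel is exercised and
recorded in `truth.tsv`.

The generator reproduces the pipeline's decision surface, not
sequencing physics. Per-gene FPKM is log-normal (log-mean ~N(1.5, 1),
log-sd 0.5); baseline promoter betas are Beta(2, 20) clipped at 0.5;
somatic passengers (Poisson mean 30 per case) are intergenic. Two
pinning choices make truth exact rather than probabilistic: carrier
genes without a planted expression hit sit at the per-gene cohort
median, and baseline promoters cannot reach the hypermethylation
threshold. Consequently "100% recovery, 0 false positives" certifies
the *engine's* correctness against planted truth — it does not estimate
real-data sensitivity or specificity, where noise, subclonality and
annotation error all erode performance. There are no reads, no
mutational signatures and no subclonal structure.

Synthetic coordinates live on a 12-chromosome miniature genome
(~30 Mb nominal chromosomes, 100 kb genes); no real reference is
shipped, and the genome-build label is carried as an opaque string.

## Fixture reconstruction

`twohit.fixtures` encodes the published 24-carrier table verbatim and
derives machine-readable inputs from it: germline records on synthetic
coordinates, and per-case tumor evidence bundles built so the engine
reproduces the printed second-hit column (these are reconstructions,
not patient data — e.g. printed "Deletion RB1" becomes a one-copy
imbalanced segment over the synthetic RB1 locus). The 312-case cohort
reconstruction follows the published category table exactly; since
malignancy is not broken down by category there, the 15 benign
background cases needed beyond the explicitly benign categories are
placed in the gynaecological tract as uterine leiomyomas. One printed
actionability value (the third recurrent CHEK2 frameshift carrier)
differs from the gene default and is carried as a per-case clinical
override.

## Numerical and degenerate-input conventions

- Internal coordinates are 0-based half-open everywhere; VCF (1-based)
  and segment-TSV (BED-like) conventions are converted at the I/O
  boundary, and round-trips are identity (htslib's 32-bit INFO floats
  are renormalized to 6 significant digits on read).
- Annotation side tables win over embedded INFO keys on conflict.
- Genes uncovered by any segment, expression cohorts under 20 samples,
  and promoters with fewer than 3 probes yield explicit no-data
  outcomes, never silent negatives.
- Empty cohorts, zero-denominator rates and degenerate t-test groups
  raise or flag rather than returning NaN.

## Limitations

- Pathogenicity ultimately rests on the assertion inputs; the package
  contains no ACMG/AMP criterion engine.
- Compound heterozygosity is declared without phasing.
- MSI / mismatch-repair immunohistochemistry evidence is representable
  only as an external case annotation, not computed.
- The stand-in panel and knowledge table are starting points; real
  deployments should supply curated versions.
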