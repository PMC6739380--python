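# Methods

## The design and the model

The extreme-discordant sibling design compares siblings who are concordant
for a monogenic risk genotype but discordant for the clinical phenotype, in
several unrelated families at once. For a biallelic site with genotype
states hom_ref / het / hom_alt / missing, define per family f and phenotype
group g (affected or non-affected):

- **recessive (shared homozygosity):** every member of group g in family f
  is hom_alt;
- **dominant (shared variants):** every member of group g in family f
  carries at least one alternate allele (het or hom_alt).

A missing genotype in a group member makes the family fail the model — the
family is not dropped from the denominator. A variant is *called* for group
g when its carrier (dominant-sense) families number at least k of the N
families (defaults k = 3, N = 4). Model assignment is recessive-first over
the confirming set: if every confirming family is homozygous-alternate the
call is recessive, otherwise dominant. This rule keeps the two model blocks
disjoint per (variant, group) while matching how gene-prioritization tools
print homozygous rows under the recessive block and mixed rows (for
instance three hom_alt families plus one heterozygous family) under the
dominant block.

**Exclusivity.** A discriminating variant should not be confirmable in the
opposite group. `same_model` (default) requires the opposite group to fail
the call's model in at least N−k+1 families; `any_model` requires failure of
both models; `none` disables the check. Exclusivity is recorded per call and
does not remove calls from the output, but the pipeline's enrichment step
queries only group-exclusive genes, because the design's question is what
distinguishes the groups.

**Families with several same-group siblings.** The model must hold in *all*
same-group members of a family (strictest reading of "shared"); a
`member_rule="any"` option accepts a single satisfying sibling.

**Gene-level rescue in table mode.** Worked-example genotype tables list one
column per family. A row whose non-blank cells satisfy a model in fewer than
k families is normally dropped; with `rescue_subthreshold` (default in table
mode) such a row is kept — flagged `subthreshold` — when another variant of
the same gene is confirmed in the same group. This mirrors gene-centric
prioritization, where a gene confirmed by one variant keeps its other
qualifying variants in the report, and is how the bundled affected-group
table yields 15 recessive variants over 14 genes although one row shows only
two genotype cells.

## Filter cascade

Stage order is fixed and every stage logs (stage, variants remaining):

| stage | rule |
|---|---|
| total | input biallelic variants (multiallelics split on read) |
| drop_low_quality | calls with GQ < 20 are set to missing; variants with no carrier call left are dropped |
| drop_unconfirmed_transcript | annotation `transcript_status != confirmed` |
| drop_utr | annotation region is 5' or 3' UTR |
| functionally_annotated | checkpoint: variants with no annotation row are counted and dropped here |
| high_confidence | max alternate-allele depth over carriers must exceed 30 (strict; `min`/`sum` aggregation configurable; fail-open when no carrier depth exists) |
| non_synonymous | consequence class synonymous dropped; unknown consequence vocabulary is an explicit error, never silently synonymous |
| drop_minor_in_reference | alternate-allele population frequency > 0.5 (the reference carries the minor allele); ties at exactly 0.5 are kept |

The Q20 threshold is applied as a genotype-quality floor because base-level
filtering happens upstream in the caller. The coverage rule reads
"alternative allele coverage > 30" as the maximum alt-supporting depth over
carrier samples, strict inequality; per-sample aggregation is configurable
because the aggregate was never specified.

**QC summaries.** Per-sample mean depth, fraction of genotyped sites ≥ 20X,
and uniformity, declared as the fraction of sites with depth ≥ 0.2 × the
sample's mean depth (a common vendor convention; stated in the report header
because definitions vary). Ti/Tv counts A↔G and C↔T as transitions over
SNVs only and is reported as undefined when there are no transversions.

**Frequency classes.** novel = no GMAF and no catalogue id; rare = GMAF ≤ 1%
(boundary inclusive — the prose definition; one table header prints "< 1%");
else common. GMAF is a *minor* allele frequency and must lie in [0, 0.5].

## Over-representation and the enrichment map

The ORA statistic is the exact hypergeometric upper tail (scipy's survival
function; no normal approximation), with BH step-up q-values (statsmodels).
The universe defaults to all genes carrying at least one post-cascade
variant — the background was never specified upstream, so the report
declares it. Sets are intersected with the universe first; sets with fewer
than 3 or more than 500 genes after intersection are skipped (configurable).
Only over-representation is tested. The enrichment map uses the overlap
coefficient |A∩B| / min(|A|,|B|) with the conventional 0.375 cutoff
(Jaccard available by flag); nodes are sets with q ≤ 0.05.

## Synthetic cohorts

The generator reproduces the study conditions the pipeline targets:

- 4 unrelated families, 9 siblings (the first family contributes two
  non-affected members), one affected sibling per family;
- background variants: allele frequency Uniform(0.02, 0.20) — low enough
  that shared-carriage false positives stay rare in a 9-exome cohort while
  every Hardy–Weinberg genotype class stays populated; genotypes are
  independent HWE draws per individual (families are unrelated and no
  explicit IBD/transmission model is simulated — sufficient for testing the
  caller, not a meiosis model);
- depths: negative binomial with mean 105 and shape 8, matching a deep
  exome run, so the coverage filter is exercised realistically; het alt
  depths are Binomial(depth, 1/2); SNV substitution types are weighted 0.7
  toward transitions (Ti/Tv ≈ 2.3);
- planted variants: 2 per (model, group) by default, forced to satisfy
  their spec in k = 3 randomly chosen families, hom_ref in the remaining
  family and in the entire opposite group (hence exclusive); carrier depths
  are floored at 80 so planted variants pass the coverage filter by
  construction;
- cascade fates: each background variant is assigned a stage fate
  (5% low quality, 10% unconfirmed transcript, 10% UTR, 3% unannotated,
  7% low alt coverage, 25% synonymous, 5% reference-minor, remainder
  surviving) and its annotation/genotype fields are crafted accordingly; the
  manifest records the stage at which each variant must fall, derived from
  the realized data by the generator's own plain reading of the rules;
- gene sets: one planted set containing all planted genes plus 4 background
  genes, and 20 decoy sets of 12 background genes each; the curated list
  holds half the planted genes plus 10 background genes;
- missingness (default 0) masks background genotype calls at random.

Every emitted variant appears in exactly one manifest entry. What passing
tests show: the caller and cascade recover exactly what was planted under
clean, independent genotypes. What they do not show: robustness to LD,
relatedness-induced genotype correlation, caller artifacts, or annotation
errors — none of which are simulated.

## Numerical and reporting conventions

- Percentages: group summaries round half-up to the nearest integer
  (57, 29, 43, 24); fraction breakdowns use one decimal, round half-up
  (49.5, 66.7). Counts are exact integers.
- The cascade, classifier and report renderer are deterministic: identical
  inputs and configuration give byte-identical outputs; the only randomness
  in the package is the generator's seeded RNG.
- Problem sizes used by the test suite: 400 background variants for the
  default cohort, 60-variant cohorts across 200 seeds for recovery
  properties, 5000 variants for the Hardy–Weinberg goodness-of-fit
  aggregate, and 100 seeded runs for planted-set detection power — sizes at
  which every statistical check has comfortable margin while the whole suite
  runs in seconds.
- Degenerate inputs: an empty VCF yields an all-zero trace and a complete
  report; an empty query gene list yields an empty enrichment table with a
  warning; a family absent from the pedigree is an error.

## Known limitations

- Strictly biallelic after splitting; no de-novo, compound-heterozygote or
  X-linked models (sex chromosomes are treated as autosomal, with an option
  to exclude them).
- Gene symbols are compared case-sensitively with no alias resolution;
  curated lists must match the annotation's symbols.
- Annotations are inputs; the package computes no consequence predictions or
  deleteriousness scores (CADD/DANN/PROVEAN are carried as opaque fields).
- The worked-example tables carry only the listed group's genotypes, so
  exclusivity is not evaluable in table mode and is reported as unset there.
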