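# Methods

This document describes the models implemented in `autozyg`, the default
parameter values, the reasoning behind the main design choices, and known
limitations. Nothing here is an empirical claim beyond what the package
itself computes.

## 1. Pedigree model

A pedigree is a set of individuals, each with either no parents (a
founder) or exactly two in-pedigree parents, with sexes consistent with
parental roles and no ancestry cycles. The built-in generator
(`sim.build_pedigree`) produces a focal couple (`FA`, `MO`) with a
configurable sibship; the couple can be unrelated, first cousins
(default) or more distant cousins. First cousins are constructed
explicitly: one shared founder couple (`ANC-1`, `ANC-2`), two of their
children married to unrelated spouses, and the focal couple as the
resulting first cousins — 16 individuals for an eight-child sibship.
Affection status is assigned during variant planting (below).

PED I/O uses the 6-column whitespace-delimited convention
(family, individual, father, mother, sex 1/2, affection 0/1/2).

## 2. Genome and marker map

The simulated genome is autosomal and build-agnostic: `n_chromosomes`
(default 4) each of `chrom_length_bp` (default 100 Mb) and
`chrom_length_morgans` (default 1.0), with `markers_per_chromosome`
(default 1,000) evenly spaced bi-allelic SNPs, i.e. 0.1 cM between
adjacent markers. Physical position maps linearly to genetic position.

Marker alternate-allele frequencies come from a two-component mixture:
with probability 0.5 a "common" frequency ~ Uniform(0.05, 0.5), otherwise
a "rare" frequency ~ Uniform(0, 0.001). Each site gets an annotation
payload: a consequence class drawn from a configurable categorical
distribution (missense 0.50, synonymous 0.35, 5' UTR 0.03, 3' UTR 0.05,
near-splice intronic 0.02, deep intronic 0.03, nonsense 0.01, frameshift
0.005, splice-site 0.005), a reference-population homozygote count
(Hardy–Weinberg expectation over a 60,000-individual reference, with rare
variants only occasionally assigned homozygotes), an in-house cohort
carrier count (binomial over 1,000 individuals), and a distance to the
nearest exon boundary for intronic classes. The mixture and class
proportions are chosen so that every branch of the filter cascade is
exercised by background variation.

## 3. Gene dropping

Founder chromosomes are labelled haplotypes represented as segment lists
(breakpoint bounds plus founder-haplotype labels), not per-marker arrays,
so identity-by-descent is tracked exactly and continuously. Each meiosis
draws a crossover count ~ Poisson(length in Morgans) with breakpoint
positions uniform on the chromosome (Haldane's no-interference model) and
a fair-coin starting phase, then splices the two parental haplotypes.
Genotypes at markers are read off by interval lookup of founder-haplotype
labels into lazily drawn founder allele matrices.

An individual is autozygous wherever its two haplotypes carry the same
founder label; the realized inbreeding coefficient is the autozygous
fraction of the genome. For first-cousin offspring its expectation is
1/16; `estimate_inbreeding` recovers this by Monte-Carlo (the package's
acceptance suite checks agreement within three standard errors over
1,000 replicates).

## 4. Variant planting and conditioning

A rare, fully penetrant recessive variant (annotated population frequency
3/187,624 ≈ 0.0016%, missense by default) is placed on one haplotype of a
founder (`ANC-1` by default) at a uniformly drawn off-marker position on
a chosen chromosome. The generator conditions the family on a target
affected count (default 5 of 8 children) using *staged* conditional
sampling:

1. the ancestor-to-focal-couple meioses on the planted chromosome are
   redrawn until both focal parents carry the planted haplotype
   (per-attempt probability 1/16 for first cousins);
2. a uniformly random subset of children of the target size is designated
   affected;
3. each child's planted-chromosome gametes are redrawn until its planted
   genotype matches its designation (homozygous if affected, probability
   1/4 per attempt; not homozygous otherwise, probability 3/4).

Whole-family rejection sampling (redraw everything until exactly the
target number of children is homozygous) has success probability
C(8,5)·(1/4)^5·(3/4)^3 ≈ 2.3 × 10⁻² *given* carrier parents, but only
≈ 10⁻³·(1/16) unconditionally per full redraw including all chromosomes
and the sibship, and it badly skews runtime. The staged scheme samples
from the same conditional distribution because chromosomes segregate
independently and children are exchangeable; the other chromosomes and
all non-planted markers remain untouched by the conditioning. Attempts
are bounded (default 10,000 per stage) and exceeding the bound raises an
error rather than silently returning.

A truth record (JSON) stores the planted site, the true genotype of every
individual at it, and every individual's exact autozygous segments.

## 5. Genotyping noise and VCF emission

Observed genotypes are the true genotypes passed through a symmetric
mis-call model (per-call error rate 0.002, errors move one allele-count
step), with per-call missingness 0.005. Depths are Poisson with mean 60;
alt-supporting reads are Binomial(depth, p) with p = 0.001 (sequencing
error floor) for hom-ref, 0.5 (allele balance) for het, and 0.999 for
hom-alt. Output is plain-text VCF 4.2 with `FORMAT GT:AD:DP` and INFO
keys `CSQCLASS`, `EXAC_AF`, `EXAC_HOM`, `INHOUSE_N`, `DIST2EXON`; reading
uses cyvcf2. A `NOISELESS` model is provided for exact-recovery tests.

## 6. Runs of homozygosity

The per-sample ROH rule: a span of consecutive non-missing calls
qualifies when it contains at least `min_snps` (default 25) calls of
which at most `max_het` (default 2) are heterozygous; missing calls are
skipped entirely (they neither interrupt nor count). The implementation
enumerates *maximal* qualifying spans directly from the heterozygote
index list in O(n), and an O(n²) brute-force oracle in the test suite
verifies equivalence on random instances. Overlapping maximal spans are
merged into regions for reporting (a merged region may contain more than
`max_het` heterozygotes by construction). Shared ROH across the sequenced
affected individuals is the exact interval intersection of their merged
regions, computed per chromosome with a two-pointer sweep. Coordinates
are 1-based inclusive.

## 7. Filter cascade

Five ordered exclusion rules (defaults in parentheses):

1. `low_alt_support` — fewer than 3 alt reads in *any* sequenced affected;
2. `common_or_recurrent` — reference-population AF > 0.05 **or** seen in
   more than 30 in-house individuals (one rule, two OR-joined clauses);
3. `population_homozygote` — any homozygotes in the reference population;
4. `synonymous`;
5. `utr_or_deep_intronic` — 5' UTR, or intronic more than 2 bp from an
   exon boundary. 3' UTR variants are retained by default (switchable).

Attribution is first-fail: each excluded variant is charged to the first
rule (in the configured order) whose predicate it fails, so the per-rule
counts plus survivors always sum to the input count. Because the rules
are independent predicates of the variant, permuting the order changes
attribution but never the surviving set; both properties are tested.

## 8. Candidate prioritization and segregation

A final candidate must (a) survive the cascade, (b) be homozygous-
alternate in every sequenced affected sample, and (c) lie inside a shared
ROH. Candidates are reported with a provenance trail naming the shared
region and samples. The top candidate is then checked for autosomal-
recessive co-segregation in a follow-up genotyping subset (the sibship's
mother, the sequenced affecteds, one further affected and one unaffected
sibling): affecteds must be homozygous-alternate, unaffecteds must not
be, unaffected parents of affecteds must be heterozygous, and child
genotypes must be Mendelian-consistent with typed parents. Missing
genotypes impose no constraint. An exhaustive trio enumeration against an
allele-level oracle covers all 54 fully typed cases in the tests.

## 9. Hand anthropometry

Nineteen hand bones per side (metacarpals 1–5, proximal phalanges 1–5,
middle phalanges 2–5, distal phalanges 1–5) are standardized against a
norm table of (bone, sex, age) → (mean, SD) in millimetres; ages between
tabulated rows are linearly interpolated and ages outside the table are
an error (no extrapolation). The bundled norm table is synthetic —
adult-plausible mean lengths with a coefficient of variation of 0.07, a
0.92 female/male size ratio and a mild age trend over ages 20–80 — and is
intended for simulation and testing, not clinical use; real analyses
should supply a published norm table in the same TSV format.

Pattern profiles (z per bone per hand) are compared between affected and
unaffected groups: the brachydactyly flag fires when the affected group
mean z is at least 1.0 SD below the unaffected group mean, and any bone
at z ≤ −5 is reported as markedly shortened. The simulator draws
unaffected bones in the z band [−1, 1] and affected bones in [−3, −1],
and by default pins two canonical outliers (−5.3 SD right PP1 of the
first sequenced affected, −7.0 SD left MC1 of the second) so the
round-trip from simulated lengths back to z-values is exact.

The five-patient clinical cohort table bundled with the simulator
(heights 160, 149, 157, 161, 155.5 cm — mean 156.5 cm — plus ocular and
joint feature flags) is a fixed reference dataset used for summary
statistics, not a random draw.

## 10. Randomness and reproducibility

Every run is driven by one integer seed. The master
`numpy.random.Generator` is split (`spawn`) into four child streams in a
fixed order — annotations, gene drop (which internally splits founder
alleles from meioses), genotyping noise, measurements — so changing, say,
the noise model cannot perturb the pedigree's meioses. The replicated
recovery experiment derives per-run seeds as `(base_seed + run) mod 2³¹`.
Identical config and seed reproduce every output file byte-for-byte
(tested).

## 11. Limitations

- No sequence-level simulation: no reads, alignment or variant calling;
  noise is injected at the genotype/AD/DP level.
- Bi-allelic autosomal sites only; no X-linked inheritance, no
  multi-allelic records, no structural variants.
- Haldane's model ignores crossover interference; marker spacing is
  uniform, unlike real exome capture.
- The annotation model is parametric, not drawn from a real population
  reference; absolute attrition counts depend on its mixture settings.
- The norm table and clinical cohort are synthetic/fixed reference data;
  clinical conclusions require real norms and measurements.
- Full penetrance is assumed throughout; the segregation checker has no
  notion of reduced penetrance or phenocopies.
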