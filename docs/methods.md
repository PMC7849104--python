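# Methods

This note documents the statistical procedures implemented in `moranprio`,
the defaults and the reasoning behind them, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## 1. Summary statistics and harmonization

The canonical internal effect scale is the log odds ratio; the OR is a
derived view (`or = exp(beta)`). Harmonization refers every record to the
risk-increasing allele: records with OR < 1 have alleles swapped and beta
negated, records with OR = 1 are kept unflipped with their stated effect
allele (the tie direction is immaterial downstream because the rank
transform assigns tied ORs a common mid-rank score). p, se and MAF are
untouched by harmonization — MAF is allele-label-free. The QC filter applies
a strict MAF cut (`maf > 0.05` by default, so MAF = 0.05 exactly is removed)
and an inclusive imputation-quality cut (`info >= 0.91`); records without an
info score pass the info criterion.

## 2. Association and meta-analysis

Per-SNP association is a logistic regression of case status on additive
allele dosage (0/1/2) plus caller-supplied covariates, fit by Newton-Raphson
(log-likelihood tolerance 1e-8, max 100 iterations, via statsmodels).
Separation — detected by a failed fit, non-finite estimates, or |log OR| >
20 — yields a flagged NA record rather than an exception, so genome scans
continue past degenerate SNPs; a rank-deficient covariate matrix is a
configuration error and raises. On a single binary exposure the fit
reproduces the closed-form 2×2-table OR and Woolf standard error, which the
test suite uses as an oracle.

The genomic inflation factor is λ = median(χ²)/F⁻¹(0.5; χ²₁), with p-values
converted through the inverse χ²₁ survival function.

Meta-analysis is DerSimonian–Laird: fixed-effect weights w = 1/se², Cochran's
Q about the fixed-effect mean, τ² = max(0, (Q − df)/(Σw − Σw²/Σw)),
random-effect weights w\* = 1/(se² + τ²). DL was chosen because it is the
default of the standard meta-analysis packages in this field; the
implementation is validated against `statsmodels.stats.meta_analysis` in the
tests. A single study passes through with τ² = 0.

## 3. The Local Moran's Index

**Transform.** "Standardizing the OR with the inverse of the normal
distribution" is implemented as a rank-based inverse-normal transform:
z = Φ⁻¹((rank − ½)/n) over the harmonized ORs ranked ascending, with
mid-ranks for ties. The ½ offset keeps z finite at both extremes; the
transform is applied genome-wide (not per chromosome), so z has median ≈ 0
over the whole scored set. Because the transform is monotone, splitting on
the median of z is identical to splitting on the median of the OR
distribution itself.

**Weights and neighborhoods.** A SNP's neighbors are the other scored SNPs
on the same chromosome within ±500 kb (boundary inclusive) whose panel MAF
differs by at most 0.05 from the focal SNP's. The MAF tolerance realizes
"matched by MAF" as an absolute band; 0.05 keeps haplotype frequencies
comparable without starving low-MAF SNPs of neighbors. Weights are r²
computed from panel dosages over pairwise-complete individuals; a pair with
fewer than two complete individuals or zero dosage variance has undefined LD
and simply contributes nothing (it never zeroes the denominator). Scored
SNPs that are absent from the panel, have panel MAF < 1%, or end up with
zero total weight are reported as *not estimable* rather than silently
dropped.

**Index and selection.** LMIᵢ = zᵢ · Σzⱼr²ᵢⱼ/Σr²ᵢⱼ. Two exclusion rules
follow: (1) LMI < 0 — the neighborhood is discordant or unlinked; (2)
LMI ≥ 0 but zᵢ strictly below the median z of all scored SNPs — a
concordant but low-effect cluster. The median itself is retained. The final
selection keeps the top floor(fraction · n) retained records by LMI
(fraction 0.005 by default), with deterministic tie-breaking by smaller
association p then lexicographic id, and reports the implied LMI threshold.
The algebra gives two exact invariants used as tests: a neighborhood with
zⱼ ≡ zᵢ yields LMI = zᵢ², and rescaling every z by c rescales every LMI by
c².

**Implementation note.** The production path computes windows per chromosome
from sorted positions; the test suite checks it against an all-pairs
double-loop oracle with the same predicates (agreement to 1e-10 on 50
random fixtures).

## 4. Credible sets

For a lead SNP, the region is the lead plus every scored SNP within ±500 kb
with r² > 0.1 to the lead (strict inequality; undefined LD excludes). Each
member's Wakefield asymptotic Bayes factor is computed from its log-OR and
standard error under a normal effect prior N(0, W); W defaults to 0.04
(prior SD 0.2 on the log-OR scale), the convention of summary-statistic
fine-mapping under a single-causal-variant assumption. Posteriors are the
BFs normalized over the region; the credible set is the smallest
posterior-descending prefix reaching mass 0.99. Ties in posterior break by
smaller p then id. Overlapping sets from nearby leads are reported
separately, never merged. The set records whether it contains the region's
smallest-p SNP, which is the headline concordance diagnostic between
p-value-based and LMI-based prioritization.

## 5. Benchmarking machinery

**Median-rank permutation test.** Given a best-first ranked list and a set
of known hits, the statistic is the hits' median (1-based) rank. The null is
the median rank of same-size SNP sets drawn uniformly without replacement
from the same ranked list — the sampling frame is the supplied list, not any
larger universe. When C(n, k) ≤ 10,000 all subsets are enumerated and the
p-value is exact; otherwise B draws (default 10,000) with the +1-corrected
estimator p = (1 + #{null ≤ observed})/(B + 1), which is never zero.
"Better" means a smaller median rank.

**LD clumping.** Independent signals are obtained greedily: visit SNPs by
score descending (ties by id) and keep a SNP iff its r² with every
already-kept SNP on the same chromosome within ±500 kb is strictly below
0.2. LD beyond the window or undefined in the panel is treated as zero —
distal same-chromosome LD is ignored for tractability.

**Rank tests.** The Wilcoxon rank-sum comparison of MAF/OR distributions
and the Spearman correlation between LMI and −log p are thin wrappers over
scipy with an explicit policy: exact enumeration for tie-free pooled samples
of size ≤ 12, normal approximation with tie and continuity corrections
otherwise.

## 6. Chromatin-interaction overlap

The 3D layer consumes interaction *calls* (fixed-width cis bin pairs with a
p-value, 40-kb bins by default); Hi-C map construction and interaction
calling are upstream and out of scope. Bonferroni filtering computes
adjusted_p = min(1, p·m) and retains adjusted_p < 1e-5; m defaults to the
number of supplied pairs. (Retaining on p < α/m would be algebraically
identical.) To compare tissues with different calling depth, the
matched-fraction rule keeps the same top fraction of a second list, sorted
by p ascending, as was retained in a reference list — floor rounding, so a
tiny list may keep nothing.

A SNP overlaps a pair when its position falls inside either bin under the
half-open [start, end) convention, the SNP position being compared directly
against the bin coordinates (a SNP at exactly the end coordinate does not
overlap); the containing bin is the bait, the partner the target. Target
bins are annotated with genes from a BED file on any ≥ 1 bp overlap, listed
by start coordinate.

## 7. The synthetic-data generator

**Genotype model.** Each LD block draws a small pool of founder haplotypes
(per-SNP allele frequencies uniform in a configurable range, or an explicit
0/1 founder matrix); every individual samples two founders uniformly with
replacement, and each allele copy flips independently at the block's
mutation rate. Few founders ⇒ strong within-block LD; mutation erodes LD
smoothly, reaching near-independence at 0.5. SNPs sit 2 kb apart within a
block with 2-Mb gaps between blocks, so the ±500 kb LMI window never spans
blocks by construction. With mutation 0, every haplotype is literally a
founder (an assertable invariant), and sample MAFs converge to founder-pool
frequencies. `exact_freq_block` builds a 10-founder pool with an exact
carrier count, giving dosages that are exactly Binomial(2, f) — used where a
condition specifies an exact allele frequency. One global seed spawns
ordered per-stage sub-seeds, so the panel and the phenotypes are each
independently reproducible and the full pipeline is bit-reproducible.

**Phenotype model.** Case status is Bernoulli with
P(case) = logistic(intercept + Σβ·g + covariate effects); covariates are age
~ Normal(60, 10) (centered at 60 in the linear predictor), sex ~
Bernoulli(0.5), and a three-level region entered as two indicators, all with
zero effect by default. When a target case fraction is set, the intercept is
re-centered by the sample mean of the linear predictor so the expected case
fraction matches the target.

**The low-MAF cluster scenario** builds the regime the LMI is designed for:
one block of 16 SNPs whose minor alleles all ride a single rare founder
haplotype (carrier frequency 0.035 per haplotype copy, so each SNP's MAF
falls in the 0.02–0.05 band; within-block mutation 0.005), a shared causal
effect of ln(1.7) planted on the middle cluster SNP, one common variant
(MAF 0.3) with effect ln(1.3), and 30 null blocks of 25 SNPs each (16
founders, mutation 0.03) as background, with n = 1000 individuals at a 50%
case fraction. The effect size is deliberately below the reliable per-SNP
detection threshold at this sample size: each cluster SNP alone gives a
mediocre p-value that interleaves with the best of ~750 null SNPs, while
the cluster's LD-concordant inflated ORs give its members dominant LMI
scores. That contrast — not raw power — is the property of interest, and it
is what the "LMI median rank beats −log p median rank" tests measure. A
null background of this size is also what makes the comparison meaningful:
with few nulls, both rankings trivially place the cluster on top and the
comparison degenerates into ties.

**What the generator does not emulate:** coalescent realism (recombination
maps, demography, mutation-age structure), genotyping error and
missingness patterns, imputation uncertainty, population stratification,
and ascertainment (phenotypes are population draws at ~50% prevalence, not
case-control sampled). Passing tests therefore demonstrate the algebraic and
statistical behaviour of the methods under controlled LD, not performance
on real cohort data.

## 8. Numerical choices and degenerate inputs

- r² is clamped to [0, 1] against floating-point overshoot; undefined LD is
  an explicit error type (`LDUndefinedError`), never silently 0 or 1.
- HWE is the 1-df chi-square goodness-of-fit test; monomorphic variants
  return p = 1 by convention (they carry no HWE information).
- Monomorphic dosages in association scans yield flagged NA records.
- Credible-set cumulative-mass comparison uses a 1e-12 slack so that mass =
  1.0 reliably returns the full region under floating-point summation.
- The permutation benchmark, top-fraction selection, clumping, and gene
  annotation all have deterministic tie rules (documented at each function)
  so identical inputs give identical outputs.
- Genomic coordinates are 1-based inclusive internally (VCF convention);
  BED/BEDPE inputs are half-open as supplied.

## 9. Problem sizes used by tests and the acceptance script

Test fixtures use panels of tens to hundreds of SNPs over 8–5,000
individuals; the oracle-equivalence suite runs 50 random fixtures of 50–150
SNPs; parameter recovery uses 100 replicates at n = 5,000; benchmark
calibration uses 200 replicates of a 400-SNP list; the cluster scenario runs
50 seeds of a 767-SNP study. These sizes were chosen so every statistical
property is measured with meaningful replication while the whole suite stays
interactive.

## 10. Known limitations

- The 2-SE Wald interval for a logistic log-OR is mildly anti-conservative
  at n = 5,000 (measured coverage ≈ 95.0–95.1% against the 95.45% normal
  ideal), so recovery rates quoted against a 95% bar have essentially no
  slack; this is a property of Wald intervals, not of the data generator.
- The LMI weight matrix uses panel r² as-is; no shrinkage for panel size, so
  a small reference panel inflates r² and with it LMI for rare variants.
- MAF matching is an absolute tolerance; ratio- or bin-based matching may be
  preferable when the scored set spans a very wide frequency range.
- Clumping ignores LD beyond ±500 kb; long-range LD (e.g. inversions) can
  leave correlated "independent" signals.
- Credible sets assume a single causal variant per region and a shared prior
  W across SNPs; multi-causal fine-mapping is out of scope.
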