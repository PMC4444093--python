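# Methods

## Scope and data model

The pipeline analyzes biallelic SNVs in the six carnitine acyltransferase
genes. All counting is *derived-allele* oriented: each variant carries an
explicit `derived_is_alt` flag instead of assuming ALT = derived, because
the cataloged frequencies are stated relative to the reference-genome
derived allele. Coordinates are 1-based inclusive everywhere; a variant
belongs to a gene when it falls within the gene's region ± a flank
(default 2,000 bp). Multi-allelic records are rejected rather than
decomposed — the analysis is defined for biallelic SNVs, and silent
decomposition changes allele counting.

Missing genotypes stay missing through QC; allele frequencies use called
chromosomes as the denominator. The burden statistic, by contrast, keeps
the full individual count in its denominator while missing genotypes
contribute zero alleles — a deliberately conservative convention (a
missing call can only lower, never raise, a cohort's burden).

## Genotype QC

A genotype is masked when any available metric fails: depth < 20 reads,
GQ < 10, or — for calls carrying at least one ALT allele — alternate-read
fraction < 0.25. The 25% rule is interpreted as the *per-genotype
alternate-read fraction* (the standard exome-QC reading of a "variant
frequency" filter), not a cohort-level MAF cut; hom-ref calls are exempt
since they have no alternate reads to fractionate. Filtering is
idempotent and masked-call counts are logged.

The Hardy–Weinberg exact test conditions on the observed allele counts
and sums the probabilities of all heterozygote counts no more probable
than the observed one (the standard exact-test convention); it is
computed in log space with a stabilized normalizer and verified against
exact-rational enumeration for all configurations with N ≤ 50.

Ancestry screening uses classical (Torgerson) metric MDS of the
allele-sharing distance d(i,j) = 1 − IBS(i,j)/2, the usual choice for
genotype panels of this size; coordinates are made deterministic by a
sign convention. Outlier flagging is a robust rule of our own design
(visual inspection is not reproducible): an individual is flagged when it
lies more than k·MAD (default k = 6, MAD scaled by 1.4826 so k·MAD ≈ k·σ
under normal spread) from its claimed cluster's medoid on either of the
first two axes. With the default k, a half-admixed individual between two
well-separated clusters is flagged while ordinary within-cluster spread
is not; the planted-admixture test exercises exactly this.

## Rarity and burden

A variant is **rare** iff its minor-allele frequency is ≤ 0.01
(inclusive) in *every* reference population; absence from a panel counts
as frequency 0. Rarity is purely reference-based — a variant at 95.5% in
the study cohort but absent elsewhere is rare. The per-gene burden is the
mean number of rare *missense* derived alleles per individual.

Significance machinery:

- **Binomial**: exact upper tail P(X ≥ k | 2N_A, p₀) with p₀ the
  comparison cohort's pooled per-gene rare-allele frequency. The pooled
  per-gene null (rather than per-variant) reproduces the published
  magnitudes; one-sided because the hypothesis is an *excess* of burden.
  p₀ = 0 with observed alleles is degenerate and returns 0 with a
  warning.
- **Permutation**: individuals pooled and relabeled into groups of the
  original sizes; statistic B_A − B_B; empirical
  p = (1 + #{perm ≥ obs}) / (1 + n_perm), never below 1/(n_perm+1).
  Default n_perm = 10⁵. The published analysis names an "adaptive"
  permutation scheme without specifying it; we implement plain
  fixed-count permutation with an optional early-stop flag (abort once
  the add-one estimate can no longer reach a requested α).
- **Bonferroni**: min(1, m·p) with m = number of variant-containing
  genes.

The burden *ratio* column is computed from burdens rounded to 3 decimals,
matching how the published table's arithmetic behaves (0.05/0.007 = 7.14).

Known data inconsistency: the published Asian *CPT2* burden (0.017) does
not follow from the published p.S122F frequency of 0.6%
(round(572·0.006) = 3 alleles → 0.010). The generators use the published
frequency, so the pipeline reports 0.010 here; the discrepancy is in the
source tables, not resolvable downstream.

## F-statistics

Four per-variant F_ST estimators ship because published values in this
literature rarely name one, and at strong differentiation the standard
formulas genuinely diverge (they agree to first order in F_ST only):

- `wright`: (H_T − H_S)/H_T with unweighted pooled frequency;
- `nei_gst`: the same with sample-size-weighted pooling;
- `weir_cockerham`: θ = a/(a+b+c), two-population variance components,
  observed heterozygosity when genotypes are available (HWE-expected
  otherwise);
- `hudson`: ratio-of-moments with sample sizes in chromosomes.

For the flagship contrast (0.955 vs 0 at 100 vs 83 individuals) the four
estimators span [0.914, 0.955], bracketing the published 0.9171. The
arithmetic mean of the published 13-variant F_ST column is 0.0951, so the
published "mean" rows (0.1833, 0.8401) are not arithmetic means of that
column; multi-locus summaries are therefore reported both as
ratio-of-sums over Weir–Cockerham components and as arithmetic means of
defined loci. Monomorphic loci are undefined (NaN) and excluded from
summaries, never coerced to 0.

F_IS = 1 − H_obs/H_exp with the small-sample-unbiased
H_exp = 2pq·2N/(2N−1) by default (switchable); the two bias conventions
bracket the published per-variant values. Significance is by
randomization: population labels permuted for F_ST; alleles re-paired
among individuals within the population for F_IS (breaking genotypic
correlation while preserving allele counts). Both use the add-one
estimator with guaranteed minimum 1/(n_rand+1); default 1,000
randomizations.

## Haplotypes and LD

Haplotype frequencies over L ≤ 12 loci come from the classic EM algorithm
on the multinomial haplotype-pair likelihood under HWE. Initialization is
uniform over the compatible haplotypes and phase ties are resolved only
by frequency-product weights, so the procedure is fully deterministic;
the log-likelihood is asserted non-decreasing at every iteration, and
convergence is max |Δf| < 10⁻⁸ (cap 1,000 iterations). Individuals
missing a call at any of the loci are dropped (and counted). Two-locus
solutions are verified against an exhaustive likelihood grid over the one
free parameter.

Pairwise D, D′, r² follow the standard definitions on EM haplotype
frequencies; LOD is the log₁₀ likelihood ratio of those frequencies
against linkage equilibrium evaluated on the genotype data. D′ confidence
intervals use a profile likelihood over |D′| ∈ [0, 1] (201-point grid)
with allele frequencies fixed at sample estimates and the sign of D at
its MLE, taking the 5th/95th percentiles of the normalized likelihood — 
the Gabriel-map convention; a seeded 200-resample bootstrap is available
as an alternative. Blocks follow the confidence-interval rules with the
published thresholds: strong LD when the CI is [≥ 0.6, ≥ 0.98], strong
recombination when the upper bound is < 0.9, block accepted when ≥ 95% of
informative pairs are strong, markers under 5% MAF excluded from pair
counting; maximal non-overlapping blocks are reported left to right,
widest first.

Haplotype-frequency contrasts are offered both as an exact one-sample
binomial tail (comparison frequency treated as fixed) and as a pooled
two-proportion z test, since either convention could underlie published
values of this kind.

## Score comparison

The Mann–Whitney U test uses midranks and, for combined samples of ≤ 20
observations, enumerates all C(n₁+n₂, n₁) group assignments of the
observed value multiset — valid under ties, which matter here because
PolyPhen-2 scores pile up at 1.0 (tabulated no-tie critical values do
not apply). Larger samples use the normal approximation with tie
correction. Both sidedness options are reported. The χ² comparison is
Pearson's on the 2×2 allele table (optional Yates correction); zero-margin
tables are undefined and rejected.

## Synthetic cohorts

The generators emulate the statistical structure the analyses assume, at
the study's own scale:

- **exact_count** mode places exactly round(2N·p) derived alleles,
  split into the HWE-closest genotype configuration
  (hom = round(N·p̂²)); heterozygote counts can be overridden per variant
  or set via a target F_IS, since the published F_IS values imply
  near-HWE configurations but the underlying hom/het splits were not
  published. This mode makes burden statistics deterministic.
- **hwe_sampling** draws genotypes i.i.d. from (q², 2pq, p²); generated
  cohorts pass the HWE exact test with super-uniform p-values.
- **haplotype cohorts** draw 2N haplotypes i.i.d. from a specified
  distribution (defaults: the published four-haplotype *CPT2* structure
  at N = 100) and retain the phased truth beside the unphased matrix.
- **admixed individuals** draw genotypes under HWE at the λ-mixed
  frequency (1−λ)p_A + λp_B.

Default cohort sizes (100 Inuit-like, 286 Asian-like comparison, 83 for
the F-statistic contrast) and all frequencies are the published study
conditions, recorded in `acylpop.catalog`. Seeds are mandatory and
outputs are reproducible bit-for-bit.

What the generators do **not** model: linkage between the
independent-variant cohorts' sites, genotyping error, missingness,
coalescent/demographic structure, or sequencing reads. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling models — not robustness to real-data artifacts such as
batch effects, call-rate structure, or cryptic relatedness.

Variant genomic positions and ref/alt alleles were not published; the
catalog uses synthetic placements inside the published gene regions,
chosen to preserve the published LD-block spans (~8 kb for the *CPT1B*
trio, ~1 kb for *CPT2* p.F352C/p.V368I) and the published *CPT2*
haplotype alphabet (T-G-C / T-A-C / G-A-C / T-G-T).

## Numerical choices and edge cases

- HWE and binomial tails in log space; probabilities clipped at 10⁻³⁰⁰
  before logs.
- Resampling tie comparisons use a 10⁻¹² slack so that exact-equality
  permutations count as "at least as extreme" (conservative).
- EM re-seeds a genotype class uniformly if all its compatible pairs hit
  zero frequency (cannot occur from uniform init, guards pathological
  inputs).
- Degenerate inputs raise (`ValueError`) rather than returning silent
  zeros: empty cohorts, all-missing variants, zero-margin χ² tables,
  monomorphic loci in LD, clusters with < 3 members.
- Problem sizes in the test suite and acceptance script: burden nulls at
  10⁵ permutations; null-calibration at 1,000 replicates of 199/99
  resamples on cohorts of 60/40; EM recovery at N = 100 (study scale)
  with a N = 10,000 convergence check. These sizes give stable results
  while keeping the default suite to well under a minute of compute.

## Known limitations

- No hierarchical (3+ population) F-statistics or jackknife CIs.
- No phasing of individual genotypes — only population haplotype
  frequencies.
- The Gabriel block search is exhaustive over contiguous spans, fine for
  gene-scale marker counts but not genome-wide use.
- The exact Mann–Whitney enumerates C(n₁+n₂, n₁) assignments and is
  capped at 20 combined observations.
- Sex-mismatch screening and variant annotation are out of scope;
  consequence classes and deleteriousness scores are inputs.
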