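# Methods

This note states exactly what each module computes, in the order the
pipeline runs. Positions are 1-based throughout and genomic regions are
closed intervals, matching VCF coordinates.

## Genotype QC (`variant_io`)

Input is a biallelic-SNP VCF (read with cyvcf2; multi-allelic and indel
records are skipped with a logged count). Genotypes are stored as int8
dosages of the ALT allele (0/1/2, −1 missing) with per-genotype allele
depths when the `AD` FORMAT field is present.

Filters, applied in this order:

1. **Missingness** — drop SNPs whose missing fraction exceeds a threshold
   (default 0.10), optionally computed as the worst per-population
   missingness rather than overall.
2. **MAF** — drop SNPs with minor-allele frequency below a threshold
   (default 0.05), computed over non-missing genotypes.
3. **HDPlot paralog filter** — per SNP, `H` is the heterozygote proportion
   and `D = (x − N/2) / sqrt(N/4)` where `x` is the summed reference-allele
   read count and `N` the summed total reads over heterozygous individuals.
   A collapsed paralog shows excess `H` and/or |`D`| far from 0 (reads from
   the two loci are not a fair 1:1 coin). SNPs with `H > 0.6` or
   `|D| > 5` are flagged.
4. **LD pruning** — within sliding windows (default 50 SNPs, step 5), while
   any pair has dosage r² above the threshold (default 0.5), the
   lower-MAF member of the worst pair is dropped (ties drop the later
   position). Used to build a near-independent SNP set for PCA and Ne.

Population assignment accepts a metadata table with sampling site and
population columns, plus an optional ancestry-proportion (Q) matrix:
individuals are assigned to a population only when their maximum ancestry
proportion strictly exceeds a threshold (default 0.85); others are left
unassigned and excluded from population-level statistics.

## Differentiation and diversity (`popgen_stats`)

**Weir–Cockerham FST.** Per locus, the variance components

- `a` (among populations), `b` (among individuals within populations), and
  `c` (within individuals)

are computed from sample sizes, allele frequencies and heterozygote
frequencies per population exactly as in the 1984 variance-components
formulation (`nc` correction included). Multi-locus FST is the ratio of
sums Σa / Σ(a+b+c). Confidence intervals are percentile bootstrap over
loci (default 1,000 resamples, seeded).

**Basic diversity.** Per population: observed heterozygosity `Ho`, and
small-sample-corrected gene diversity
`Hs = ñ/(ñ−1) · (1 − Σp² − Ho/(2ñ))` with ñ the population sample size.
Overall `Ht` uses the harmonic mean of sample sizes; `Dst = Ht − mean(Hs)`;
the size-corrected `D'st` and `F'st = D'st/H't` follow the standard
`np/(np−1)` corrections. `Fis = 1 − Ho/Hs` with a bootstrap CI over loci.

**βWT.** The population-specific differentiation coefficient from
allele-matching proportions: with `M_i` the within-population matching and
`M_B` the between-population average, `β_i = (M_i − M_B)/(1 − M_B)`,
combined over loci as a ratio of sums, bootstrap CI over loci.

**Kinship.** A method-of-moments IBD estimator on pruned SNPs: per pair,
IBS counts are converted to expected `z0/z1/z2` IBD-state probabilities
using factorial-moment small-sample corrections, solved sequentially,
clipped to [0,1] and renormalized; `PI_HAT = z2 + z1/2`.

## Structure and outlier scan (`popstruct`)

Genotypes are mean-imputed per SNP, centred, and scaled by
`sqrt(p(1−p))`; PCA is the SVD of the centred matrix. The outlier scan
regresses each SNP's standardized dosages on the first K PC scores,
collects the K z-scores per SNP, and measures each SNP's robust
Mahalanobis distance (minimum covariance determinant estimate of
location/scatter of the z-matrix). Distances are divided by a genomic
inflation factor (median distance over the χ²_K median), converted to
χ²_K p-values, and FDR-adjusted by Benjamini–Hochberg. Each significant
SNP is annotated with the PC it loads on most strongly.

## Linkage disequilibrium (`linkage`)

Pairwise r² is the squared Pearson correlation of dosage columns
(complete-data matrix fast path; pairwise-complete fallback under
missingness), scoped within-chromosome, between-chromosome, or to a
region, with an optional reporting floor.

**Decay fit.** Observed (distance, r²) pairs are fitted by least squares
to the Hill–Weir expectation for sample size n (chromosomes):

    E[r²](C) = [(10+C) / ((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))]

with `C = ρ·d` and ρ ≥ 0 the single free parameter (several log-spaced
starts; best RSS kept). Note the expectation asymptotes to ~1/n, not 0:
the sampling floor remains at infinite distance. Half-decay and
moderate-LD (0.20) distances are solved from the fitted curve by
bisection to 1 bp.

**LD-based Ne.** On inter-chromosomal (unlinked) pairs after a MAF screen,
the drift component is `r²_drift = mean(r²) − E[r²_sample]` with
`E[r²_sample] = 1/S + 3.19/S²` for sample size S, and

    Ne = (1/3 + sqrt(1/9 − 2.76·r²_drift)) / (2·r²_drift).

The CI treats `mean(r²)` as χ²-distributed with an effective number of
independent comparisons. The pairwise comparisons share loci and
individuals and are strongly positively correlated, so the effective
degrees of freedom is taken as the number of loci, not the number of
pairs (the latter is known to give far-too-narrow intervals). This is the
package's own choice; coverage is verified by simulation in the test
suite.

## Selection scan (`selection_scan`)

All statistics are unpolarized. For a core SNP, haplotypes are grouped by
identity over the SNP set extending outward from the core; with group
sizes `n_h` among `n` haplotypes, `h = Σ n_h(n_h−1) / (n(n−1))` and
`EHHS = h(x)/h(core)`. Extension stops below a cutoff (default 0.05) or at
a >200 kb position gap. `iES` is the trapezoidal integral of EHHS over bp
in both directions. XP-EHH per SNP is `ln(iES_A) − ln(iES_B)` (difference
of logs, so swapping populations negates it exactly), standardized by its
genome-wide mean and SD; two-sided normal p-values are FDR-adjusted.
Candidate regions are 100-kb windows advanced by 10 kb containing ≥3
significant SNPs, merged when overlapping; each region reports its
majority favored population.

## Inversion test (`inversion_call`)

Four steps over a configured region (default chr8:15,260,000–15,900,000):

1. **Regional LD** — mean/max pairwise r² inside the region versus the
   same-chromosome background, with the reporting floor echoed.
2. **Karyotyping** — PCA restricted to region SNPs; k-means with k = 3 on
   PC1 scores (100 seeded restarts); clusters ordered along PC1 and
   labelled homokaryotype A / heterokaryotype / homokaryotype B.
   Discreteness = between-cluster sum of squares over total. A useful
   calibration: the optimal 3-level quantizer of a continuous Gaussian
   explains ~81% of its variance, so discreteness ≥ ~0.9 indicates
   genuinely trimodal scores.
3. **Heterozygosity contrast** — per-individual heterozygous fraction over
   region SNPs, compared between clusters by two-sided Wilcoxon rank-sum
   tests (normal approximation with tie correction). The inversion
   signature is confirmed when the middle cluster's median exceeds both
   homokaryote clusters at p < 0.05 in both comparisons.
4. **Arrangement frequencies** — karyotype proportions per sampling site
   and per population; the "assumed derived" arrangement is the
   homokaryotype with lower mean regional heterozygosity (exact ties are
   reported as ties).

## Forward simulation (`forward_sim`)

A bit-packed Wright–Fisher engine: haplotypes are uint64 words, one bit
per locus. Each generation: migration (per-individual probability of
moving, destination uniform among other populations; or a full rate
matrix), then reproduction with separate male/female parent pools (equal
sexes), free recombination implemented as a random bitmask between the
two parental haplotypes, and symmetric two-state flip mutation applied by
binomial event counts. Initial assignment is maximally variable (each
locus at frequency 1/2) or fixed frequencies.

**Migration-rate inference.** For each rate in
{0, 0.0001, 0.001, 0.002, 0.003, 0.004, 0.005, 0.01, 0.02, 0.03}, ≥5
seeded replicates of the two-population design (N = 4,500 and 350, 930
generations, 200 two-state loci, μ = 3.28e-9) are run and the multi-locus
Weir–Cockerham FST of the final generation averaged; the selected rate is
the one whose mean falls inside the observed FST interval (fallback:
closest to the interval midpoint, with the full table reported).

**Synthetic cohorts.** The inversion-cohort generator lays out background
SNPs under a Balding–Nichols model at a target background FST, and a
58-SNP region whose haplotypes are drawn whole from one of two
arrangement-specific pools diverged by haploid drift to a target FST
(default 0.8); the arrangement segregates as a single Mendelian locus, so
heterokaryotypes carry one haplotype from each pool. Read depths are
Poisson, allele-balanced for true heterozygotes; optional paralog
artifacts (all-heterozygous carriers with 2:1 read ratios) and
missingness are applied after ground truth is captured. A null-cohort
generator draws two labelled samples from one panmictic pool.
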