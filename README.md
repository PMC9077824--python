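# radpop

Population-genomic analysis of RAD-capture SNP cohorts: genotype QC,
differentiation and diversity statistics, structure and outlier scans,
linkage-disequilibrium decay and LD-based effective population size,
cross-population haplotype selection scans, a four-step chromosomal-
inversion test, and a forward Wright–Fisher simulator for migration-rate
inference and synthetic-cohort generation.

## What it does

Starting from a biallelic-SNP VCF and a sample metadata table, the
pipeline:

1. **Filters genotypes** — per-SNP missingness and minor-allele-frequency
   thresholds, an HDPlot paralog filter (excess heterozygosity H and
   read-ratio deviation D from allele depths), and greedy LD pruning.
2. **Quantifies differentiation** — Weir–Cockerham FST from the a/b/c
   variance components (ratio of sums across loci, bootstrap CIs),
   hierfstat-style diversity statistics (Ho, Hs, Ht, Dst, F'ST, FIS),
   population-specific βWT, and method-of-moments kinship.
3. **Scans structure** — genotype PCA and a PC-regression outlier scan:
   per-SNP z-scores on K components, robust Mahalanobis distances,
   genomic-inflation correction, χ²_K p-values, Benjamini–Hochberg
   q-values.
4. **Measures LD** — pairwise dosage r², a Hill–Weir decay-curve fit
   (half-decay and moderate-LD distances), and an LD-based Ne estimate
   from unlinked (inter-chromosomal) pairs with a χ² confidence interval.
5. **Scans for selection** — unpolarized EHHS profiles around each SNP,
   trapezoid-integrated iES, standardized XP-EHH between two populations,
   and candidate regions (100-kb windows, 10-kb step, ≥3 FDR-significant
   SNPs, merged).
6. **Tests for an inversion** — over a configured region: regional LD vs
   background, regional PCA + k-means (k = 3) karyotyping with a cluster-
   discreteness statistic, Wilcoxon heterozygosity contrasts between
   karyotype clusters, and arrangement frequencies per site/population.
7. **Simulates** — a bit-packed forward Wright–Fisher engine (migration,
   free recombination, two-state flip mutation) used both to infer the
   migration rate compatible with an observed FST interval and to
   generate fully ground-truthed synthetic cohorts (inversion, paralog
   artifacts, missingness, read depths).

The mathematical details of every estimator are in
[docs/methods.md](docs/methods.md).

## Worked example

Everything below is generated from scratch — no data downloads. First emit
the synthetic fixture cohorts (a two-population cohort of 150 individuals
carrying a 58-SNP inversion polymorphism on chr8, plus a structureless
null cohort):

```sh
$ radpop make-fixtures --seed 0 --out fixtures
fixtures written under fixtures
```

Run the four-step inversion test over the default region:

```sh
$ radpop inversion --vcf fixtures/inversion_cohort/cohort.vcf \
    --metadata fixtures/inversion_cohort/metadata.tsv \
    --out results --seed 0
{
 "region": "chr8:15,260,000-15,900,000",
 "ld": {
  "mean_r2": 0.6552811627889713,
  "max_r2": 1.0,
  "background_mean_r2": 0.08031870467875121,
  "n_region_pairs": 334,
  "n_background_pairs": 508,
  "report_floor": 0.05
 },
 "discreteness": 0.9954245332947852,
 "wilcoxon": {
  "pvalues": {
   "HOM_A_vs_HET": 1.1596320920258346e-08,
   "HET_vs_HOM_B": 1.3555786261087153e-08,
   "HOM_A_vs_HOM_B": 6.299452782088233e-08
  },
  "medians": {
   "HOM_A": 0.05357142857142857,
   "HET": 0.37037037037037035,
   "HOM_B": 0.019433962264150943
  },
  "confirmed": true,
  "low_power": false,
  "alpha": 0.05
 },
 "assumed_derived": "HOM_B"
}
```

All four inversion signatures are present: region LD (mean r² 0.66) far
above the chromosomal background (0.08); three near-perfectly discrete
PC1 clusters (discreteness 0.995; a continuous cline would sit near 0.81,
the variance explained by the best 3-level quantization of a Gaussian);
the middle cluster's heterozygosity (median 0.37) significantly exceeds
both homokaryote clusters; and the lower-heterozygosity homokaryotype is
reported as the putative derived arrangement.

Differentiation statistics on the same cohort:

```sh
$ radpop stats --vcf fixtures/inversion_cohort/cohort.vcf \
    --metadata fixtures/inversion_cohort/metadata.tsv \
    --out results --seed 0
{
 "fst": {
  "point": 0.06280457810811164,
  "ci": [
   0.045403987757594765,
   0.08105688311138981
  ],
  "n_loci": 974
 },
 "diversity": {
  "Ho": 0.34190267095788773,
  "Hs": 0.3420044700590087,
  "Ht": 0.3534658127705002,
  "Dst": 0.011461342711491518,
  "Fstp": 0.06281441399642361,
  "Fis": 0.0002976542999668652,
  "Fis_ci": [
   -0.00525774931657263,
   0.006083240637308686
  ]
 },
 "seed": 0
}
```

Other subcommands: `radpop filter`, `radpop structure`, `radpop ld`,
`radpop scan` (XP-EHH between two populations, needs a phased complete
VCF), `radpop simulate` (migration-rate grid search), and `radpop all`
(the analysis stages in dependency order). `radpop <cmd> --help` lists
options; a YAML config (`--config`) can set any default.

The same functionality is available as a library:

```python
from radpop import forward_sim as fs
from radpop.popgen_stats import wc_fst

cohort = fs.simulate_null_cohort(seed=7)
print(wc_fst(cohort.gm, cohort.pm, n_boot=100, seed=0).point)  # ~0.0
```

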