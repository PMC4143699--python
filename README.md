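# fbatrare

Family-based association tests for rare variants (FBAT-rare) in large
extended pedigrees, with unweighted and frequency-weighted collapsing, a
disjoint 100-kb sliding-window genome scan, a replicate-based power /
type-I-error evaluation harness, and a gene-dropping simulator of
extended-family study designs.

## Who this is for

Statistical geneticists analysing whole-genome sequence data from family
studies of quantitative traits (blood pressure is the motivating example),
where rare variants (founder minor-allele frequency < 0.01) are individually
untestable and population-based burden tests are vulnerable to
stratification. Conditioning offspring genotypes on parental genotypes makes
the test immune to stratification while pedigrees naturally enrich rare
alleles.

## The statistic

Rare variants of a unit (a gene or a 100-kb window) are combined linearly
into one pseudo-marker per individual,

    X = Σ_k w_k x_k ,

where `x_k` is the minor-allele count at variant *k* and the weights are

* **v0** (unweighted burden): `w_k = 1`;
* **v1** (Madsen–Browning):   `w_k = 1 / √(ζ p_k (1 − p_k))`,

with `p_k` the founder minor-allele frequency and `ζ` the total number of
nuclear families. Each nuclear family *i* contributes

    u_i = Σ_j T_ij (X_ij − E[X_ij | parents]) ,

where `T_ij` is the offset-centred quantitative trait of offspring *j* and
the expectation follows Mendelian transmission given the parental genotypes.
The two-sided score test is `Z = U/√V` with `U = Σ u_i` and `V` either the
model-based conditional variance `Σ_ij T_ij² Var(X_ij | parents)` or the
empirical sum of squares `Σ u_i²`; `Z` is referred to the standard normal.

The window scan tiles a chromosome into disjoint 100-kb windows anchored at
coordinate 0 ([0, 100 kb), [100 kb, 200 kb), …), tests each variant-bearing
window like a gene, and Bonferroni-corrects by the number of tested windows.
Across phenotype replicates, a unit's *power at threshold τ* is the fraction
of replicate p-values strictly below τ; its *summary detection threshold* is
the smallest power of ten detected in more than half the replicates.

## Worked example

`examples/02_window_scan.py` simulates a 239-kb gene spanning four absolute
100-kb windows whose nine causal rare variants cluster in two of them, then
compares the whole-gene burden with the per-window scan:

```
gene-level  BIG_GENE: 38 rare variants, Z=+2.38, p=1.73e-02
window 3:47800000-47900000: 12 rare variants, Z=+0.02, p=9.85e-01, Bonferroni p=1.00e+00
window 3:47900000-48000000:  9 rare variants, Z=+0.56, p=5.76e-01, Bonferroni p=1.00e+00
window 3:48000000-48100000:  8 rare variants, Z=+4.67, p=2.98e-06, Bonferroni p=1.19e-05
window 3:48100000-48200000:  9 rare variants, Z=-0.39, p=6.94e-01, Bonferroni p=1.00e+00

best window 3:48000000-48100000: Bonferroni-adjusted p = 1.19e-05 vs gene-level p = 1.73e-02
```

The causal-dense window keeps the signal (Z = 4.67) that the diluted
whole-gene test spreads over 38 variants (Z = 2.38); even after multiplying
by the four tested windows, the window p-value is three orders of magnitude
smaller. The other examples cover single-gene testing
(`01_gene_burden_test.py`), multi-replicate power/type-I evaluation
(`03_power_and_type1.py`) and covariate adjustment
(`04_covariate_adjustment.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
fbatrare simulate --preset map4_like --seed 7 --out study/
fbatrare test-genes --vcf study/genotypes.vcf --ped study/pedigree.ped \
    --pheno study/phenotypes.tsv --regions study/regions.bed --scheme v1 --out genes/
fbatrare test-windows --vcf study/genotypes.vcf --ped study/pedigree.ped \
    --pheno study/phenotypes.tsv --chromosome 3 --out windows/
fbatrare evaluate --results genes/gene_results.tsv --truth study/truth.tsv --out eval/
```

Every output directory receives a `manifest.json` (config, input digests,
seed, version); identical invocations produce identical result files.

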