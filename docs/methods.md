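# Methods

## The family-based score test

For a quantitative trait `Y` and a (possibly collapsed) marker `X`, each
nuclear family — one father–mother pair and their common offspring — makes
the contribution

    u_i = Σ_j T_ij (X_ij − E[X_ij | G_father, G_mother]),

where `T_ij = Y_ij − μ` is the offset-centred trait of offspring *j*.
Offspring genotypes are conditioned on the observed parental genotypes under
Mendelian transmission: a parent carrying `c ∈ {0,1,2}` copies of the minor
allele transmits it with probability `c/2`, independently of the other
parent, so for a single variant

    E[x | par] = (c_f + c_m)/2,
    Var(x | par) = 1[c_f = 1]/4 + 1[c_m = 1]/4.

Because the conditioning fixes the parental genotypes, transmitted-allele
deviations have mean zero whatever the population structure — the test is
robust to stratification by construction. The statistic is

    Z = U / √V,   U = Σ_i u_i,

summed over informative families (those with positive conditional variance),
and `p = 2(1 − Φ(|Z|))`. Two variance estimators are exposed:

* `model` (default): `V = Σ_ij T_ij² Var(X_ij | parents)` — exact when
  transmissions are independent across the collapsed variants, which holds
  in the simulator (no linkage disequilibrium) and approximately for sparse
  rare variants;
* `empirical`: `V = Σ_i u_i²` — robust to between-variant transmission
  correlation (linked variants inside one collapsed unit), at some cost in
  stability for small family counts.

Assumptions and conventions:

* **Both parents genotyped.** A family missing either parent at any
  collapsed variant is excluded as uninformative. Sufficient-statistic
  conditioning for missing parents (Rabinowitz–Laird) is a documented
  extension point, not implemented; the motivating data are fully
  typed/imputed.
* **Offspring missingness.** An offspring missing any collapsed variant or
  the trait is dropped from that unit's test only.
* **Trait offset.** `μ` defaults to the sample mean of all offspring
  entering the test (per replicate); a fixed offset is available for
  sensitivity analysis. Mean-centring is the neutral choice for a
  quantitative trait with no natural reference level.
* **Normal approximation.** `Z` is referred to N(0,1); no exact small-sample
  p-value is computed. A reporting floor of `min_informative = 10`
  informative families (configurable) suppresses units where the
  approximation is untrustworthy; such units carry status
  `below_min_families` and no p-value. p-values are clamped to the smallest
  positive double rather than reported as 0.
* An individual who is an offspring in one nuclear family and a parent in
  another contributes as offspring only in the family of its own parents;
  elsewhere its genotype only conditions its children. Extended pedigrees
  are thus decomposed into nuclear families, deliberately discarding
  between-family information (a known cost of the nuclear-family treatment).

## Collapsing and weights

Variants with founder minor-allele frequency strictly inside (0, 0.01) are
combined as `X = Σ_k w_k x_k`. The founder population (pedigree members
without parents in the data) defines both the frequency and the minor-allele
orientation; ties at 0.5 orient to the VCF ALT allele. Weights:

* v0: `w_k = 1` (plain burden);
* v1: `w_k = 1/√(ζ p_k (1 − p_k))` with `ζ` the total number of nuclear
  families in the dataset — the Madsen–Browning inverse-square-root form,
  which equalises the expected variance contribution of each variant and
  thereby up-weights the rarest. A plain reciprocal form
  (`weight_form="linear"`) is provided for sensitivity checks because the
  weight is sometimes printed without the radical; the square-root form is
  the default and the one used throughout the evaluation.

`Z` and `p` are invariant to rescaling all weights by a positive constant;
collapsing a single variant with unit weight reproduces the raw
single-marker test exactly (the pipeline is composed from the same
operations, so the identity holds bit-for-bit).

## Window scan

Chromosomes are tiled into disjoint fixed-size windows (default 100 kb)
anchored at absolute coordinate 0, never at gene starts. Coordinates are
handled 0-based half-open internally; VCF positions are converted by
subtracting 1, and a variant exactly on a boundary belongs to the right-hand
window. Windows without rare variants are skipped (counted in the log); each
tested window is Bonferroni-corrected by the number of *tested* windows —
an observable quantity, unlike the number of windows that happen to contain
causal variants. When a scan is restricted to one gene, the correction
factor is the number of variant-bearing windows overlapping that gene.
Whole windows are tested wherever they overlap a gene; genes are not
truncated at window boundaries.

## Power and type-I metrics

Replicate p-values of a unit are summarised by the fraction strictly below
each threshold in a decreasing power-of-ten series (default 10⁻⁷…10⁻⁴).
Untestable replicates count as non-detections (conservative power). The
summary detection threshold is the smallest threshold whose fraction
strictly exceeds 0.5; a unit with no qualifying threshold is "not
detected". Type-I error pools noncausal unit × replicate tests (untestable
tests are excluded from the denominator — unbiased size); a per-unit
breakdown is also emitted because either pooling convention is defensible.

Phenotype adjustment takes ordinary-least-squares residuals of the trait on
intercept + sex + age + medication use, per replicate (one shared design
matrix, so all replicates are solved at once). Constant covariates are
dropped with a warning; medication is treated as a binary use flag.

## The simulator

`simdata` stands in for restricted family-study data. It emulates:

* **Pedigrees** — 20 extended pedigrees built top-down from a founder
  couple; each non-terminal offspring marries an unrelated incoming founder;
  offspring counts are uniform on a configurable range. Defaults give 5
  generations and ~1000 members overall.
* **Genotypes** — gene dropping: founder haplotypes are Bernoulli draws at
  the configured frequency per variant; nonfounders inherit one uniformly
  chosen allele from each parent, independently across variants. There is no
  linkage disequilibrium, recombination, genotyping error or missingness.
* **Phenotypes** — `Y = μ + β_sex·sex + β_age·age + β_med·med + Σ β_k x_k +
  a_fam + ε` with a shared within-pedigree effect `a_fam ~ N(0, 4²)` and
  residual `ε ~ N(0, 8²)` (blood-pressure-like scale, mmHg; baseline 120).
  Covariates are drawn once; genotypes are fixed across replicates; family
  effects and noise are redrawn per replicate. Everything is reproducible
  byte-for-byte from (config, seed).

Three named scenarios define the evaluation conditions; their parameters
were fixed by design-stage power calculations (targeting the regime where
the phenomena of interest are expressed but unsaturated) and then frozen:

* `null` — 4 generations (~450 members), 50 genes × 25 rare variants (MAF
  uniform on (0.002, 0.01)), all effects zero, 20 replicates. With ~25
  informative families per gene every gene clears the reporting floor and
  the normal approximation is well calibrated at α = 0.05.
* `weight_favoring` — 5 generations, 20 genes × 18 variants; in the 10
  causal genes the 6 rarest variants (MAF 0.002–0.004) carry β = 15 mmHg
  per allele while 12 commoner rare variants (MAF 0.006–0.009) supply
  burden noise that the unweighted test cannot discount. This is the regime
  inverse-frequency weighting was designed for; the expected noncentrality
  advantage of v1 over v0 is ≈1.4×.
* `map4_like` — one 239-kb gene spanning four absolute 100-kb windows with
  9 causal variants (MAF 0.0035–0.0055, β = 9) clustered in two windows
  (eight of them in a single window free of neutral variants), 31 neutral
  rare variants diluting the other three windows, plus two small noncausal
  genes. Denser sibships (2–3 offspring, ~1800 members) keep realized
  founder frequencies of causal variants safely under the 0.01 filter.
  Effect sizes of this magnitude are in line with the large rare-variant
  effects reported for blood-pressure genes.

What passing tests on these data do **not** show: behaviour under linkage
disequilibrium between collapsed variants (the model-variance estimator
would be anticonservative there — use `variance_mode="empirical"`),
ascertained sampling, imputation error, Mendelian inconsistencies, or
dichotomous traits.

## Numerical and interface choices

* Regions and windows are 0-based half-open; VCF positions 1-based.
  `tile_windows(chrom, max_position)` treats `max_position` as a 0-based
  coordinate and ends with the window containing it.
* Founder MAF estimation requires ≥1 genotyped founder; variants with none
  are flagged (NaN) and excluded from collapsing, as are monomorphic
  variants. The rare filter is strict: `0 < p < threshold`.
* Weight computation rejects `p ∈ {0, 1}` rather than silently clamping.
* Nuclear families are ordered by (family, father, mother) and offspring
  lexicographically, making every pipeline output deterministic given its
  inputs; the simulator splits its seed into independent streams for
  pedigrees, genotypes and phenotypes.
* The CLI's statistical subcommands take no seed (they are deterministic);
  `simulate` requires one.

## Known limitations

* No Rabinowitz–Laird conditioning for partially typed families; missing
  parents simply remove a family.
* Bonferroni is the only multiplicity control; no FDR or permutation
  calibration across windows.
* Overlapping windows (stride < size), variable-threshold and
  dispersion-style (SKAT-type) tests are out of scope.
* The power metric is threshold-based by design; it says nothing about
  effect-size estimation.
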