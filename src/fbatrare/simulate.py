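"""Gene-dropping simulator for extended pedigrees with rare-variant genotypes
and replicated quantitative phenotypes.

The generator emulates the structure of a large family study of blood
pressure: 20 extended pedigrees of up to 5 generations (~1000 genotyped
members by default), genes carrying rare variants with declared founder
frequencies, and replicated quantitative traits driven by a subset of causal
rare variants plus sex/age/medication covariates, a shared within-pedigree
random effect, and independent residual noise:

    Y = mu + b_sex*sex + b_age*age + b_med*med + sum_k beta_k x_k + a_fam + eps

Founder haplotype alleles are drawn independently per variant at the
configured frequency; each nonfounder inherits one uniformly chosen allele
from each parent, with transmissions independent across variants (no linkage
disequilibrium or recombination modelling).  Genotypes are fixed across
phenotype replicates; covariates are drawn once; the family effect and noise
are redrawn per replicate.  Everything is reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    Region,
    Variant,
    _orient_to_minor,
    read_genotypes,
    read_regions,
    write_regions,
    write_vcf,
)
from .pedigree import Individual, Pedigree, read_pedigree, write_ped
from .phenotypes import TraitTable, read_trait_table, write_trait_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSpec:
    """Explicit layout of one simulated gene: positions, frequencies, effects."""

    name: str
    start: int  # 0-based half-open span
    end: int
    positions: tuple[int, ...]  # 1-based, as in VCF
    mafs: tuple[float, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.mafs) == len(self.betas)):
            raise ValueError(f"gene {self.name!r}: positions/mafs/betas lengths differ")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError(f"gene {self.name!r}: duplicate positions")
        for p in self.positions:
            if not (self.start < p <= self.end):  # 1-based p inside [start, end)
                raise ValueError(f"gene {self.name!r}: position {p} outside span")
        for m in self.mafs:
            if not (0.0 < m < 0.5):
                raise ValueError(f"gene {self.name!r}: maf {m} outside (0, 0.5)")

    @property
    def causal(self) -> bool:
        return any(b != 0.0 for b in self.betas)

    def region(self, chromosome: str) -> Region:
        return Region(name=self.name, chromosome=chromosome, start=self.start, end=self.end)


@dataclass(kw_only=True)
class SimConfig:
    """Study design of a simulated dataset (the seed is mandatory)."""

    seed: int
    n_pedigrees: int = 20
    generations: int = 5
    offspring_range: tuple[int, int] = (1, 3)
    chromosome: str = "3"
    # explicit gene layout, or an auto-generated one from the fields below
    genes: list[GeneSpec] | None = None
    n_genes: int = 50
    variants_per_gene: int = 10
    maf_range: tuple[float, float] = (0.002, 0.01)
    gene_span: int = 20_000
    gene_spacing: int = 180_000
    first_gene_start: int = 1_000_000
    causal_gene_names: tuple[str, ...] = ()
    beta: float = 0.0
    causal_maf_max: float | None = None
    # trait model
    trait_mean: float = 120.0
    covariate_effects: tuple[float, float, float] = (4.0, 0.4, -5.0)  # sex, age, medication
    age_range: tuple[float, float] = (20.0, 80.0)
    medication_rate: float = 0.3
    family_effect_sd: float = 4.0
    residual_sd: float = 8.0
    n_replicates: int = 200

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("need at least 2 generations to produce nonfounders")
        if self.family_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        lo, hi = self.offspring_range
        if not (1 <= lo <= hi):
            raise ValueError("offspring_range must satisfy 1 <= low <= high")


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, ...]:
    return tuple(np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3))


def simulate_pedigrees(cfg: SimConfig) -> Pedigree:
    """Build the extended pedigrees top-down.

    Each pedigree starts from one founder couple; every offspring of a
    non-terminal generation marries a new unrelated founder and reproduces,
    with the number of offspring drawn uniformly from ``offspring_range``.
    """
    rng = _rngs(cfg)[0]
    lo, hi = cfg.offspring_range
    individuals: list[Individual] = []
    for f in range(1, cfg.n_pedigrees + 1):
        fam = f"F{f:02d}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fam}_I{counter:03d}"

        father, mother = new_id(), new_id()
        individuals.append(Individual(father, fam, sex="male"))
        individuals.append(Individual(mother, fam, sex="female"))
        couples = [(father, mother)]
        for gen in range(2, cfg.generations + 1):
            next_couples = []
            for fa, mo in couples:
                n_off = int(rng.integers(lo, hi + 1))
                for _ in range(n_off):
                    sex = "male" if rng.random() < 0.5 else "female"
                    child = new_id()
                    individuals.append(Individual(child, fam, father_id=fa, mother_id=mo, sex=sex))
                    if gen < cfg.generations:
                        spouse = new_id()
                        spouse_sex = "female" if sex == "male" else "male"
                        individuals.append(Individual(spouse, fam, sex=spouse_sex))
                        pair = (child, spouse) if sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    ped = Pedigree(individuals)
    if not ped.nonfounders:
        raise ValueError("configuration produced no nonfounders")
    return ped


def _build_gene_specs(cfg: SimConfig, rng: np.random.Generator) -> list[GeneSpec]:
    """Auto layout: equally spaced genes, random positions/frequencies within each."""
    genes: list[GeneSpec] = []
    for g in range(cfg.n_genes):
        name = f"G{g + 1:03d}"
        start = cfg.first_gene_start + g * (cfg.gene_span + cfg.gene_spacing)
        end = start + cfg.gene_span
        positions = np.sort(
            rng.choice(np.arange(start + 1, end + 1), size=cfg.variants_per_gene, replace=False)
        )
        mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.variants_per_gene)
        causal_gene = name in cfg.causal_gene_names
        betas = np.zeros(cfg.variants_per_gene)
        if causal_gene and cfg.beta != 0.0:
            mask = (
                mafs <= cfg.causal_maf_max
                if cfg.causal_maf_max is not None
                else np.ones_like(mafs, dtype=bool)
            )
            betas[mask] = cfg.beta
        genes.append(
            GeneSpec(
                name=name,
                start=int(start),
                end=int(end),
                positions=tuple(int(p) for p in positions),
                mafs=tuple(float(m) for m in mafs),
                betas=tuple(float(b) for b in betas),
            )
        )
    return genes


@dataclass
class TruthTable:
    """Declared simulation truth: causal flags per gene, effects per variant."""

    genes: pd.DataFrame  # unit_name, causal
    variants: pd.DataFrame  # variant_id, gene, beta, maf

    def __post_init__(self) -> None:
        noncausal = set(self.genes.loc[~self.genes["causal"], "unit_name"])
        bad = self.variants[self.variants["gene"].isin(noncausal) & (self.variants["beta"] != 0.0)]
        if len(bad):
            raise ValueError("noncausal genes must have all-zero effect sizes")

    @property
    def causal_genes(self) -> list[str]:
        return sorted(self.genes.loc[self.genes["causal"], "unit_name"])

    @property
    def noncausal_genes(self) -> list[str]:
        return sorted(self.genes.loc[~self.genes["causal"], "unit_name"])

    def is_causal(self, gene: str) -> bool:
        sel = self.genes.loc[self.genes["unit_name"] == gene, "causal"]
        if sel.empty:
            raise KeyError(gene)
        return bool(sel.iloc[0])


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[Region], np.ndarray]:
    """Gene-drop genotypes for every pedigree member.

    Returns the minor-allele-oriented matrix, the gene regions, and the raw
    simulated-allele counts (used by the phenotype model, independent of the
    minor-allele orientation applied afterwards).
    """
    if rng is None:
        rng = _rngs(cfg)[1]
    genes = cfg.genes if cfg.genes is not None else _build_gene_specs(cfg, rng)
    order = sorted(
        ((g, k) for g in genes for k in range(len(g.positions))),
        key=lambda t: t[0].positions[t[1]],
    )
    mafs = np.array([g.mafs[k] for g, k in order])
    n_var = mafs.size
    ids = list(ped.individual_ids)  # construction order: parents precede children
    row = {iid: i for i, iid in enumerate(ids)}
    hap = np.zeros((len(ids), n_var, 2), dtype=np.int8)
    for ind in ped:
        i = row[ind.individual_id]
        if ind.is_founder:
            hap[i] = rng.random((n_var, 2)) < mafs[:, None]
        else:
            for slot, parent in enumerate((ind.father_id, ind.mother_id)):
                pick = rng.integers(0, 2, size=n_var)
                hap[i, :, slot] = hap[row[parent], np.arange(n_var), pick]
    alt_counts = hap.sum(axis=2).astype(np.int8)

    founder_mask = np.array([ped.get(iid).is_founder for iid in ids])
    variants: list[Variant] = []
    counts = np.empty_like(alt_counts)
    for j, (g, k) in enumerate(order):
        col, minor, maf = _orient_to_minor(alt_counts[:, j].copy(), founder_mask)
        counts[:, j] = col
        variants.append(
            Variant(
                chromosome=cfg.chromosome,
                position=g.positions[k],
                ref_allele="A",
                alt_allele="C",
                minor_allele=minor,
                founder_maf=maf,
            )
        )
    gm = GenotypeMatrix(variants, ids, counts)
    regions = [g.region(cfg.chromosome) for g in genes]
    return gm, regions, alt_counts


def simulate_phenotypes(
    ped: Pedigree,
    gm: GenotypeMatrix,
    alt_counts: np.ndarray,
    cfg: SimConfig,
    replicate_ids=None,
    rng: np.random.Generator | None = None,
) -> tuple[TraitTable, TruthTable]:
    """Replicated quantitative traits plus the declared truth table."""
    if rng is None:
        rng = _rngs(cfg)[2]
    if replicate_ids is None:
        replicate_ids = list(range(1, cfg.n_replicates + 1))
    replicate_ids = [int(r) for r in replicate_ids]
    if not replicate_ids:
        raise ValueError("replicate_ids must be nonempty")

    genes = cfg.genes if cfg.genes is not None else None
    # gene layout must match the genotype call; rebuild deterministically if auto
    if genes is None:
        raise ValueError(
            "simulate_phenotypes needs the gene layout; call via simulate_dataset "
            "or pass a config with explicit genes"
        )
    order = sorted(
        ((g, k) for g in genes for k in range(len(g.positions))),
        key=lambda t: t[0].positions[t[1]],
    )
    betas = np.array([g.betas[k] for g, k in order])

    ids = list(gm.individuals)
    n = len(ids)
    sex = np.array([1.0 if ped.get(i).sex == "male" else 0.0 for i in ids])
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    med = (rng.random(n) < cfg.medication_rate).astype(float)
    b_sex, b_age, b_med = cfg.covariate_effects

    genetic = alt_counts.astype(float) @ betas
    fam_ids = sorted({ped.get(i).family_id for i in ids})
    fam_index = {f: k for k, f in enumerate(fam_ids)}
    fam_of = np.array([fam_index[ped.get(i).family_id] for i in ids])

    n_rep = len(replicate_ids)
    a_fam = rng.normal(0.0, cfg.family_effect_sd, size=(len(fam_ids), n_rep))
    eps = rng.normal(0.0, cfg.residual_sd, size=(n, n_rep))
    base = cfg.trait_mean + b_sex * sex + b_age * age + b_med * med + genetic
    y = base[:, None] + a_fam[fam_of] + eps

    values = pd.DataFrame(y, index=pd.Index(ids, name="individual_id"), columns=replicate_ids)
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "medication": med}, index=values.index
    )
    traits = TraitTable(values, covariates)

    truth_genes = pd.DataFrame(
        {"unit_name": [g.name for g in genes], "causal": [g.causal for g in genes]}
    )
    truth_variants = pd.DataFrame(
        {
            "variant_id": [gm.variants[j].variant_id for j in range(gm.n_variants)],
            "gene": [g.name for g, _ in order],
            "beta": betas,
            "maf": [g.mafs[k] for g, k in order],
        }
    )
    return traits, TruthTable(truth_genes, truth_variants)


@dataclass
class Dataset:
    """A complete simulated study: pedigree, genotypes, traits, regions, truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    traits: TraitTable
    regions: list[Region]
    truth: TruthTable | None = None


def simulate_dataset(cfg: SimConfig, replicate_ids=None) -> Dataset:
    """Run the full generator: pedigrees -> genotypes -> phenotypes."""
    rng_ped, rng_geno, rng_pheno = _rngs(cfg)
    ped = simulate_pedigrees(cfg)
    if cfg.genes is None:
        cfg = SimConfig(**{**cfg.__dict__, "genes": _build_gene_specs(cfg, rng_geno)})
    gm, regions, alt_counts = simulate_genotypes(ped, cfg, rng_geno)
    traits, truth = simulate_phenotypes(ped, gm, alt_counts, cfg, replicate_ids, rng_pheno)
    return Dataset(pedigree=ped, genotypes=gm, traits=traits, regions=regions, truth=truth)


# ---------------------------------------------------------------------------
# presets

#: Large-effect cluster preset: effect per causal allele, in trait units
#: (mmHg-scale).  Chosen by a design power calculation so the diluted
#: gene-level test sits in the detectable-but-unsaturated regime while the
#: causal-dense window is clearly stronger, mirroring a large gene whose
#: causal variants cluster in a subset of its windows.
MAP4_LIKE_BETA = 9.0
#: Weight-favoring preset: effect per causal allele on the rarest variants.
WEIGHT_FAVORING_BETA = 15.0


def _linspace_positions(start: int, stop: int, n: int) -> tuple[int, ...]:
    return tuple(int(round(p)) for p in np.linspace(start, stop, n))


def make_gaw_like_scenario(preset: str, seed: int = 1) -> SimConfig:
    """Named study designs used throughout the evaluation harness.

    * ``null``           -- 20 pedigrees (~450 members), 50 genes, no genetic
      or covariate effects; 20 phenotype replicates.  For size calibration.
    * ``map4_like``      -- one 239-kb gene spanning 4 absolute 100-kb windows,
      with 9 rare causal variants clustered in 2 of them, plus diluting
      noncausal variants across the span and two small noncausal genes.
    * ``weight_favoring``-- 20 genes of 12 variants with frequencies spread
      over (0.001, 0.009); in the 10 causal genes only the rarest variants
      (MAF <= 0.005) carry effects, the regime where frequency weighting
      should outperform the unweighted burden.
    """
    if preset == "null":
        return SimConfig(
            seed=seed,
            generations=4,
            n_genes=50,
            variants_per_gene=25,
            maf_range=(0.002, 0.01),
            covariate_effects=(0.0, 0.0, 0.0),
            n_replicates=20,
        )
    if preset == "weight_favoring":
        # causal effects sit on the rarest variants while commoner (but still
        # rare) neutral variants supply the burden noise that the unweighted
        # test cannot discount -- the regime frequency weighting targets
        mafs = tuple(float(m) for m in np.geomspace(0.002, 0.004, 6)) + tuple(
            float(m) for m in np.geomspace(0.006, 0.009, 12)
        )
        genes = []
        for g in range(20):
            name = f"G{g + 1:03d}"
            start = 1_000_000 + g * 200_000
            end = start + 20_000
            positions = _linspace_positions(start + 500, end - 500, 18)
            causal = g < 10
            betas = tuple(
                WEIGHT_FAVORING_BETA if (causal and m <= 0.005) else 0.0 for m in mafs
            )
            genes.append(
                GeneSpec(name=name, start=start, end=end, positions=positions, mafs=mafs, betas=betas)
            )
        return SimConfig(
            seed=seed,
            generations=5,
            genes=genes,
            covariate_effects=(0.0, 0.0, 0.0),
            n_replicates=50,
        )
    if preset == "map4_like":
        causal_mafs = [float(m) for m in np.geomspace(0.0035, 0.0055, 9)]
        noncausal_mafs = [float(m) for m in np.linspace(0.002, 0.009, 31)]
        positions: list[int] = []
        mafs: list[float] = []
        betas: list[float] = []
        # one causal variant in the second window, eight clustered in the third
        causal_pos = [47_950_000] + list(_linspace_positions(48_010_000, 48_090_000, 8))
        for p, m in zip(causal_pos, causal_mafs):
            positions.append(p)
            mafs.append(m)
            betas.append(MAP4_LIKE_BETA)
        # noncausal variants dilute the gene-level burden from the three
        # windows outside the dense causal cluster
        noncausal_pos = (
            list(_linspace_positions(47_892_500, 47_899_500, 12))
            + list(_linspace_positions(47_905_000, 47_995_000, 8))
            + list(_linspace_positions(48_100_500, 48_130_500, 11))
        )
        for p, m in zip(noncausal_pos, noncausal_mafs):
            positions.append(p)
            mafs.append(m)
            betas.append(0.0)
        big = GeneSpec(
            name="BIG_GENE",
            start=47_892_000,
            end=48_131_000,
            positions=tuple(positions),
            mafs=tuple(mafs),
            betas=tuple(betas),
        )
        smalls = [
            GeneSpec(
                name=f"SMALL_GENE_{i}",
                start=s,
                end=s + 20_000,
                positions=_linspace_positions(s + 500, s + 19_500, 10),
                mafs=tuple(float(m) for m in np.linspace(0.002, 0.009, 10)),
                betas=(0.0,) * 10,
            )
            for i, s in ((1, 46_000_000), (2, 49_000_000))
        ]
        return SimConfig(
            seed=seed,
            generations=5,
            offspring_range=(2, 3),
            genes=[big] + smalls,
            covariate_effects=(0.0, 0.0, 0.0),
            n_replicates=50,
        )
    raise ValueError(f"unknown preset {preset!r}; expected null, map4_like or weight_favoring")


# ---------------------------------------------------------------------------
# on-disk bundle


def write_dataset(ds: Dataset, outdir: str | Path) -> None:
    """Write the PED / VCF / phenotype TSV / BED / truth TSV bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ped(ds.pedigree, outdir / "pedigree.ped")
    write_vcf(ds.genotypes, outdir / "genotypes.vcf")
    write_trait_table(ds.traits, outdir / "phenotypes.tsv")
    write_regions(ds.regions, outdir / "regions.bed")
    if ds.truth is not None:
        ds.truth.genes.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        ds.truth.variants.to_csv(
            outdir / "truth_variants.tsv", sep="\t", index=False, float_format="%.10g"
        )


def load_dataset(directory: str | Path) -> Dataset:
    """Read a bundle written by :func:`write_dataset` back into memory."""
    directory = Path(directory)
    ped = read_pedigree(directory / "pedigree.ped")
    gm = read_genotypes(directory / "genotypes.vcf", ped)
    traits = read_trait_table(directory / "phenotypes.tsv")
    regions = read_regions(directory / "regions.bed")
    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        genes = pd.read_csv(truth_path, sep="\t")
        genes["causal"] = genes["causal"].astype(bool)
        var_path = directory / "truth_variants.tsv"
        variants = (
            pd.read_csv(var_path, sep="\t")
            if var_path.exists()
            else pd.DataFrame(columns=["variant_id", "gene", "beta", "maf"])
        )
        truth = TruthTable(genes, variants)
    return Dataset(pedigree=ped, genotypes=gm, traits=traits, regions=regions, truth=truth)
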