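"""Genotype and region data model.

Genotypes are stored as minor-allele counts per (individual, variant), with
the minor allele resolved against the *founder* population: the allele whose
founder frequency is <= 0.5 (ties go to the VCF ALT allele).  Rare-variant
selection downstream is entirely founder-frequency based, so orientation and
frequency estimation live here.

Coordinates: VCF positions are 1-based; regions are 0-based half-open.  A
variant at VCF position ``p`` has 0-based coordinate ``p - 1`` and falls in a
region ``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in the int8 count matrix


@dataclass(frozen=True)
class Region:
    """Named genomic interval, 0-based half-open."""

    name: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"region {self.name!r}: need 0 <= start < end, got [{self.start}, {self.end})")

    def contains_position0(self, chromosome: str, position0: int) -> bool:
        return chromosome == self.chromosome and self.start <= position0 < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with founder-based minor-allele annotation.

    ``founder_maf`` is the minor-allele frequency among founders (NaN when no
    founder is genotyped); ``minor_allele`` records whether the minor allele
    is the VCF REF or ALT allele.
    """

    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    minor_allele: str = "alt"  # "ref" | "alt"
    founder_maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.minor_allele not in ("ref", "alt"):
            raise ValueError(f"minor_allele must be 'ref' or 'alt', got {self.minor_allele!r}")
        if np.isfinite(self.founder_maf) and not (0.0 <= self.founder_maf <= 0.5):
            raise ValueError(f"founder_maf must lie in [0, 0.5], got {self.founder_maf}")

    @property
    def position0(self) -> int:
        return self.position - 1

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}:{self.alt_allele}"


class GenotypeMatrix:
    """Minor-allele counts for an ordered set of variants and individuals.

    ``counts`` is an int8 array of shape (n_individuals, n_variants) holding
    minor-allele copy numbers {0, 1, 2} with -1 for missing.
    """

    def __init__(self, variants: list[Variant], individuals: list[str], counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int8)
        if counts.shape != (len(individuals), len(variants)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(individuals)} individuals x {len(variants)} variants"
            )
        self.variants = list(variants)
        self.individuals = list(individuals)
        self.counts = counts
        self._row = {iid: i for i, iid in enumerate(individuals)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def row_index(self, individual_id: str) -> int | None:
        return self._row.get(individual_id)

    def counts_for(self, individual_id: str) -> np.ndarray:
        return self.counts[self._row[individual_id]]

    def founder_mafs(self) -> np.ndarray:
        return np.array([v.founder_maf for v in self.variants], dtype=float)

    def subset_variants(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.variants[i] for i in indices], self.individuals, self.counts[:, indices]
        )

    def subset_region(self, region: Region) -> "GenotypeMatrix":
        keep = [
            i
            for i, v in enumerate(self.variants)
            if region.contains_position0(v.chromosome, v.position0)
        ]
        return self.subset_variants(keep)


def _orient_to_minor(counts: np.ndarray, founder_rows: np.ndarray) -> tuple[np.ndarray, str, float]:
    """Flip alt counts to minor-allele counts using founder frequency.

    Returns (oriented counts, minor_allele, founder_maf).  Tie at 0.5 keeps
    the alt allele as minor.
    """
    fc = counts[founder_rows]
    known = fc >= 0
    n_known = int(known.sum())
    if n_known == 0:
        return counts, "alt", float("nan")
    alt_freq = float(fc[known].sum()) / (2.0 * n_known)
    if alt_freq > 0.5:
        flipped = counts.copy()
        obs = counts >= 0
        flipped[obs] = 2 - counts[obs]
        return flipped, "ref", 1.0 - alt_freq
    return counts, "alt", alt_freq


def read_genotypes(
    path: str | Path, pedigree: Pedigree, region: Region | None = None
) -> GenotypeMatrix:
    """Read biallelic genotypes from a VCF into a founder-oriented matrix.

    Rows follow the pedigree's individual order; pedigree members absent
    from the VCF get all-missing rows (warned).  Extra VCF samples are
    ignored with a warning; multiallelic records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    ped_ids = list(pedigree.individual_ids)
    present = [iid for iid in ped_ids if iid in sample_pos]
    if not present:
        raise ValueError(f"{path}: no overlap between VCF samples and pedigree members")
    absent = [iid for iid in ped_ids if iid not in sample_pos]
    if absent:
        logger.warning("%s: %d pedigree members missing from VCF (all-missing rows)", path, len(absent))
    extra = set(samples) - set(ped_ids)
    if extra:
        logger.warning("%s: ignoring %d VCF samples not in the pedigree", path, len(extra))

    founder_ids = {ind.individual_id for ind in pedigree.founders}
    col_of = {iid: j for j, iid in enumerate(ped_ids)}
    sample_cols = np.array([sample_pos[iid] for iid in present], dtype=int)
    dest_rows = np.array([col_of[iid] for iid in present], dtype=int)
    founder_mask = np.array([ped_ids[i] in founder_ids for i in range(len(ped_ids))])

    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        pos0 = rec.POS - 1
        if region is not None and not region.contains_position0(rec.CHROM, pos0):
            continue
        gts = np.asarray(rec.gt_types, dtype=np.int8)  # 0/1/2 alt copies, 3 unknown
        col = np.full(len(ped_ids), MISSING, dtype=np.int8)
        vals = gts[sample_cols]
        vals = np.where(vals == 3, MISSING, vals).astype(np.int8)
        col[dest_rows] = vals
        col, minor, maf = _orient_to_minor(col, founder_mask)
        variants.append(
            Variant(
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                minor_allele=minor,
                founder_maf=maf,
            )
        )
        columns.append(col)
    if n_multi:
        logger.info("%s: skipped %d multiallelic records", path, n_multi)
    counts = (
        np.stack(columns, axis=1) if columns else np.zeros((len(ped_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(variants, ped_ids, counts)


def founder_minor_allele_freq(gm: GenotypeMatrix, ped: Pedigree) -> dict[str, float]:
    """Recompute founder minor-allele frequencies for every variant.

    Returns a mapping variant_id -> frequency in [0, 0.5]; variants with no
    genotyped founder map to NaN (to be excluded downstream).  Assumes the
    matrix is already minor-allele oriented.
    """
    founder_rows = np.array([gm.row_index(f.individual_id) for f in ped.founders
                             if f.individual_id in gm._row], dtype=int)
    out: dict[str, float] = {}
    for j, variant in enumerate(gm.variants):
        col = gm.counts[founder_rows, j]
        known = col >= 0
        n = int(known.sum())
        out[variant.variant_id] = float("nan") if n == 0 else float(col[known].sum()) / (2 * n)
    return out


def annotate_founder_maf(gm: GenotypeMatrix, ped: Pedigree) -> GenotypeMatrix:
    """Return a matrix whose variants carry freshly computed founder MAFs."""
    freqs = founder_minor_allele_freq(gm, ped)
    gm.variants = [replace(v, founder_maf=freqs[v.variant_id]) for v in gm.variants]
    return gm


# child count c is Mendelian-reachable from parent counts (f, m) iff a
# transmissible allele pair sums to c
_REACHABLE = np.zeros((3, 3, 3), dtype=bool)
for _f in range(3):
    for _m in range(3):
        for _af in ({0} if _f == 0 else {1} if _f == 2 else {0, 1}):
            for _am in ({0} if _m == 0 else {1} if _m == 2 else {0, 1}):
                _REACHABLE[_f, _m, _af + _am] = True


def count_mendelian_errors(gm: GenotypeMatrix, ped: Pedigree) -> int:
    """Count (offspring, variant) cells inconsistent with both parents.

    Only fully typed trios are checked; missing genotypes are ignored.
    """
    n_err = 0
    for ind in ped.nonfounders:
        rc = gm.row_index(ind.individual_id)
        rf = gm.row_index(ind.father_id)
        rm = gm.row_index(ind.mother_id)
        if rc is None or rf is None or rm is None:
            continue
        c, f, m = gm.counts[rc], gm.counts[rf], gm.counts[rm]
        ok = (c >= 0) & (f >= 0) & (m >= 0)
        if ok.any():
            n_err += int((~_REACHABLE[f[ok], m[ok], c[ok]]).sum())
    return n_err


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a plain-text VCF (GT only), in ALT-allele orientation."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = sorted({v.chromosome for v in gm.variants})
    order = sorted(range(gm.n_variants), key=lambda i: (gm.variants[i].chromosome, gm.variants[i].position))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fbatrare\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.individuals) + "\n")
        for j in order:
            v = gm.variants[j]
            col = gm.counts[:, j].astype(int)
            if v.minor_allele == "ref":  # stored counts are REF copies; emit ALT copies
                col = np.where(col >= 0, 2 - col, MISSING)
            fields = [v.chromosome, str(v.position), ".", v.ref_allele, v.alt_allele, ".", "PASS", ".", "GT"]
            fields += [gt_str[int(c)] for c in col]
            fh.write("\t".join(fields) + "\n")


def read_regions(path: str | Path) -> list[Region]:
    """Read a BED-style 4-column file (chrom, start, end, name), 0-based half-open."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}, line {lineno}: expected 4 columns (chrom start end name)")
            chrom, start, end, name = fields[:4]
            regions.append(Region(name=name, chromosome=chrom, start=int(start), end=int(end)))
    return regions


def write_regions(regions: list[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.name}\n")
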