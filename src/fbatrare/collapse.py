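"""Rare-variant collapsing, gene tests, and the disjoint 100-kb window scan.

Variants with founder minor-allele frequency strictly below a threshold
(default 0.01) are combined linearly into a single pseudo-marker
X = sum_k w_k x_k and tested with the family-based score test.  Two weight
schemes are supported:

* v0 (unweighted burden): w_k = 1,
* v1 (Madsen-Browning):   w_k = 1 / sqrt(zeta * p_k * (1 - p_k)),

where p_k is the founder minor-allele frequency and zeta the total number of
nuclear families in the dataset.  The reciprocal *square-root* form is the
Madsen-Browning weight; a plain reciprocal ("linear") form is available for
sensitivity analysis.

The window scan tiles a chromosome into disjoint fixed-size windows anchored
at absolute coordinate 0 ([0, 100kb), [100kb, 200kb), ...), collapses the
rare variants inside each variant-bearing window, and tests each window like
a gene.  Bonferroni correction multiplies a window p-value by the number of
tested windows.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    STATUS_UNINFORMATIVE,
    FamilyContribution,
    TestResult,
    TraitOffsetPolicy,
    fbat_test,
)
from .genotypes import GenotypeMatrix, Region
from .pedigree import NuclearFamily, Pedigree, decompose_nuclear_families

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 100_000


@dataclass(frozen=True)
class WeightScheme:
    """Weighting rule for collapsing: unweighted (v0) or frequency-weighted (v1)."""

    name: str  # "v0" | "v1"
    zeta: int | None = None  # total nuclear families; required for v1
    weight_form: str = "sqrt"  # "sqrt" (Madsen-Browning) | "linear"

    def __post_init__(self) -> None:
        if self.name not in ("v0", "v1"):
            raise ValueError(f"unknown weight scheme {self.name!r}")
        if self.weight_form not in ("sqrt", "linear"):
            raise ValueError(f"unknown weight form {self.weight_form!r}")
        if self.name == "v1" and (self.zeta is None or self.zeta < 1):
            raise ValueError("v1 weighting requires zeta >= 1 (total nuclear families)")


def compute_weights(founder_mafs, scheme: WeightScheme) -> np.ndarray:
    """Per-variant collapsing weights from founder minor-allele frequencies."""
    p = np.asarray(founder_mafs, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0)):
        raise ValueError("founder MAFs must lie strictly in (0, 1); filter monomorphic variants first")
    if scheme.name == "v0":
        return np.ones_like(p)
    q = scheme.zeta * p * (1.0 - p)
    return 1.0 / np.sqrt(q) if scheme.weight_form == "sqrt" else 1.0 / q


def select_rare_variants(gm: GenotypeMatrix, maf_threshold: float = 0.01) -> list[int]:
    """Indices of polymorphic variants with founder MAF strictly below the threshold."""
    mafs = gm.founder_mafs()
    keep = np.isfinite(mafs) & (mafs > 0.0) & (mafs < maf_threshold)
    return [int(i) for i in np.flatnonzero(keep)]


@dataclass
class FamilyMarkerData:
    """Per-family collapsed-marker data: retained offspring with conditional moments.

    The conditional mean and variance are identical across offspring of one
    family (they share parents): E[X] = sum_k w_k (f_k + m_k)/2 and
    Var(X) = sum_k w_k^2 (1[f_k=1] + 1[m_k=1])/4 under independent
    transmission across variants.
    """

    family: NuclearFamily
    offspring_ids: tuple[str, ...]
    x: np.ndarray  # pseudo-counts per retained offspring
    expected: float
    variance: float


@dataclass
class CollapsedMarker:
    """A weighted sum of rare-variant counts treated as a single pseudo-variant."""

    unit_name: str
    variant_ids: tuple[str, ...]
    weights: np.ndarray
    individuals: tuple[str, ...]
    pseudo_count: np.ndarray  # per individual; NaN if any collapsed variant is missing
    families: list[FamilyMarkerData] = field(default_factory=list)
    chromosome: str | None = None
    span: tuple[int, int] | None = None

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


def collapse_genotypes(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    variant_indices: Sequence[int],
    weights,
    unit_name: str = "",
    families: list[NuclearFamily] | None = None,
) -> CollapsedMarker:
    """Collapse a variant subset into a pseudo-marker with per-family moments.

    Missing-data rules: a nuclear family whose father or mother is missing
    any collapsed variant is excluded entirely (conditioning would be
    inexact); an offspring missing any collapsed variant is dropped from this
    unit only.
    """
    idx = np.asarray(list(variant_indices), dtype=int)
    w = np.asarray(weights, dtype=float)
    if idx.size != w.size or idx.size == 0:
        raise ValueError("need one positive weight per collapsed variant (>=1 variant)")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weights must be finite and > 0")

    raw = gm.counts[:, idx].astype(float)
    raw[raw < 0] = np.nan
    pseudo = raw @ w

    if families is None:
        families = decompose_nuclear_families(pedigree)
    fam_data: list[FamilyMarkerData] = []
    for fam in families:
        rf = gm.row_index(fam.father_id)
        rm = gm.row_index(fam.mother_id)
        if rf is None or rm is None:
            continue
        f_counts = raw[rf]
        m_counts = raw[rm]
        if np.any(~np.isfinite(f_counts)) or np.any(~np.isfinite(m_counts)):
            continue  # missing parent genotype -> family uninformative
        expected = float(np.dot(w, (f_counts + m_counts) / 2.0))
        variance = float(np.dot(w * w, ((f_counts == 1) * 0.25 + (m_counts == 1) * 0.25)))
        kept: list[str] = []
        xs: list[float] = []
        for oid in fam.offspring_ids:
            ro = gm.row_index(oid)
            if ro is None or not np.isfinite(pseudo[ro]):
                continue
            kept.append(oid)
            xs.append(float(pseudo[ro]))
        if not kept:
            continue
        fam_data.append(
            FamilyMarkerData(fam, tuple(kept), np.array(xs), expected, variance)
        )

    variants = [gm.variants[i] for i in idx]
    chrom = variants[0].chromosome if variants else None
    span = (
        (min(v.position0 for v in variants), max(v.position0 for v in variants) + 1)
        if variants
        else None
    )
    return CollapsedMarker(
        unit_name=unit_name,
        variant_ids=tuple(v.variant_id for v in variants),
        weights=w,
        individuals=tuple(gm.individuals),
        pseudo_count=pseudo,
        families=fam_data,
        chromosome=chrom,
        span=span,
    )


@dataclass
class TestConfig:
    """Tunable parameters of the collapsing test pipeline."""

    __test__ = False  # not a pytest collection target

    maf_threshold: float = 0.01
    scheme: str = "v1"
    weight_form: str = "sqrt"
    variance_mode: str = "model"
    min_informative: int = 10
    window_size: int = DEFAULT_WINDOW_SIZE
    offset: TraitOffsetPolicy = field(default_factory=TraitOffsetPolicy.sample_mean)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TestConfig":
        known = {
            k: mapping[k]
            for k in (
                "maf_threshold",
                "scheme",
                "weight_form",
                "variance_mode",
                "min_informative",
                "window_size",
            )
            if k in mapping
        }
        cfg = cls(**known)
        if "offset" in mapping:
            off = mapping["offset"]
            cfg.offset = (
                TraitOffsetPolicy.sample_mean()
                if off in ("sample_mean", None)
                else TraitOffsetPolicy.fixed(float(off))
            )
        return cfg


def _empty_result(unit_name, config, chromosome=None, span=None, n_variants=0) -> TestResult:
    return TestResult(
        unit_name=unit_name,
        score_u=0.0,
        variance_v=0.0,
        z=None,
        p_two_sided=None,
        n_informative_families=0,
        n_variants_collapsed=n_variants,
        status=STATUS_UNINFORMATIVE,
        chromosome=chromosome,
        span=span,
    )


def collapsed_marker_test(
    marker: CollapsedMarker, traits, config: TestConfig = TestConfig()
) -> TestResult:
    """Run the family-based score test on a collapsed pseudo-marker.

    ``traits`` maps individual_id -> raw trait value (a pandas Series or
    mapping); the offset policy centers traits over all offspring entering
    the test.  Offspring with a missing trait are dropped from this test.
    """
    get = traits.get if hasattr(traits, "get") else traits.__getitem__
    entries: list[tuple[FamilyMarkerData, list[int], list[float]]] = []
    all_t: list[float] = []
    for fd in marker.families:
        kept_idx: list[int] = []
        t_vals: list[float] = []
        for k, oid in enumerate(fd.offspring_ids):
            t = get(oid)
            if t is None or not np.isfinite(t):
                continue
            kept_idx.append(k)
            t_vals.append(float(t))
        if kept_idx:
            entries.append((fd, kept_idx, t_vals))
            all_t.extend(t_vals)
    if not all_t:
        return _empty_result(
            marker.unit_name, config, marker.chromosome, marker.span, marker.n_variants
        )
    offset = (
        float(np.mean(np.array(all_t)))
        if config.offset.mode == "sample_mean"
        else config.offset.fixed_value
    )
    contribs: list[FamilyContribution] = []
    for fd, kept_idx, t_vals in entries:
        t = np.array(t_vals) - offset
        dev = fd.x[kept_idx] - fd.expected
        v_model = float(np.dot(t * t, np.full(len(kept_idx), fd.variance)))
        u = float(np.dot(t, dev))
        contribs.append(FamilyContribution(fd.family, u, v_model, v_model > 0.0, len(kept_idx)))
    return fbat_test(
        contribs,
        variance_mode=config.variance_mode,
        min_informative=config.min_informative,
        unit_name=marker.unit_name,
        n_variants=marker.n_variants,
        chromosome=marker.chromosome,
        span=marker.span,
    )


def build_marker(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    region: Region | None,
    config: TestConfig,
    unit_name: str,
    zeta: int | None = None,
    families: list[NuclearFamily] | None = None,
) -> CollapsedMarker | None:
    """Select rare variants in a region, weight, and collapse; None if no rare variant."""
    sub = gm.subset_region(region) if region is not None else gm
    rare = select_rare_variants(sub, config.maf_threshold)
    if not rare:
        logger.info("unit %s: no rare variants after filtering; skipped", unit_name)
        return None
    if families is None:
        families = decompose_nuclear_families(pedigree)
    if zeta is None:
        zeta = len(families)
    scheme = WeightScheme(config.scheme, zeta=zeta, weight_form=config.weight_form)
    mafs = sub.founder_mafs()[rare]
    weights = compute_weights(mafs, scheme)
    marker = collapse_genotypes(sub, pedigree, rare, weights, unit_name, families=families)
    return marker


def gene_test(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    region: Region,
    traits,
    config: TestConfig = TestConfig(),
    zeta: int | None = None,
    families: list[NuclearFamily] | None = None,
) -> TestResult:
    """Collapse the rare variants of one gene region and test the pseudo-marker."""
    marker = build_marker(gm, pedigree, region, config, region.name, zeta, families)
    if marker is None:
        return _empty_result(region.name, config, region.chromosome, (region.start, region.end))
    return collapsed_marker_test(marker, traits, config)


@dataclass(frozen=True)
class Window:
    """One fixed-size tile of the genome, anchored at absolute coordinate 0."""

    chromosome: str
    start: int
    end: int

    @property
    def id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}"

    def as_region(self) -> Region:
        return Region(name=self.id, chromosome=self.chromosome, start=self.start, end=self.end)


def tile_windows(chromosome: str, max_position: int, size: int = DEFAULT_WINDOW_SIZE) -> list[Window]:
    """Disjoint windows [0, size), [size, 2*size), ... covering ``max_position``.

    ``max_position`` is a 0-based coordinate; the tiling ends with the window
    that contains it.  A position exactly on a boundary belongs to the
    right-hand window.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    if max_position < 0:
        raise ValueError("max_position must be nonnegative")
    n = max_position // size + 1
    return [Window(chromosome, i * size, (i + 1) * size) for i in range(n)]


def windows_overlapping(region: Region, size: int = DEFAULT_WINDOW_SIZE) -> list[Window]:
    """All windows of the absolute tiling that intersect a region."""
    first = region.start // size
    last = (region.end - 1) // size
    return [Window(region.chromosome, i * size, (i + 1) * size) for i in range(first, last + 1)]


def window_scan(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    chromosome: str,
    traits,
    config: TestConfig = TestConfig(),
    zeta: int | None = None,
    families: list[NuclearFamily] | None = None,
    windows: list[Window] | None = None,
) -> list[TestResult]:
    """Test every variant-bearing window of a chromosome.

    Windows with no rare variant are omitted (counted in the log).  Each
    result carries a Bonferroni-adjusted p-value using the number of tested
    windows as the correction factor.
    """
    positions = [v.position0 for v in gm.variants if v.chromosome == chromosome]
    if not positions:
        return []
    if windows is None:
        windows = tile_windows(chromosome, max(positions), config.window_size)
    if families is None:
        families = decompose_nuclear_families(pedigree)
    if zeta is None:
        zeta = len(families)
    results: list[TestResult] = []
    n_skipped = 0
    for win in windows:
        marker = build_marker(gm, pedigree, win.as_region(), config, win.id, zeta, families)
        if marker is None:
            n_skipped += 1
            continue
        res = collapsed_marker_test(marker, traits, config)
        res.span = (win.start, win.end)
        results.append(res)
    n_tested = len(results)
    for res in results:
        if res.p_two_sided is not None:
            res.p_bonferroni = bonferroni_adjust(res.p_two_sided, n_tested)
    logger.info(
        "window scan %s: %d windows tested, %d without rare variants", chromosome, n_tested, n_skipped
    )
    return results


def scan_region_windows(
    gm: GenotypeMatrix,
    pedigree: Pedigree,
    region: Region,
    traits,
    config: TestConfig = TestConfig(),
    zeta: int | None = None,
    families: list[NuclearFamily] | None = None,
) -> list[TestResult]:
    """Window-scan restricted to the absolute-tiling windows overlapping a gene.

    The Bonferroni factor is the number of *tested* (variant-bearing) windows
    overlapping the gene -- an observable quantity, unlike the number of
    windows that happen to carry causal variants.
    """
    wins = windows_overlapping(region, config.window_size)
    return window_scan(
        gm, pedigree, region.chromosome, traits, config, zeta, families, windows=wins
    )


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return min(1.0, p * n_tests)


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def write_results(results: Sequence[TestResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")
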