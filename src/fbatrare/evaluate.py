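"""Replicate-based power and type-I-error evaluation.

Replicate p-values for a unit are summarised by the fraction falling
strictly below each of a decreasing series of powers of ten (default
1e-7 ... 1e-4).  The *summary detection threshold* of a unit is the smallest
threshold whose fraction exceeds 0.5; a unit with no qualifying threshold is
"not detected".  Type-I error pools tests of noncausal units across
replicates (a per-unit breakdown is also emitted, since either convention is
defensible).

Phenotype adjustment regresses the trait on an intercept plus sex, age and
medication use per replicate and keeps the ordinary-least-squares residuals,
mirroring the construction of an adjusted blood-pressure trait from a raw
one.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collapse import TestConfig, build_marker, collapsed_marker_test
from .core import STATUS_OK
from .pedigree import decompose_nuclear_families
from .phenotypes import COVARIATE_COLUMNS, TraitTable

logger = logging.getLogger(__name__)

POWER_THRESHOLDS = (1e-7, 1e-6, 1e-5, 1e-4)
TYPE1_THRESHOLDS = (1e-6, 1e-5, 1e-4, 1e-3)


@dataclass
class PowerSummary:
    """Per-threshold detection fractions for one unit across replicates."""

    unit_name: str
    thresholds: tuple[float, ...]
    fraction_below: tuple[float, ...]
    n_replicates: int
    summary_threshold: float | None = None
    scheme: str | None = None

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.fraction_below):
            raise ValueError("one fraction per threshold required")
        order = np.argsort(self.thresholds)
        fr = np.array(self.fraction_below)[order]
        if np.any(np.diff(fr) < -1e-12):
            raise ValueError("fraction_below must be non-decreasing as thresholds loosen")


def power_at_thresholds(
    pvalues: Sequence[float | None],
    thresholds: Sequence[float] = POWER_THRESHOLDS,
    n_replicates: int | None = None,
    unit_name: str = "",
    scheme: str | None = None,
) -> PowerSummary:
    """Fraction of replicate p-values strictly below each threshold.

    ``pvalues`` holds one entry per replicate; None/NaN (untestable
    replicates) count as non-detections.  ``n_replicates`` defaults to
    ``len(pvalues)`` and is the denominator of every fraction.
    """
    pvals = [p for p in pvalues if p is not None and np.isfinite(p)]
    n = n_replicates if n_replicates is not None else len(list(pvalues))
    if n <= 0:
        raise ValueError("power requires at least one replicate")
    thresholds = tuple(sorted(float(t) for t in thresholds))
    fractions = tuple(sum(p < t for p in pvals) / n for t in thresholds)
    return PowerSummary(
        unit_name=unit_name,
        thresholds=thresholds,
        fraction_below=fractions,
        n_replicates=n,
        scheme=scheme,
    )


def summary_power(ps: PowerSummary) -> float | None:
    """Smallest threshold whose detection fraction is strictly above 0.5.

    Returns None when no threshold qualifies (the unit is not detected).
    """
    for t, f in sorted(zip(ps.thresholds, ps.fraction_below)):
        if f > 0.5:
            return t
    return None


@dataclass
class Type1Report:
    """False-positive rates of noncausal units, pooled over unit x replicate tests."""

    thresholds: tuple[float, ...]
    rate: tuple[float, ...]
    n_units: int
    n_replicates: int
    n_tests: int
    per_unit: pd.DataFrame | None = field(default=None, repr=False)

    def rate_at(self, threshold: float) -> float:
        for t, r in zip(self.thresholds, self.rate):
            if math.isclose(t, threshold, rel_tol=1e-9):
                return r
        raise KeyError(f"threshold {threshold} not in report")


def type1_error_rate(
    pvalues: Sequence[float],
    thresholds: Sequence[float] = TYPE1_THRESHOLDS,
    n_units: int | None = None,
    n_replicates: int | None = None,
) -> Type1Report:
    """Pooled type-I-error rates from noncausal unit x replicate p-values.

    ``pvalues`` contains only completed tests (untestable unit-replicates
    are excluded from the denominator).
    """
    pvals = np.asarray([p for p in pvalues if p is not None and np.isfinite(p)], dtype=float)
    if pvals.size == 0:
        raise ValueError("type-I error requires at least one completed noncausal test")
    thresholds = tuple(sorted(float(t) for t in thresholds))
    rate = tuple(float(np.mean(pvals < t)) for t in thresholds)
    return Type1Report(
        thresholds=thresholds,
        rate=rate,
        n_units=n_units or 0,
        n_replicates=n_replicates or 0,
        n_tests=int(pvals.size),
    )


def adjust_phenotype(traits: TraitTable) -> TraitTable:
    """Residualise the trait on intercept + sex + age + medication, per replicate.

    Rows with missing covariates are dropped (their residuals are NaN,
    logged); constant covariates are removed from the design with a warning.
    All replicates share one design matrix, so a single least-squares solve
    produces every replicate's residuals.
    """
    cov = traits.covariates.copy()
    cols = [c for c in COVARIATE_COLUMNS if c in cov.columns]
    usable = cov[cols].notna().all(axis=1) if cols else pd.Series(True, index=cov.index)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("adjust_phenotype: dropping %d individuals with missing covariates", n_dropped)
    kept_cols = []
    for c in cols:
        if cov.loc[usable, c].nunique() <= 1:
            logger.warning("adjust_phenotype: covariate %r is constant; dropped from design", c)
        else:
            kept_cols.append(c)
    y = traits.values.loc[usable].to_numpy(dtype=float)  # (n, R)
    x = np.column_stack(
        [np.ones(int(usable.sum()))] + [cov.loc[usable, c].to_numpy(dtype=float) for c in kept_cols]
    )
    resid = np.full_like(y, np.nan)
    finite = np.isfinite(y)
    if finite.all():
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
    else:  # per-replicate masked fit when some trait values are missing
        for r in range(y.shape[1]):
            m = finite[:, r]
            if m.sum() <= x.shape[1]:
                continue
            beta, *_ = np.linalg.lstsq(x[m], y[m, r], rcond=None)
            resid[m, r] = y[m, r] - x[m] @ beta
    values = pd.DataFrame(np.nan, index=traits.values.index, columns=traits.values.columns)
    values.loc[usable] = resid
    return TraitTable(values, traits.covariates.copy())


@dataclass
class ExperimentResult:
    """Full cross of units x schemes x replicates, with summaries."""

    results: pd.DataFrame
    power: pd.DataFrame
    type1: Type1Report | None
    type1_by_scheme: dict[str, Type1Report] = field(default_factory=dict)


def run_experiment(
    dataset,
    schemes: Sequence[str] = ("v0", "v1"),
    replicates: Sequence[int] | None = None,
    config: TestConfig = TestConfig(),
    power_thresholds: Sequence[float] = POWER_THRESHOLDS,
    type1_thresholds: Sequence[float] = TYPE1_THRESHOLDS,
    adjust: bool = False,
) -> ExperimentResult:
    """Test every gene region under each scheme for each phenotype replicate.

    ``dataset`` provides ``pedigree``, ``genotypes``, ``traits``, ``regions``
    and optionally ``truth`` (causal labels; without it no type-I report is
    produced).  Results are deterministic given the inputs and config;
    untestable unit-replicates are carried with their status, counted as
    non-detections in power, and excluded from the type-I denominator.
    """
    traits = adjust_phenotype(dataset.traits) if adjust else dataset.traits
    replicates = list(replicates) if replicates is not None else traits.replicate_ids
    families = decompose_nuclear_families(dataset.pedigree)
    zeta = len(families)

    rows = []
    power_rows = []
    for scheme in schemes:
        cfg = TestConfig(**{**config.__dict__, "scheme": scheme})
        for region in dataset.regions:
            marker = build_marker(
                dataset.genotypes, dataset.pedigree, region, cfg, region.name, zeta, families
            )
            pvals: list[float | None] = []
            for r in replicates:
                if marker is None:
                    row = {
                        "unit_name": region.name,
                        "chrom": region.chromosome,
                        "span": f"{region.start}-{region.end}",
                        "n_variants": 0,
                        "n_families": 0,
                        "U": 0.0,
                        "V": 0.0,
                        "Z": None,
                        "p": None,
                        "p_bonferroni": None,
                        "status": "uninformative",
                    }
                else:
                    res = collapsed_marker_test(marker, traits.replicate(r), cfg)
                    row = res.to_row()
                row.update({"scheme": scheme, "replicate": int(r)})
                pvals.append(row["p"] if row["status"] == STATUS_OK else None)
                rows.append(row)
            ps = power_at_thresholds(
                pvals,
                thresholds=power_thresholds,
                n_replicates=len(replicates),
                unit_name=region.name,
                scheme=scheme,
            )
            prow = {"unit_name": region.name, "scheme": scheme, "n_replicates": ps.n_replicates}
            prow.update({f"frac_below_{t:g}": f for t, f in zip(ps.thresholds, ps.fraction_below)})
            st = summary_power(ps)
            prow["summary_threshold"] = st if st is not None else ""
            power_rows.append(prow)

    results = pd.DataFrame(rows)
    power = pd.DataFrame(power_rows)

    type1 = None
    type1_by_scheme: dict[str, Type1Report] = {}
    truth = getattr(dataset, "truth", None)
    if truth is not None:
        noncausal = set(truth.noncausal_genes)
        ok = results[(results["status"] == STATUS_OK) & results["unit_name"].isin(noncausal)]
        if len(ok):
            type1 = type1_error_rate(
                ok["p"].tolist(),
                thresholds=type1_thresholds,
                n_units=len(noncausal),
                n_replicates=len(replicates),
            )
            type1.per_unit = (
                ok.groupby(["unit_name", "scheme"])["p"]
                .apply(lambda s: {f"{t:g}": float(np.mean(s < t)) for t in type1.thresholds})
                .reset_index(name="rates")
            )
            for scheme in schemes:
                sub = ok[ok["scheme"] == scheme]
                if len(sub):
                    type1_by_scheme[scheme] = type1_error_rate(
                        sub["p"].tolist(),
                        thresholds=type1_thresholds,
                        n_units=len(noncausal),
                        n_replicates=len(replicates),
                    )
    return ExperimentResult(results=results, power=power, type1=type1, type1_by_scheme=type1_by_scheme)
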