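"""The family-based association score test for a quantitative trait.

For a (possibly collapsed) marker X and centered trait T, each nuclear family
i contributes

    u_i = sum_j T_ij * (X_ij - E[X_ij | parents]),

where the expectation conditions offspring genotypes on the parental
genotypes under Mendelian transmission.  The test statistic is

    Z = U / sqrt(V),   U = sum_i u_i,

with V either the model-based conditional variance sum_ij T_ij^2 Var(X_ij)
(exact when transmissions are independent across collapsed variants) or the
empirical sum of squares sum_i u_i^2 (robust to between-variant transmission
correlation).  Conditioning on parental genotypes makes the test immune to
population stratification; Z is treated as standard normal under the null
and the reported p-value is the two-sided tail.

Families with a missing parental genotype are excluded as uninformative;
full sufficient-statistic conditioning for missing parents is a documented
extension point, not implemented.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .pedigree import NuclearFamily

STATUS_OK = "ok"
STATUS_UNINFORMATIVE = "uninformative"
STATUS_BELOW_MIN = "below_min_families"


class UninformativeFamilyError(ValueError):
    """Raised when a conditional distribution is requested with a missing parent."""


@dataclass(frozen=True)
class OffspringMoments:
    """Conditional distribution of an offspring genotype value given parents."""

    expected_count: float
    variance: float
    support: Mapping[float, float]

    def __post_init__(self) -> None:
        total = sum(self.support.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"support probabilities sum to {total}, not 1")
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")


def _transmissions(count: int) -> list[tuple[float, int]]:
    if count == 0:
        return [(1.0, 0)]
    if count == 1:
        return [(0.5, 0), (0.5, 1)]
    if count == 2:
        return [(1.0, 1)]
    raise UninformativeFamilyError(f"parental genotype count must be 0, 1 or 2, got {count!r}")


def offspring_conditional_dist(father_count: int, mother_count: int) -> OffspringMoments:
    """Offspring allele-count distribution given both parental counts.

    Each parent independently transmits one allele: a heterozygous parent
    transmits the minor allele with probability 1/2, homozygotes
    deterministically.  Raises :class:`UninformativeFamilyError` for a
    missing parental genotype (the family is then excluded from the test).
    """
    for c in (father_count, mother_count):
        if c is None or (isinstance(c, float) and not np.isfinite(c)) or c < 0:
            raise UninformativeFamilyError("missing parental genotype: family is uninformative")
    support: dict[float, float] = {}
    for pf, af in _transmissions(int(father_count)):
        for pm, am in _transmissions(int(mother_count)):
            g = float(af + am)
            support[g] = support.get(g, 0.0) + pf * pm
    e = sum(g * p for g, p in support.items())
    var = sum(g * g * p for g, p in support.items()) - e * e
    return OffspringMoments(expected_count=e, variance=max(var, 0.0), support=support)


@dataclass(frozen=True)
class TraitOffsetPolicy:
    """How to center the trait before it weights the genotype deviation."""

    mode: str = "sample_mean"  # "sample_mean" | "fixed"
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("sample_mean", "fixed"):
            raise ValueError(f"unknown offset mode {self.mode!r}")
        if (self.mode == "fixed") != (self.fixed_value is not None):
            raise ValueError("fixed_value must be given exactly when mode='fixed'")

    @classmethod
    def sample_mean(cls) -> "TraitOffsetPolicy":
        return cls(mode="sample_mean")

    @classmethod
    def fixed(cls, value: float) -> "TraitOffsetPolicy":
        return cls(mode="fixed", fixed_value=float(value))


def center_trait(traits, policy: TraitOffsetPolicy = TraitOffsetPolicy()) -> np.ndarray:
    """Subtract the offset (sample mean of tested offspring, or a fixed value)."""
    t = np.asarray(traits, dtype=float)
    finite = np.isfinite(t)
    if t.size == 0 or not finite.any():
        raise ValueError("no non-missing trait values to center")
    if policy.mode == "sample_mean":
        return t - float(np.mean(t[finite]))
    return t - policy.fixed_value


@dataclass(frozen=True)
class FamilyContribution:
    """Score and model-variance contribution of one nuclear family."""

    family: NuclearFamily
    u: float
    v_model: float
    informative: bool
    n_offspring: int


def family_score_contribution(
    fam: NuclearFamily,
    marker_counts: Mapping[str, float],
    traits: Mapping[str, float],
    moments: Mapping[str, OffspringMoments],
) -> FamilyContribution:
    """Compute u_i and its model variance for one nuclear family.

    ``traits`` must already be centered.  Families with any offspring lacking
    a marker value, trait, or conditional moments are returned with
    ``informative=False`` and zero contributions.
    """
    xs, ts, es, vs = [], [], [], []
    for oid in fam.offspring_ids:
        x = marker_counts.get(oid)
        t = traits.get(oid)
        m = moments.get(oid)
        if x is None or t is None or m is None or not (np.isfinite(x) and np.isfinite(t)):
            return FamilyContribution(fam, 0.0, 0.0, False, len(fam.offspring_ids))
        xs.append(float(x))
        ts.append(float(t))
        es.append(m.expected_count)
        vs.append(m.variance)
    t_arr = np.array(ts)
    dev = np.array(xs) - np.array(es)
    u = float(np.dot(t_arr, dev))
    v_model = float(np.dot(t_arr * t_arr, np.array(vs)))
    return FamilyContribution(fam, u, v_model, v_model > 0.0, len(fam.offspring_ids))


@dataclass
class TestResult:
    """Outcome of the score test for one unit (marker, gene, or window)."""

    __test__ = False  # not a pytest collection target

    unit_name: str
    score_u: float
    variance_v: float
    z: float | None
    p_two_sided: float | None
    n_informative_families: int
    n_variants_collapsed: int
    status: str
    chromosome: str | None = None
    span: tuple[int, int] | None = None
    p_bonferroni: float | None = None

    def to_row(self) -> dict:
        span = f"{self.span[0]}-{self.span[1]}" if self.span else ""
        return {
            "unit_name": self.unit_name,
            "chrom": self.chromosome or "",
            "span": span,
            "n_variants": self.n_variants_collapsed,
            "n_families": self.n_informative_families,
            "U": self.score_u,
            "V": self.variance_v,
            "Z": self.z,
            "p": self.p_two_sided,
            "p_bonferroni": self.p_bonferroni,
            "status": self.status,
        }


def fbat_test(
    contributions: Sequence[FamilyContribution],
    variance_mode: str = "model",
    min_informative: int = 10,
    unit_name: str = "",
    n_variants: int = 1,
    chromosome: str | None = None,
    span: tuple[int, int] | None = None,
) -> TestResult:
    """Combine family contributions into the two-sided score test.

    U sums u_i over informative families; V is the model-based conditional
    variance or the empirical sum of squares.  ``status`` is ``uninformative``
    when V = 0 and ``below_min_families`` when fewer than ``min_informative``
    families are informative; in either case no p-value is reported.
    """
    if variance_mode not in ("model", "empirical"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    u_arr = np.array([c.u if c.informative else 0.0 for c in contributions], dtype=float)
    v_arr = np.array([c.v_model for c in contributions], dtype=float)
    u_total = float(np.sum(u_arr)) if u_arr.size else 0.0
    if variance_mode == "model":
        v_total = float(np.sum(v_arr)) if v_arr.size else 0.0
    else:
        v_total = float(np.sum(u_arr * u_arr)) if u_arr.size else 0.0
    n_informative = int(sum(c.informative for c in contributions))

    kwargs = dict(
        unit_name=unit_name,
        score_u=u_total,
        variance_v=v_total,
        n_informative_families=n_informative,
        n_variants_collapsed=n_variants,
        chromosome=chromosome,
        span=span,
    )
    if v_total <= 0.0:
        return TestResult(z=None, p_two_sided=None, status=STATUS_UNINFORMATIVE, **kwargs)
    if n_informative < min_informative:
        return TestResult(z=None, p_two_sided=None, status=STATUS_BELOW_MIN, **kwargs)
    z = u_total / np.sqrt(v_total)
    p = float(2.0 * norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)  # keep p in (0, 1]
    return TestResult(z=float(z), p_two_sided=p, status=STATUS_OK, **kwargs)
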