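"""The family score test: conditional moments, contributions, and the statistic."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import fbatrare as fb
from fbatrare.core import (
    STATUS_BELOW_MIN,
    STATUS_OK,
    STATUS_UNINFORMATIVE,
    FamilyContribution,
    UninformativeFamilyError,
)
from fbatrare.pedigree import NuclearFamily


def enumerate_transmissions(father, mother, n_offspring):
    """Independent oracle: every transmission vector with its probability.

    Each offspring draws one of the father's two alleles and one of the
    mother's, each choice with probability 1/2; alleles of a parent with
    count c are (c >= 1, c == 2).
    """
    f_alleles = [1 if father >= 1 else 0, 1 if father == 2 else 0]
    m_alleles = [1 if mother >= 1 else 0, 1 if mother == 2 else 0]
    per_off = [fa + ma for fa in f_alleles for ma in m_alleles]  # 4 outcomes, p=1/4
    for combo in itertools.product(per_off, repeat=n_offspring):
        yield np.array(combo, dtype=float), 0.25**n_offspring


@pytest.mark.parametrize(
    "father,mother,expected_support,expected_e,expected_var",
    [
        (1, 1, {0: 0.25, 1: 0.5, 2: 0.25}, 1.0, 0.5),
        (0, 2, {1: 1.0}, 1.0, 0.0),
        (1, 0, {0: 0.5, 1: 0.5}, 0.5, 0.25),
    ],
)
def test_conditional_dist_worked_examples(father, mother, expected_support, expected_e, expected_var):
    m = fb.offspring_conditional_dist(father, mother)
    assert m.support == pytest.approx(expected_support)
    assert m.expected_count == pytest.approx(expected_e)
    assert m.variance == pytest.approx(expected_var)


def test_conditional_dist_matches_enumeration_for_all_parent_pairs():
    for father in (0, 1, 2):
        for mother in (0, 1, 2):
            m = fb.offspring_conditional_dist(father, mother)
            probs: dict[float, float] = {}
            for vec, p in enumerate_transmissions(father, mother, 1):
                probs[vec[0]] = probs.get(vec[0], 0.0) + p
            for g, p in probs.items():
                assert m.support.get(g, 0.0) == pytest.approx(p, abs=1e-15)
            e = sum(g * p for g, p in probs.items())
            var = sum(g * g * p for g, p in probs.items()) - e * e
            assert m.expected_count == pytest.approx(e, abs=1e-15)
            assert m.variance == pytest.approx(var, abs=1e-15)


def test_missing_parent_signals_uninformative():
    with pytest.raises(UninformativeFamilyError):
        fb.offspring_conditional_dist(None, 1)
    with pytest.raises(UninformativeFamilyError):
        fb.offspring_conditional_dist(1, float("nan"))


def _fam(*offspring):
    return NuclearFamily("F1", "DAD", "MOM", tuple(offspring))


def test_family_contribution_worked_example():
    # parents (1,0): E[X]=0.5, Var=0.25; offspring (X=1,T=+1), (X=0,T=-1)
    fam = _fam("O1", "O2")
    moments = {o: fb.offspring_conditional_dist(1, 0) for o in fam.offspring_ids}
    contrib = fb.family_score_contribution(
        fam, {"O1": 1, "O2": 0}, {"O1": 1.0, "O2": -1.0}, moments
    )
    assert contrib.u == pytest.approx(1.0)
    assert contrib.v_model == pytest.approx(0.5)
    assert contrib.informative


def test_family_contribution_degenerate_cases():
    fam = _fam("O1")
    hom = {"O1": fb.offspring_conditional_dist(0, 0)}
    c = fb.family_score_contribution(fam, {"O1": 0}, {"O1": 2.0}, hom)
    assert (c.u, c.v_model, c.informative) == (0.0, 0.0, False)
    het = {"O1": fb.offspring_conditional_dist(1, 1)}
    c = fb.family_score_contribution(fam, {"O1": 1}, {"O1": 0.0}, het)
    assert (c.u, c.v_model, c.informative) == (0.0, 0.0, False)
    # missing offspring marker fails the precondition -> uninformative
    c = fb.family_score_contribution(fam, {}, {"O1": 1.0}, het)
    assert not c.informative


def test_score_and_variance_match_enumeration_oracle():
    """E[u]=0 and Var(u)=v_model under the transmission law, to 1e-12."""
    traits = [1.3, -0.7, 0.4]
    for father, mother in itertools.product((0, 1, 2), repeat=2):
        m = fb.offspring_conditional_dist(father, mother)
        for n_off in (1, 2, 3):
            t = np.array(traits[:n_off])
            mean_u = 0.0
            var_u = 0.0
            for vec, p in enumerate_transmissions(father, mother, n_off):
                u = float(np.dot(t, vec - m.expected_count))
                mean_u += p * u
                var_u += p * u * u
            var_u -= mean_u**2
            fam = _fam(*[f"O{i}" for i in range(n_off)])
            moments = {o: m for o in fam.offspring_ids}
            contrib = fb.family_score_contribution(
                fam,
                {o: 1 for o in fam.offspring_ids},  # any value; only v_model checked
                dict(zip(fam.offspring_ids, t)),
                moments,
            )
            assert abs(mean_u) < 1e-12
            assert abs(var_u - contrib.v_model) < 1e-12


def test_fbat_test_z_and_p_closed_form():
    fam = _fam("O1", "O2")
    moments = {o: fb.offspring_conditional_dist(1, 0) for o in fam.offspring_ids}
    contrib = fb.family_score_contribution(
        fam, {"O1": 1, "O2": 0}, {"O1": 1.0, "O2": -1.0}, moments
    )
    res = fb.fbat_test([contrib], min_informative=1)
    assert res.status == STATUS_OK
    assert res.z == pytest.approx(1.0 / np.sqrt(0.5), abs=1e-12)
    assert res.p_two_sided == pytest.approx(2 * norm.sf(np.sqrt(2)), abs=1e-12)
    assert res.p_two_sided == pytest.approx(0.15730, abs=1e-5)
    below = fb.fbat_test([contrib], min_informative=10)
    assert below.status == STATUS_BELOW_MIN and below.p_two_sided is None


def test_fbat_test_uninformative_when_variance_zero():
    c = FamilyContribution(_fam("O1"), 0.0, 0.0, False, 1)
    res = fb.fbat_test([c], min_informative=1)
    assert res.status == STATUS_UNINFORMATIVE
    assert res.p_two_sided is None and res.z is None


def test_empirical_variance_mode_uses_sum_of_squares():
    fams = []
    for i, (u, v) in enumerate([(1.0, 0.5), (-0.5, 0.25)]):
        fams.append(FamilyContribution(_fam(f"O{i}"), u, v, True, 1))
    res = fb.fbat_test(fams, variance_mode="empirical", min_informative=1)
    assert res.variance_v == pytest.approx(1.0**2 + 0.5**2)
    assert res.score_u == pytest.approx(0.5)


def test_center_trait_policies():
    np.testing.assert_allclose(fb.center_trait([1.0, 3.0]), [-1.0, 1.0])
    np.testing.assert_allclose(
        fb.center_trait([5.0], fb.TraitOffsetPolicy.fixed(5.0)), [0.0]
    )
    np.testing.assert_allclose(fb.center_trait([2.0, 2.0, 2.0]), [0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        fb.center_trait([np.nan, np.nan])


def test_p_invariant_under_trait_sign_flip():
    fam = _fam("O1", "O2", "O3")
    moments = {o: fb.offspring_conditional_dist(1, 1) for o in fam.offspring_ids}
    marker = {"O1": 2, "O2": 0, "O3": 1}
    t = {"O1": 0.8, "O2": -1.1, "O3": 0.3}
    t_neg = {k: -v for k, v in t.items()}
    r1 = fb.fbat_test([fb.family_score_contribution(fam, marker, t, moments)], min_informative=1)
    r2 = fb.fbat_test([fb.family_score_contribution(fam, marker, t_neg, moments)], min_informative=1)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-15)
    assert r1.z == pytest.approx(-r2.z, abs=1e-15)


def test_null_gene_drop_z_is_standard_normal():
    """1000 tests of 5 informative het x het families each: Z ~ N(0, 1)."""
    rng = np.random.default_rng(0)
    zs = []
    for _ in range(1000):
        contribs = []
        for i in range(5):
            fam = _fam(f"O{i}a", f"O{i}b")
            moments = {o: fb.offspring_conditional_dist(1, 1) for o in fam.offspring_ids}
            counts = {o: int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25])) for o in fam.offspring_ids}
            traits = {o: float(rng.normal()) for o in fam.offspring_ids}
            contribs.append(fb.family_score_contribution(fam, counts, traits, moments))
        res = fb.fbat_test(contribs, min_informative=1)
        zs.append(res.z)
    zs = np.array(zs)
    assert abs(zs.mean()) < 0.05
    assert 0.9 < zs.var() < 1.1
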