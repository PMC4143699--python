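"""Weights, collapsing, gene tests, window tiling and scan."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest

import fbatrare as fb
from fbatrare.collapse import TestConfig, WeightScheme, build_marker
from fbatrare.core import STATUS_OK, STATUS_UNINFORMATIVE
from fbatrare.genotypes import GenotypeMatrix, Variant
from fbatrare.pedigree import Individual, Pedigree


# -- weights ----------------------------------------------------------------


def test_weights_worked_examples():
    v1 = WeightScheme("v1", zeta=1)
    assert fb.compute_weights([0.5], v1)[0] == pytest.approx(2.0)
    v1_10 = WeightScheme("v1", zeta=10)
    assert fb.compute_weights([0.01], v1_10)[0] == pytest.approx(
        1.0 / np.sqrt(10 * 0.01 * 0.99), abs=1e-12
    )
    assert fb.compute_weights([0.01], v1_10)[0] == pytest.approx(3.17821, abs=1e-5)
    np.testing.assert_allclose(fb.compute_weights([0.1, 0.01], WeightScheme("v0")), [1.0, 1.0])
    linear = WeightScheme("v1", zeta=10, weight_form="linear")
    assert fb.compute_weights([0.01], linear)[0] == pytest.approx(1.0 / 0.099)


def test_weights_reject_degenerate_frequencies():
    with pytest.raises(ValueError):
        fb.compute_weights([0.0], WeightScheme("v1", zeta=5))
    with pytest.raises(ValueError):
        fb.compute_weights([1.0], WeightScheme("v1", zeta=5))
    with pytest.raises(ValueError):
        WeightScheme("v1")  # zeta required


@given(
    st.lists(st.floats(min_value=1e-4, max_value=0.5), min_size=2, max_size=10, unique=True)
)
def test_v1_weights_strictly_decreasing_in_frequency(ps):
    ps = sorted(ps)
    w = fb.compute_weights(ps, WeightScheme("v1", zeta=7))
    assert np.all(np.diff(w) < 0)


# -- rare-variant selection -------------------------------------------------


def _matrix_with_mafs(mafs):
    variants = [
        Variant("1", 100 * (i + 1), "A", "C", "alt", m) for i, m in enumerate(mafs)
    ]
    counts = np.zeros((2, len(mafs)), dtype=np.int8)
    return GenotypeMatrix(variants, ["S1", "S2"], counts)


def test_select_rare_strict_threshold_and_monomorphic_exclusion():
    gm = _matrix_with_mafs([0.009, 0.01, 0.05, 0.0])
    assert fb.select_rare_variants(gm, 0.01) == [0]
    assert fb.select_rare_variants(gm, 0.5) == [0, 1, 2]  # all polymorphic


# -- collapsing -------------------------------------------------------------


def _two_variant_setup():
    ped = Pedigree(
        [
            Individual("DAD", "F1", sex="male"),
            Individual("MOM", "F1", sex="female"),
            Individual("KID", "F1", father_id="DAD", mother_id="MOM"),
        ]
    )
    variants = [Variant("1", 100, "A", "C", "alt", 0.1), Variant("1", 200, "A", "C", "alt", 0.2)]
    # rows: DAD, MOM, KID; variant1 parents (1,0), variant2 parents (0,0)
    counts = np.array([[1, 0], [0, 0], [1, 0]], dtype=np.int8)
    return ped, GenotypeMatrix(variants, ["DAD", "MOM", "KID"], counts)


def test_collapse_moments_with_nonsegregating_second_variant():
    ped, gm = _two_variant_setup()
    marker = fb.collapse_genotypes(gm, ped, [0, 1], [1.0, 2.0], "unit")
    fd = marker.families[0]
    assert fd.x[0] == pytest.approx(1.0)  # X = 1*1 + 2*0
    assert fd.expected == pytest.approx(0.5)
    assert fd.variance == pytest.approx(0.25)


def test_offspring_missing_a_collapsed_variant_is_dropped():
    ped, gm = _two_variant_setup()
    gm.counts[2, 1] = -1  # KID missing variant 2
    marker = fb.collapse_genotypes(gm, ped, [0, 1], [1.0, 1.0], "unit")
    assert marker.families == []  # only offspring dropped -> family has none left
    single = fb.collapse_genotypes(gm, ped, [0], [1.0], "unit")
    assert single.families[0].offspring_ids == ("KID",)


def test_missing_parent_excludes_whole_family():
    ped, gm = _two_variant_setup()
    gm.counts[1, 1] = -1  # MOM missing variant 2
    marker = fb.collapse_genotypes(gm, ped, [0, 1], [1.0, 1.0], "unit")
    assert marker.families == []


# -- identity reduction and scale invariance --------------------------------


def _identity_dataset():
    inds, counts_rows, traits = [], {}, {}
    # 12 families: parents (1,0), two offspring with counts (1,0)
    for i in range(1, 13):
        fam = f"F{i:02d}"
        dad, mom = f"{fam}D", f"{fam}M"
        o1, o2 = f"{fam}a", f"{fam}b"
        inds += [
            Individual(dad, fam, sex="male"),
            Individual(mom, fam, sex="female"),
            Individual(o1, fam, father_id=dad, mother_id=mom),
            Individual(o2, fam, father_id=dad, mother_id=mom),
        ]
        counts_rows.update({dad: 1, mom: 0, o1: 1, o2: 0})
        traits.update({o1: 1.0 + 0.25 * i, o2: -1.0 - 0.5 * i, dad: 0.0, mom: 0.0})
    ped = Pedigree(inds)
    ids = list(ped.individual_ids)
    variants = [Variant("1", 1000, "A", "C", "alt", 0.005)]
    counts = np.array([[counts_rows[i]] for i in ids], dtype=np.int8)
    return ped, GenotypeMatrix(variants, ids, counts), traits


def test_single_variant_v0_collapse_equals_raw_marker_test_bitwise():
    ped, gm, traits = _identity_dataset()
    region = fb.Region("g", "1", 0, 2000)
    cfg = TestConfig(scheme="v0", min_informative=1)
    pipeline = fb.gene_test(gm, ped, region, traits, cfg)

    # raw single-marker path composed from the core operations
    fams = fb.decompose_nuclear_families(ped)
    entering = [o for f in fams for o in f.offspring_ids]
    centered = fb.center_trait([traits[o] for o in entering])
    t_map = dict(zip(entering, centered))
    contribs = []
    for f in fams:
        m = fb.offspring_conditional_dist(
            int(gm.counts_for(f.father_id)[0]), int(gm.counts_for(f.mother_id)[0])
        )
        contribs.append(
            fb.family_score_contribution(
                f,
                {o: float(gm.counts_for(o)[0]) for o in f.offspring_ids},
                t_map,
                {o: m for o in f.offspring_ids},
            )
        )
    raw = fb.fbat_test(contribs, min_informative=1)

    assert pipeline.status == raw.status == STATUS_OK
    assert pipeline.score_u == raw.score_u
    assert pipeline.variance_v == raw.variance_v
    assert pipeline.z == raw.z
    assert pipeline.p_two_sided == raw.p_two_sided


def test_weight_scale_invariance_of_z_and_p(null_dataset):
    ds = null_dataset
    region = ds.regions[0]
    sub = ds.genotypes.subset_region(region)
    rare = fb.select_rare_variants(sub, 0.01)
    w = fb.compute_weights(sub.founder_mafs()[rare], WeightScheme("v1", zeta=120))
    traits = ds.traits.replicate(1)
    cfg = TestConfig()
    r1 = fb.collapsed_marker_test(fb.collapse_genotypes(sub, ds.pedigree, rare, w, "u"), traits, cfg)
    r2 = fb.collapsed_marker_test(
        fb.collapse_genotypes(sub, ds.pedigree, rare, 3.7 * w, "u"), traits, cfg
    )
    assert r1.status == r2.status == STATUS_OK
    assert r1.z == pytest.approx(r2.z, abs=1e-12)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)


# -- window tiling ----------------------------------------------------------


def test_tile_windows_worked_examples():
    wins = fb.tile_windows("3", 250_000)
    assert len(wins) == 3 and wins[-1].end == 300_000
    assert len(fb.tile_windows("3", 100_000)) == 2
    assert [w.start for w in wins] == [0, 100_000, 200_000]
    assert wins[0].id == "3:0-100000"


def test_window_boundary_belongs_to_right_hand_window():
    wins = fb.tile_windows("3", 200_000)
    assert sum(w.start <= 100_000 < w.end for w in wins) == 1
    hit = next(w for w in wins if w.start <= 100_000 < w.end)
    assert hit.start == 100_000


def test_region_overlapping_four_windows():
    region = fb.Region("big", "3", 47_892_000, 48_131_000)
    wins = fb.windows_overlapping(region)
    assert len(wins) == 4
    assert wins[0].start == 47_800_000 and wins[-1].end == 48_200_000


@given(st.integers(min_value=0, max_value=10_000_000), st.integers(min_value=1, max_value=500_000))
def test_tiling_is_disjoint_exhaustive_and_covers_max_position(pos, size):
    wins = fb.tile_windows("1", pos, size)
    assert all(b.start == a.end for a, b in zip(wins, wins[1:]))
    assert wins[0].start == 0
    assert wins[-1].end > pos >= wins[-1].start


def test_windows_partition_chromosome_variants(map4_dataset):
    ds = map4_dataset
    cfg = TestConfig()
    rare_total = len(fb.select_rare_variants(ds.genotypes, cfg.maf_threshold))
    results = fb.window_scan(ds.genotypes, ds.pedigree, "3", ds.traits.replicate(1), cfg)
    assert sum(r.n_variants_collapsed for r in results) == rare_total
    spans = [r.span for r in results]
    assert len(set(spans)) == len(spans)


def test_window_scan_invariant_to_variant_input_order(map4_dataset):
    ds = map4_dataset
    gm = ds.genotypes
    rng = np.random.default_rng(4)
    perm = rng.permutation(gm.n_variants)
    shuffled = GenotypeMatrix(
        [gm.variants[i] for i in perm], list(gm.individuals), gm.counts[:, perm]
    )
    traits = ds.traits.replicate(2)
    cfg = TestConfig()
    res_a = fb.window_scan(gm, ds.pedigree, "3", traits, cfg)
    res_b = fb.window_scan(shuffled, ds.pedigree, "3", traits, cfg)
    assert [r.unit_name for r in res_a] == [r.unit_name for r in res_b]
    for a, b in zip(res_a, res_b):
        assert a.score_u == pytest.approx(b.score_u, abs=1e-9)
        assert a.variance_v == pytest.approx(b.variance_v, abs=1e-9)


# -- gene test --------------------------------------------------------------


def test_gene_without_rare_variants_is_uninformative(null_dataset):
    empty = fb.Region("desert", "3", 0, 1000)
    res = fb.gene_test(null_dataset.genotypes, null_dataset.pedigree, empty, null_dataset.traits.replicate(1))
    assert res.status == STATUS_UNINFORMATIVE
    assert res.p_two_sided is None and res.n_variants_collapsed == 0


def test_causal_dense_region_detected_in_majority_of_replicates(map4_dataset):
    ds = map4_dataset
    dense = fb.Region("dense", "3", 48_000_000, 48_100_000)
    hits = 0
    for r in ds.traits.replicate_ids:
        res = fb.gene_test(ds.genotypes, ds.pedigree, dense, ds.traits.replicate(r))
        hits += res.status == STATUS_OK and res.p_two_sided < 1e-4
    assert hits > len(ds.traits.replicate_ids) / 2


def test_permuted_traits_give_uniform_p_values(map4_dataset):
    """Permuting traits across individuals breaks the association: p ~ U(0,1)."""
    ds = map4_dataset
    big = next(r for r in ds.regions if r.name == "BIG_GENE")
    marker = build_marker(ds.genotypes, ds.pedigree, big, TestConfig(), "BIG_GENE")
    rng = np.random.default_rng(99)
    pvals = []
    for r in ds.traits.replicate_ids:
        tr = ds.traits.replicate(r)
        permuted = dict(zip(tr.index, rng.permutation(tr.to_numpy())))
        res = fb.collapsed_marker_test(marker, permuted, TestConfig())
        pvals.append(res.p_two_sided)
    assert kstest(pvals, "uniform").pvalue > 0.01


# -- bonferroni -------------------------------------------------------------


def test_bonferroni_examples_and_errors():
    assert fb.bonferroni_adjust(1e-7, 2) == pytest.approx(2e-7)
    assert fb.bonferroni_adjust(0.6, 4) == 1.0
    assert fb.bonferroni_adjust(0.01, 1) == 0.01
    with pytest.raises(ValueError):
        fb.bonferroni_adjust(0.01, 0)
    with pytest.raises(ValueError):
        fb.bonferroni_adjust(0.0, 2)
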