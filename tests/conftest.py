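import pytest
from hypothesis import HealthCheck, settings

import fbatrare as fb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def null_dataset():
    """Null study: 20 pedigrees, 50 genes, no genetic or covariate effects."""
    return fb.simulate_dataset(fb.make_gaw_like_scenario("null", seed=1))


@pytest.fixture(scope="session")
def wf_dataset():
    """Weight-favoring study: causal effects on the rarest variants."""
    return fb.simulate_dataset(fb.make_gaw_like_scenario("weight_favoring", seed=1))


@pytest.fixture(scope="session")
def map4_dataset():
    """Large clustered-causal gene spanning four 100-kb windows."""
    return fb.simulate_dataset(fb.make_gaw_like_scenario("map4_like", seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny simulated study for fast I/O and bookkeeping tests."""
    cfg = fb.SimConfig(
        seed=11,
        n_pedigrees=3,
        generations=3,
        n_genes=2,
        variants_per_gene=6,
        maf_range=(0.02, 0.1),
        n_replicates=4,
    )
    return fb.simulate_dataset(cfg)


@pytest.fixture()
def trio_ped_file(tmp_path):
    path = tmp_path / "trio.ped"
    path.write_text(
        "FAM1 DAD 0 0 1 0\n"
        "FAM1 MOM 0 0 2 0\n"
        "FAM1 KID DAD MOM 1 0\n"
    )
    return path
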