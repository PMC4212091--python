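import numpy as np
import pytest

import mapbias as mb


@pytest.fixture(scope="session")
def small_cfg():
    return mb.SimulationConfig(rng_seed=7, genome_len=20_000, n_individuals=20)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """A 20 kb genome with 30 SNPs and 5 indels, no duplications."""
    return mb.make_reference_panel(small_cfg, n_snps=30, n_indels=5)


@pytest.fixture(scope="session")
def planted_panel(small_cfg):
    """Same genome family with a biased duplication planted at one SNP."""
    ref, panel = mb.make_reference_panel(small_cfg, n_snps=12, n_indels=0)
    target = panel.variants[3].vid
    ref, copy_loc = mb.plant_biased_duplication(ref, panel, target, small_cfg)
    return ref, panel, target, copy_loc


@pytest.fixture(scope="session")
def cohort_fixture():
    """Desk-scale cohort: 60 individuals, 20 true + 5 bias + 10 null genes."""
    cfg = mb.SimulationConfig(rng_seed=11, n_individuals=60)
    return mb.build_cohort_fixture(cfg)


@pytest.fixture(scope="session")
def cohort_analysis(cohort_fixture, tmp_path_factory):
    from mapbias.eqtl import EqtlConfig
    from mapbias.pipeline import run_cohort_analysis

    work = tmp_path_factory.mktemp("cohort")
    return run_cohort_analysis(
        cohort_fixture,
        work,
        eqtl_cfg=EqtlConfig(cis_window=2500, n_perm=300, rng_seed=11),
        drop_threshold=3.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
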