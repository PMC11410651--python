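import pytest

import epicenmap as em


@pytest.fixture(scope="session")
def tiny_scenario():
    """A two-chromosome miniature of the packaged scenario for fast tests."""
    return em.default_scenario().replace(
        n_chromosomes=2,
        chromosome_length=60_000,
        centromere_start=15_000,
        centromere_end=35_000,
        element_chromosome="Chr2",
        athila5_count=3,
        athila_other_count=4,
        element_length=1_500,
        causal_chrom="Chr2",
        causal_start=24_000,
        causal_end=25_000,
        planted_dmr_chrom="Chr2",
        planted_dmr_start=26_000,
        planted_dmr_end=27_000,
        private_locus_length=800,
        population_size=60,
        pool_size=5,
        coverage=10.0,
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_scenario):
    return em.build_genome(tiny_scenario, seed=7)


@pytest.fixture(scope="session")
def default_scenario_cfg():
    return em.default_scenario()


@pytest.fixture(scope="session")
def default_genome(default_scenario_cfg):
    """The packaged reference assembly, built once per session."""
    cfg = default_scenario_cfg
    return em.build_genome(cfg, cfg.seed)
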