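import numpy as np
import pytest

from fnmut.simulate import SimConfig, GenomeConfig, simulate


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic cohort (4 Mb genome, 27 lines, noise off)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """Small, fast cohort for unit-level checks."""
    cfg = SimConfig(
        seed=7,
        genome=GenomeConfig(contigs=(("chr1", 200_000), ("chr2", 200_000))),
        n_genes=4,
    )
    cfg.cohort.n_lines = 6
    cfg.cohort.snp_mean = 20
    cfg.cohort.indel_mean = 10
    cfg.cohort.n_families = 1
    cfg.panel.n_lines = 8
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
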