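import numpy as np
import pytest

from rumenet.synthetic import SimConfig, gen_abundance_table, gen_genotypes
from rumenet.tables import AbundanceTable


@pytest.fixture(scope="session")
def two_cluster_cfg() -> SimConfig:
    return SimConfig(n_samples=200, n_genera=50, n_snps=200, seed=11)


@pytest.fixture(scope="session")
def two_cluster_sim(two_cluster_cfg):
    return gen_abundance_table(two_cluster_cfg)


@pytest.fixture(scope="session")
def small_table() -> AbundanceTable:
    rng = np.random.default_rng(3)
    counts = rng.integers(0, 200, size=(12, 8))
    counts[:, 0] += 50  # keep one genus ubiquitous
    return AbundanceTable([f"s{i}" for i in range(12)],
                          [f"g{i}" for i in range(8)], counts)


@pytest.fixture(scope="session")
def hwe_genotypes():
    cfg = SimConfig(n_samples=300, n_snps=400, seed=5)
    return gen_genotypes(cfg)
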