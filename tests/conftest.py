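import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import baiscan as b

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_cluster_config() -> b.SimConfig:
    """A compact three-cluster reference layout used across module tests."""
    return b.SimConfig(
        seed=11,
        n_clusters=3,
        genomes_per_cluster=2,
        within_cluster_divergence=0.02,
        between_cluster_divergence=0.30,
        gene_length_aa=100,
        n_reads=2000,
    )


@pytest.fixture(scope="session")
def three_cluster_reference(three_cluster_config):
    return b.generate_reference_operons(three_cluster_config)


@pytest.fixture(scope="session")
def single_genome_reference():
    """One genome, eight families, 100-aa genes — plus its ground truth."""
    config = b.SimConfig(seed=5, n_clusters=1, genomes_per_cluster=1, gene_length_aa=100)
    db, truth = b.generate_reference_operons(config)
    return config, db, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
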